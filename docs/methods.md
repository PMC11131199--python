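# Methods

This note documents the models, rules and numerical choices behind
`cazyome`, in the order the pipeline applies them, and what the
simulation-based tests do and do not establish.

## Consensus calling

Three annotation tools disagree routinely; the consensus rule is
asymmetric by design. HMMER profile matches define family membership:
a gene is **classified** iff HMMER hit it, and each HMMER label becomes
one module, so a protein annotated `GH5_2 + CBM6` counts two modules
(repeated labels are repeated modules — tandem CBMs are real).
DIAMOND/Hotpep evidence without HMMER yields an **unclassified**
CAZyme: probable activity, no family. Because family-level statistics
are built only from HMMER labels, unclassified genes never enter
diversity or profile matrices; they are tracked separately as the
unclassified ratio `u/(c+u)` and as candidate novelty inside clusters.

GT exclusion (default on) removes glycosyltransferase modules *before*
status is decided. One consequence is deliberate and worth stating: a
gene whose HMMER hits are all GT keeps status `none` even if DIAMOND
carries a GH label, because HMMER presence settles the
classified/unclassified split first. The alternative (demoting such
genes to unclassified) would make the unclassified set depend on the
exclusion flag; we chose the literal rule and note that with realistic
inputs the case is rare (HMMER-GT plus DIAMOND-GH disagreement).

## Cluster detection

Clusters are detected per contig on **gene ranks** (position in gene
order), never base-pair distances, so assembler-dependent intergenic
spacing cannot change results; strand is ignored. Signature genes are
classified CAZymes and auxiliary genes; auxiliary status comes from
case-insensitive product-text signatures (transcription
regulator/factor, transporter, permease, porin, TonB, MFS, ABC) that
stand in for CGCFinder's TF/transporter databases, and is configurable
because product vocabularies vary by annotation pipeline. CAZyme status
takes precedence over any product text.

The chaining rule: consecutive signature genes with more than
`max_gap = 2` intervening other genes break the chain; a maximal chain
is emitted iff it has ≥ 1 CAZyme and (≥ 1 auxiliary or ≥ 2 CAZymes),
trimmed to start and end on signature genes. The gap constraint is
pairwise between consecutive signature genes, not a budget over the
whole cluster. Because the composition rule is monotone in member
counts, a maximal chain failing composition contains no valid
sub-window — greedy chaining is therefore *exactly* equivalent to
enumerating all windows and keeping maximal valid ones, which the test
suite verifies against an independent brute-force oracle on 1000+
random contigs at `max_gap` 0–3. Contig ends terminate chains; there
is no circular-replicon handling (draft genomes are linear contigs).

Unclassified CAZymes count as "other" genes for chaining (they have no
family and CGCFinder's signature logic would not see them) but are
reported inside the unassigned-within-cluster fraction, which is where
novel in-cluster enzymes would surface.

## Substrates and secretion

Only GH and PL modules are categorised (CE/AA/CBM support degradation
but do not define the target substrate). Lookup tries the subfamily
label first, then the parent family; unmapped families are
`unassigned` and reduce the assigned ratio. The shipped map covers ~40
well-characterised families for demonstrations and tests; real
analyses should supply a curated table (same 3-column TSV). The map is
single-category per label; polyspecific families (e.g. GH95, GH141)
are forced to their dominant target, an acknowledged simplification.

The assigned ratio counts **modules** (a bifunctional GH5+GH10 protein
contributes twice); secretion ratios count **genes**, because a signal
peptide belongs to the whole protein. A gene whose modules map to
several categories counts once in each category's secretion
denominator. Genes without a signal-peptide record are treated as
having none. By default any type ≠ NONE counts as secreted/anchored;
restricting the accepted type set can only lower the ratio (tested as
a monotonicity property).

## Per-genome metrics and filtering

Coding frequency = 100 × classified CAZyme genes / metadata protein
count; the protein count comes from metadata rather than the GFF so
fragmented or truncated fixtures remain usable. The T1/T2 trend splits
on GH+CBM coding frequency strictly above 2%; exactly 2% goes to T2
(the boundary must land somewhere; the lower bin was chosen and is
asserted in tests). Quality filtering keeps genomes with completeness
strictly above 75%, contamination strictly below 10% and ≥ 10
classified CAZymes — all three boundaries exact and boundary-tested.
Taxonomy classes with fewer than 10 retained genomes are pooled into
"other class" before group statistics. Rare families are those present
in strictly fewer than 5% of genomes.

Spearman GH–CBM diversity correlation uses average-rank ties; the
two-sided p comes from the t approximation for n ≥ 10 and from the
exact permutation distribution for n < 10, where small taxon groups
make the approximation unreliable (full n! enumeration is affordable
below 10).

## Comparative statistics

Profiles default to family granularity (subfamily optional) and
presence/absence. Jaccard distance over family sets; a pair of empty
repertoires is defined as distance 0 with a warning (identical
emptiness as identity) — post-filter matrices cannot contain such
genomes anyway.

PCoA is computed in-package by Gower double-centering and symmetric
eigendecomposition so the full eigenvalue spectrum is reported;
negative eigenvalues (non-Euclidean distances) are kept visible and
contribute no axes (positive-eigenvalue cutoff 1e-10). For
Euclidean-embeddable input the coordinates reproduce the distances to
1e-8, and the coordinates match scikit-bio's `pcoa` up to axis sign;
scikit-bio serves as the cross-check, not the implementation.
PERMANOVA and ANOSIM are delegated to scikit-bio with an explicit
seed; p = (1 + #{permuted statistic ≥ observed}) / (1 + permutations),
default 999 permutations, seed mandatory. Calibration is verified
empirically: over 500 structure-free simulated datasets both tests
reject at the nominal 5% rate (±2 points).

Benjamini–Hochberg adjustment is the step-up rule
`min_{j≥i}(p_(j)·m/j)` clipped at 1, implemented in-package so it can
be held to exact agreement with an independent brute-force
implementation; NaNs (skipped constant families) pass through and do
not count toward m. The statsmodels implementation agrees to 1e-12.

LDA effect sizes follow LEfSe's conventions: per-genome profiles are
normalised to one million, families are screened by Kruskal–Wallis at
raw p < 0.05, and the effect size is the between-class mean difference
of normalised abundance averaged over 30 bootstrap rounds subsampling
2/3 of each class, reported as log10 with > 4 flagged. For a single
family the discriminant axis is the feature itself, so the
one-dimensional per-family formulation replaces LEfSe's joint LDA fit;
scores are comparable in rank, not bit-identical to the R package.
Multi-class inputs use the maximum pairwise class-mean difference.

Novelty: best hit per query is maximal bitscore, ties broken by higher
identity then lexicographically smaller subject; < 30% identity flags
a putatively novel enzyme. No coverage/e-value filter is applied by
default (the upstream search is expected to have applied its own).

## Synthetic data: what it emulates, and what it does not

The generator emulates annotation *outputs*: per-group family
occurrence probabilities, planted clusters with controlled
composition, multi-modular genes (10% get a CBM attachment),
DIAMOND-only unclassified genes (4% of classified), GT genes (3%),
category-dependent signal-peptide probabilities, best-hit identities
(normal, mean 55, sd 15), and uniform completeness/contamination in
realistic post-QC ranges (80–100%, 0–5%).

Layout guarantees make planted structure identifiable: clusters are
flanked by at least `max_gap + 1` non-signature genes, background
CAZymes are isolated singletons (failing composition alone), and
auxiliary products appear only inside planted clusters — so planted
clusters are provably the only clusters, and recovery can be scored
as exact precision/recall. Genomes are single-contig; fragmentation in
real drafts truncates clusters at contig ends, which the detector
handles but the generator does not model, so recovery rates here say
nothing about sensitivity lost to assembly breaks. Other unmodelled
features of real data: annotation errors correlated between tools,
operonic order within clusters, family co-occurrence structure beyond
independence, and any sequence-level signal. Passing tests therefore
demonstrate algorithmic correctness under the stated generative
assumptions, not field performance.

The `paper_flavoured` preset contrasts 30 diverse genomes (GH family
occurrence 0.65 over a 60-family universe → ~40 distinct GH
families/genome, > 2% GH+CBM coding frequency, trend T1) with 30
specialists (0.08 → ~9, with planted-cluster genes adding ~3–4
families over the background draw; < 2%, T2), 1800–2200 genes per
genome, 2 planted clusters each. Problem sizes used by the acceptance
computations — 1000 oracle contigs, 500 null calibrations at 40
genomes / 199 permutations, 100 enrichment replicates at 50 genomes
per group with 100 background families and occupancy 0.9 vs 0.1 —
were chosen to give stable rates at desk scale while exercising the
full pipeline code paths.

## Known limitations

- Family assignment trusts the upstream overview table; no e-value or
  coverage re-thresholding is performed.
- The substrate map is a small default; conclusions about biomass
  specialisation require a curated map.
- The per-family LDA formulation ignores covariance between families
  that LEfSe's joint fit would capture.
- PERMANOVA is one-factor with unordered groups; no marginal/sequential
  decomposition for multi-factor designs.
- Quarantine tolerates up to 10% unreadable genomes per run; beyond
  that the run aborts rather than silently analysing a biased subset.
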