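"""Synthetic annotated-genome bundles with known ground truth.

The generator emulates the *statistical structure of annotation
outputs* for a set of draft genomes — per-group CAZyme family
occurrence profiles, co-localised gene clusters, multi-modular
proteins, unclassified (DIAMOND-only) CAZymes, signal-peptide labels
and quality metadata — without simulating any sequence. Every emitted
bundle parses cleanly through :mod:`cazyome.io`, and planted structure
(cluster spans, enriched families, per-gene truth) is recorded so
recovery can be scored exactly.

Layout contract: planted clusters are flanked by at least
``max_gap + 1`` non-signature genes, and background CAZyme genes are
placed so that no *accidental* cluster can form (isolated singletons
fail the composition rule; auxiliary products appear only inside
planted clusters). Planted clusters are therefore exactly the clusters
a correct detector must report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .consensus import CazymeModule, ToolHits
from .io import (
    GeneRecord,
    GenomeMetadata,
    SignalPeptideCall,
    AlignmentHit,
    write_dbcan_overview,
    write_gff,
    write_metadata,
    write_outfmt6,
    write_signalp,
)
from .substrates import SubstrateMap

AUX_PRODUCTS = (
    "ABC transporter permease",
    "MFS transporter",
    "TonB-dependent receptor",
    "LacI family transcriptional regulator",
    "sugar ABC transporter substrate-binding protein",
    "outer membrane porin",
)

OTHER_PRODUCTS = (
    "hypothetical protein",
    "hypothetical protein",
    "hypothetical protein",  # weighted towards hypothetical
    "DNA polymerase III subunit beta",
    "50S ribosomal protein L3",
    "elongation factor Tu",
    "chaperonin GroEL",
    "two-component sensor histidine kinase",
)

CBM_ATTACHMENTS = ("CBM2", "CBM6", "CBM13", "CBM50")


@dataclass
class SimulationConfig:
    """Conditions for one simulated dataset.

    ``group_family_probs`` maps group -> {family label -> occurrence
    probability}; ``planted_enrichments`` entries are
    (family, group, occupancy_in_group, occupancy_elsewhere).
    """

    seed: int = 0
    n_genomes: dict[str, int] = field(default_factory=lambda: {"A": 10, "B": 10})
    genes_per_genome: tuple[int, int] = (120, 160)
    group_family_probs: dict[str, dict[str, float]] = field(default_factory=dict)
    planted_enrichments: list[tuple[str, str, float, float]] = field(default_factory=list)
    planted_cgcs_per_genome: int = 0
    cgc_n_cazymes: tuple[int, int] = (2, 3)
    cgc_n_auxiliary: tuple[int, int] = (1, 1)
    max_gap: int = 2
    flank_gap: int = 3  # must exceed max_gap
    isolate_background: bool = True
    fraction_multimodular: float = 0.10
    fraction_unclassified: float = 0.04
    fraction_gt: float = 0.03  # GT genes per genome, relative to CAZyme genes
    tool_agreement: float = 0.7  # P(Hotpep/DIAMOND also hit a classified gene)
    sp_prob_by_category: dict[str, float] = field(
        default_factory=lambda: {
            "lignocellulose": 0.8,
            "algal polysaccharides": 0.8,
            "pectin": 0.8,
            "glucans": 0.25,
            "*": 0.5,
        }
    )
    completeness_range: tuple[float, float] = (80.0, 100.0)
    contamination_range: tuple[float, float] = (0.0, 5.0)
    habitats: tuple[str, ...] = ("soil", "marine sediment", "freshwater")
    emit_signalp: bool = True
    emit_outfmt6: bool = True
    identity_mean: float = 55.0
    identity_sd: float = 15.0

    def validate(self) -> None:
        if self.flank_gap <= self.max_gap:
            raise ValueError("flank_gap must exceed max_gap so planted clusters are unambiguous")
        for probs in self.group_family_probs.values():
            for fam, p in probs.items():
                CazymeModule.parse(fam)
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"occurrence probability for {fam} outside [0,1]")
        for frac in (self.fraction_multimodular, self.fraction_unclassified, self.fraction_gt):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0,1]")


@dataclass
class GroundTruth:
    planted_cgcs: list[dict] = field(default_factory=list)
    planted_enriched_families: list[str] = field(default_factory=list)
    gene_status: dict[str, str] = field(default_factory=dict)
    gene_sp_type: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


@dataclass
class Bundle:
    """In-memory dataset: everything the pipeline consumes."""

    genes_by_genome: dict[str, list[GeneRecord]]
    hits_by_genome: dict[str, list[ToolHits]]
    signalp_calls: list[SignalPeptideCall]
    metadata: list[GenomeMetadata]
    alignment_hits: list[AlignmentHit]
    substrate_map: SubstrateMap
    groups: dict[str, str]  # genome_id -> group label

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit the bundle as files; returns the path map."""
        outdir = Path(outdir)
        (outdir / "gff").mkdir(parents=True, exist_ok=True)
        (outdir / "overview").mkdir(exist_ok=True)
        paths = {"gff_dir": outdir / "gff", "overview_dir": outdir / "overview"}
        for gid in sorted(self.genes_by_genome):
            write_gff(self.genes_by_genome[gid], outdir / "gff" / f"{gid}.gff")
            write_dbcan_overview(self.hits_by_genome[gid], outdir / "overview" / f"{gid}.tsv")
        paths["signalp"] = outdir / "signalp.tsv"
        write_signalp(self.signalp_calls, paths["signalp"])
        paths["metadata"] = outdir / "metadata.tsv"
        write_metadata(self.metadata, paths["metadata"])
        paths["outfmt6"] = outdir / "hits.outfmt6"
        write_outfmt6(self.alignment_hits, paths["outfmt6"])
        paths["substrate_map"] = outdir / "substrate_map.tsv"
        self.substrate_map.to_tsv(paths["substrate_map"])
        return paths


def _plan_families(
    rng: np.random.Generator,
    group: str,
    config: SimulationConfig,
) -> list[str]:
    """Draw the present-family set for one genome of ``group``."""
    probs = dict(config.group_family_probs.get(group, {}))
    for fam, g, occ_high, occ_low in config.planted_enrichments:
        probs[fam] = occ_high if g == group else occ_low
    present = []
    for fam in sorted(probs):
        if rng.random() < probs[fam]:
            present.append(fam)
    return present


def _gene_plan_for_genome(
    rng: np.random.Generator, group: str, config: SimulationConfig
) -> tuple[list[tuple[str, list[str]]], list[dict]]:
    """Return (slots, planted cluster descriptors).

    ``slots`` is the laid-out gene sequence for one contig; each slot is
    (kind, modules) with kind in {CAZ, AUX, OTH, UNCL, GT}.
    """
    families = _plan_families(rng, group, config)
    n_caz_bg = len(families)

    # planted clusters consume extra CAZyme genes drawn from the universe
    cluster_blocks: list[list[tuple[str, list[str]]]] = []
    cluster_meta: list[dict] = []
    universe = sorted(
        set().union(*(config.group_family_probs.get(g, {}) for g in config.n_genomes))
    ) or ["GH5"]
    for _ in range(config.planted_cgcs_per_genome):
        n_c = int(rng.integers(config.cgc_n_cazymes[0], config.cgc_n_cazymes[1] + 1))
        n_a = int(rng.integers(config.cgc_n_auxiliary[0], config.cgc_n_auxiliary[1] + 1))
        members: list[tuple[str, list[str]]] = []
        for _ in range(n_c):
            fam = universe[int(rng.integers(len(universe)))]
            members.append(("CAZ", [fam]))
        for _ in range(n_a):
            members.append(("AUX", []))
        rng.shuffle(members)
        # sprinkle OTHER genes inside, never exceeding max_gap between signatures
        block: list[tuple[str, list[str]]] = []
        for i, m in enumerate(members):
            block.append(m)
            if i < len(members) - 1:
                for _ in range(int(rng.integers(0, config.max_gap + 1))):
                    block.append(("OTH", []))
        cluster_blocks.append(block)
        cluster_meta.append({"n_cazymes": n_c, "n_auxiliary": n_a, "block_len": len(block)})

    n_uncl = int(round(config.fraction_unclassified * max(n_caz_bg, 1)))
    n_gt = int(round(config.fraction_gt * max(n_caz_bg, 1)))

    flank = config.flank_gap
    spacing = flank if config.isolate_background else 1

    slots: list[tuple[str, list[str]]] = []
    cluster_positions: list[tuple[int, int]] = []

    def pad(n: int) -> None:
        slots.extend(("OTH", []) for _ in range(n))

    pad(flank)
    for block, meta in zip(cluster_blocks, cluster_meta):
        start = len(slots)
        slots.extend(block)
        # signature span: first..last signature slot within the block
        sig_idx = [i for i, (k, _) in enumerate(block) if k in ("CAZ", "AUX")]
        cluster_positions.append((start + sig_idx[0], start + sig_idx[-1]))
        pad(flank)
    for fam in families:
        mods = [fam]
        if rng.random() < config.fraction_multimodular:
            mods.append(CBM_ATTACHMENTS[int(rng.integers(len(CBM_ATTACHMENTS)))])
        slots.append(("CAZ", mods))
        pad(spacing)
    for _ in range(n_uncl):
        slots.append(("UNCL", []))
        pad(1)
    for _ in range(n_gt):
        slots.append(("GT", []))
        pad(1)

    lo, hi = config.genes_per_genome
    if len(slots) > hi:
        raise ValueError(
            f"infeasible config: layout needs {len(slots)} genes, genome maximum is {hi}"
        )
    target = int(rng.integers(max(lo, len(slots)), hi + 1))
    pad(target - len(slots))

    for meta, (first, last) in zip(cluster_meta, cluster_positions):
        meta["first_rank"], meta["last_rank"] = first, last
    return slots, cluster_meta


def _products(rng: np.random.Generator, kind: str, modules: list[str]) -> str:
    if kind == "CAZ":
        return f"glycoside hydrolase family protein ({'+'.join(modules)})"
    if kind == "AUX":
        return AUX_PRODUCTS[int(rng.integers(len(AUX_PRODUCTS)))]
    if kind == "GT":
        return "glycosyltransferase"
    if kind == "UNCL":
        return "putative carbohydrate-active protein"
    return OTHER_PRODUCTS[int(rng.integers(len(OTHER_PRODUCTS)))]


def generate_dataset(
    config: SimulationConfig,
    outdir: str | Path | None = None,
    substrate_map: SubstrateMap | None = None,
) -> tuple[Bundle, GroundTruth]:
    """Generate a dataset under ``config``; deterministic per seed.

    Returns the in-memory bundle and its ground truth; when ``outdir``
    is given the bundle (and ground truth JSON) is also written there.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    substrate_map = substrate_map or SubstrateMap.default()
    truth = GroundTruth(
        planted_enriched_families=sorted({f for f, *_ in config.planted_enrichments})
    )

    genes_by_genome: dict[str, list[GeneRecord]] = {}
    hits_by_genome: dict[str, list[ToolHits]] = {}
    signalp_calls: list[SignalPeptideCall] = []
    metadata: list[GenomeMetadata] = []
    alignment_hits: list[AlignmentHit] = []
    groups: dict[str, str] = {}

    genome_no = 0
    for group in sorted(config.n_genomes):
        for _ in range(config.n_genomes[group]):
            genome_no += 1
            gid = f"G{genome_no:04d}"
            groups[gid] = group
            contig = f"{gid}_c1"
            slots, cluster_meta = _gene_plan_for_genome(rng, group, config)

            genes: list[GeneRecord] = []
            hits: list[ToolHits] = []
            pos = 1
            for rank, (kind, modules) in enumerate(slots):
                gene_id = f"{gid}_{rank:05d}"
                length = int(rng.integers(600, 2400))
                length -= length % 3
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(
                    GeneRecord(
                        gid, contig, gene_id, pos, pos + length - 1, strand, rank,
                        _products(rng, kind, modules), max(1, length // 3 - 1),
                    )
                )
                pos += length + int(rng.integers(20, 220))

                if kind == "CAZ":
                    labels = tuple(modules)
                    hotpep = labels if rng.random() < config.tool_agreement else ()
                    diamond = labels if rng.random() < config.tool_agreement else ()
                    hits.append(ToolHits(gene_id, hmmer=labels, hotpep=hotpep, diamond=diamond))
                    truth.gene_status[gene_id] = "classified"
                elif kind == "UNCL":
                    fam = sorted(config.group_family_probs.get(group, {"GH5": 1}))[0]
                    hits.append(ToolHits(gene_id, diamond=(fam,)))
                    truth.gene_status[gene_id] = "unclassified"
                elif kind == "GT":
                    gt_label = f"GT{int(rng.integers(1, 5))}"
                    hits.append(ToolHits(gene_id, hmmer=(gt_label,)))
                    truth.gene_status[gene_id] = "none"
                else:
                    truth.gene_status[gene_id] = "none"

                if kind == "CAZ":
                    if config.emit_signalp:
                        cats = {
                            substrate_map.lookup(CazymeModule.parse(m))[1] for m in modules
                        }
                        p_sp = max(
                            config.sp_prob_by_category.get(
                                c, config.sp_prob_by_category.get("*", 0.5)
                            )
                            for c in cats
                        )
                        if rng.random() < p_sp:
                            sp_type = ["SP", "TAT", "LIPO"][
                                int(rng.choice(3, p=[0.7, 0.15, 0.15]))
                            ]
                            prob = float(np.round(rng.uniform(0.8, 1.0), 4))
                        else:
                            sp_type, prob = "NONE", 0.0
                        signalp_calls.append(SignalPeptideCall(gene_id, sp_type, prob))
                        truth.gene_sp_type[gene_id] = sp_type
                    if config.emit_outfmt6:
                        n_hits = int(rng.integers(1, 4))
                        idents = np.clip(
                            rng.normal(config.identity_mean, config.identity_sd, n_hits),
                            5.0, 95.0,
                        )
                        bits = np.sort(rng.uniform(50, 500, n_hits))[::-1]
                        for k in range(n_hits):
                            alignment_hits.append(
                                AlignmentHit(
                                    gene_id, f"CAZY_{int(rng.integers(1e6)):06d}",
                                    float(np.round(idents[k], 1)), float(np.round(bits[k], 1)),
                                )
                            )

            for meta in cluster_meta:
                truth.planted_cgcs.append(
                    {
                        "genome_id": gid,
                        "contig_id": contig,
                        "first_rank": meta["first_rank"],
                        "last_rank": meta["last_rank"],
                        "n_cazymes": meta["n_cazymes"],
                        "n_auxiliary": meta["n_auxiliary"],
                    }
                )

            genes_by_genome[gid] = genes
            hits_by_genome[gid] = hits
            metadata.append(
                GenomeMetadata(
                    gid,
                    group,
                    f"{group}_order",
                    f"{group}_family",
                    config.habitats[int(rng.integers(len(config.habitats)))],
                    float(np.round(rng.uniform(*config.completeness_range), 2)),
                    float(np.round(rng.uniform(*config.contamination_range), 2)),
                    sum(g.end - g.start for g in genes) + len(genes) * 100,
                    len(genes),
                )
            )

    bundle = Bundle(
        genes_by_genome, hits_by_genome, signalp_calls, metadata, alignment_hits,
        substrate_map, groups,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        bundle.write(outdir)
        truth.to_json(outdir / "ground_truth.json")
    return bundle, truth


def generate_null_dataset(
    config: SimulationConfig, outdir: str | Path | None = None
) -> tuple[Bundle, GroundTruth]:
    """Same generator with *no* group structure: every group draws from
    the first group's family-occurrence profile and no enrichments are
    planted. Group labels are retained for type-I-error testing."""
    import copy

    null_cfg = copy.deepcopy(config)
    null_cfg.planted_enrichments = []
    if null_cfg.group_family_probs:
        first = null_cfg.group_family_probs[sorted(null_cfg.group_family_probs)[0]]
        null_cfg.group_family_probs = {g: dict(first) for g in null_cfg.n_genomes}
    return generate_dataset(null_cfg, outdir=outdir)


# ---------------------------------------------------------------------------
# presets


def paper_flavoured_config(seed: int = 0) -> SimulationConfig:
    """Two contrasting groups of 30 genomes: a CAZyme-diverse group
    (~40 distinct GH families per genome, >2% GH+CBM coding frequency)
    versus a CAZyme-poor group (~8), with 2 planted clusters per
    genome — a toy-scale echo of a diverse-vs-specialist contrast."""
    gh_universe = [f"GH{i}" for i in range(1, 61)]
    extra = ["PL1", "PL9", "CE1", "CE4", "AA2", "AA10", "CBM2", "CBM6"]
    rich = {f: 0.65 for f in gh_universe}
    rich.update({f: 0.5 for f in extra})
    # planted-cluster genes add ~3-4 extra families per genome on top of
    # the background draw, so the background rate sits below the target
    poor = {f: 0.08 for f in gh_universe}
    poor.update({f: 0.25 for f in extra})
    return SimulationConfig(
        seed=seed,
        n_genomes={"diverse": 30, "specialist": 30},
        genes_per_genome=(1800, 2200),
        group_family_probs={"diverse": rich, "specialist": poor},
        planted_cgcs_per_genome=2,
        fraction_multimodular=0.10,
        fraction_unclassified=0.04,
    )


def null_calibration_config(seed: int = 0, n_per_group: int = 20) -> SimulationConfig:
    """Small homogeneous dataset for permutation-test calibration."""
    fams = [f"GH{i}" for i in (1, 2, 3, 5, 9, 10, 13, 18, 28, 29, 43, 95)] + ["PL1", "CE1"]
    probs = {f: 0.5 for f in fams}
    return SimulationConfig(
        seed=seed,
        n_genomes={"A": n_per_group, "B": n_per_group},
        genes_per_genome=(30, 45),
        group_family_probs={"A": probs, "B": probs},
        planted_cgcs_per_genome=0,
        isolate_background=False,
        emit_signalp=False,
        emit_outfmt6=False,
        fraction_unclassified=0.0,
        fraction_gt=0.0,
    )


def enrichment_config(seed: int = 0, n_background: int = 100) -> SimulationConfig:
    """Planted-enrichment dataset: one family at occupancy 0.9 in one
    group versus 0.1 in the other, over a homogeneous background."""
    background = [f"GH{i}" for i in range(1, n_background + 1)]
    probs = {f: 0.5 for f in background}
    return SimulationConfig(
        seed=seed,
        n_genomes={"A": 50, "B": 50},
        genes_per_genome=(140, 180),
        group_family_probs={"A": dict(probs), "B": dict(probs)},
        planted_enrichments=[("PL99", "A", 0.9, 0.1)],
        planted_cgcs_per_genome=0,
        isolate_background=False,
        emit_signalp=False,
        emit_outfmt6=False,
        fraction_unclassified=0.0,
        fraction_gt=0.0,
    )
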