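"""CAZyme gene cluster (CGC) detection on gene-order neighbourhoods.

A CGC is the bacterial analogue of a Bacteroidota polysaccharide
utilisation locus: CAZyme coding genes co-localised on a contig with
auxiliary genes (transcription factors, transporters). Detection here
follows a modified CGCFinder co-localisation rule:

* *signature* genes are classified CAZymes and auxiliary genes;
* two consecutive signature genes belong to the same chain iff at most
  ``max_gap`` (default 2) other genes lie between them;
* a maximal chain is a cluster iff it contains >=1 CAZyme and either
  >=1 auxiliary gene or >=2 CAZymes;
* the cluster span starts and ends on a signature gene.

Distances are measured in gene-order ranks, never base pairs; strand is
ignored. Unclassified CAZymes (no HMMER family) count as OTHER for
clustering but are tracked for the unassigned-within-CGC fraction.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .consensus import CazymeCall, STATUS_CLASSIFIED, STATUS_UNCLASSIFIED
from .io import GeneRecord

logger = logging.getLogger(__name__)

ROLE_CAZYME = "CAZYME"
ROLE_AUXILIARY = "AUXILIARY"
ROLE_OTHER = "OTHER"

# keyword signatures standing in for CGCFinder's TF/transporter databases
DEFAULT_AUXILIARY_PATTERNS: tuple[str, ...] = (
    r"transcription(?:al)?\s+(?:regulator|factor)",
    r"transporter",
    r"permease",
    r"porin",
    r"\btonb\b",
    r"\bmfs\b",
    r"\babc\b",
)

DEFAULT_HYPOTHETICAL_PATTERNS: tuple[str, ...] = (
    r"hypothetical protein",
    r"uncharacteri[sz]ed protein",
)


@dataclass(frozen=True)
class GeneRole:
    gene_id: str
    genome_id: str
    contig_id: str
    rank: int
    role: str
    is_hypothetical: bool = False
    is_unclassified_cazyme: bool = False


@dataclass(frozen=True)
class CGC:
    cgc_id: str
    genome_id: str
    contig_id: str
    first_rank: int
    last_rank: int
    n_cazymes: int
    n_auxiliary: int
    n_other: int
    signature_ranks: tuple[int, ...]

    @property
    def member_ranks(self) -> tuple[int, ...]:
        return tuple(range(self.first_rank, self.last_rank + 1))

    @property
    def n_genes(self) -> int:
        return self.last_rank - self.first_rank + 1


def _compile(patterns: Iterable[str]) -> list[re.Pattern]:
    return [re.compile(p, re.IGNORECASE) for p in patterns]


def assign_auxiliary(
    genes: Sequence[GeneRecord],
    calls: Mapping[str, CazymeCall],
    auxiliary_patterns: Sequence[str] = DEFAULT_AUXILIARY_PATTERNS,
    hypothetical_patterns: Sequence[str] = DEFAULT_HYPOTHETICAL_PATTERNS,
) -> list[GeneRole]:
    """Assign CAZYME / AUXILIARY / OTHER roles to genes.

    A classified CAZyme is CAZYME regardless of its product text; a
    non-CAZyme whose product matches a TF/transporter signature is
    AUXILIARY; everything else is OTHER.
    """
    if not auxiliary_patterns:
        logger.warning("empty auxiliary signature list: clusters will need >=2 CAZymes")
    aux_res = _compile(auxiliary_patterns)
    hyp_res = _compile(hypothetical_patterns)
    roles = []
    for g in genes:
        call = calls.get(g.gene_id)
        is_uncl = call is not None and call.status == STATUS_UNCLASSIFIED
        if call is not None and call.status == STATUS_CLASSIFIED:
            role = ROLE_CAZYME
        elif any(r.search(g.product) for r in aux_res):
            role = ROLE_AUXILIARY
        else:
            role = ROLE_OTHER
        roles.append(
            GeneRole(
                g.gene_id,
                g.genome_id,
                g.contig_id,
                g.rank,
                role,
                is_hypothetical=any(r.search(g.product) for r in hyp_res),
                is_unclassified_cazyme=is_uncl,
            )
        )
    return roles


def _composition_ok(n_caz: int, n_aux: int) -> bool:
    return n_caz >= 1 and (n_aux >= 1 or n_caz >= 2)


def detect_cgcs(
    genes: Sequence[GeneRole], max_gap: int = 2, cgc_prefix: str = "CGC"
) -> list[CGC]:
    """Greedy chaining of signature genes on one contig.

    ``genes`` must be the full gene list of a single contig sorted by
    rank. Consecutive signature genes with more than ``max_gap``
    intervening OTHER genes break the chain; maximal chains failing the
    composition rule are discarded.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if any(genes[i].rank >= genes[i + 1].rank for i in range(len(genes) - 1)):
        raise ValueError("genes must be sorted by rank with no duplicates")
    if len({g.contig_id for g in genes}) > 1:
        raise ValueError("detect_cgcs operates on one contig at a time")

    sig = [g for g in genes if g.role in (ROLE_CAZYME, ROLE_AUXILIARY)]
    clusters: list[CGC] = []
    chain: list[GeneRole] = []

    def flush(chain: list[GeneRole]) -> None:
        if not chain:
            return
        n_caz = sum(1 for g in chain if g.role == ROLE_CAZYME)
        n_aux = len(chain) - n_caz
        if not _composition_ok(n_caz, n_aux):
            return
        first, last = chain[0].rank, chain[-1].rank
        clusters.append(
            CGC(
                cgc_id=f"{cgc_prefix}{len(clusters)}",
                genome_id=chain[0].genome_id,
                contig_id=chain[0].contig_id,
                first_rank=first,
                last_rank=last,
                n_cazymes=n_caz,
                n_auxiliary=n_aux,
                n_other=(last - first + 1) - len(chain),
                signature_ranks=tuple(g.rank for g in chain),
            )
        )

    for g in sig:
        if chain and g.rank - chain[-1].rank - 1 > max_gap:
            flush(chain)
            chain = []
        chain.append(g)
    flush(chain)

    # renumber so ids are stable left-to-right
    return [
        CGC(
            f"{c.genome_id}|{c.contig_id}|{cgc_prefix}{i}",
            c.genome_id,
            c.contig_id,
            c.first_rank,
            c.last_rank,
            c.n_cazymes,
            c.n_auxiliary,
            c.n_other,
            c.signature_ranks,
        )
        for i, c in enumerate(clusters)
    ]


def detect_cgcs_genome(
    roles: Sequence[GeneRole], max_gap: int = 2
) -> list[CGC]:
    """Run :func:`detect_cgcs` contig by contig over one genome."""
    by_contig: dict[str, list[GeneRole]] = {}
    for r in roles:
        by_contig.setdefault(r.contig_id, []).append(r)
    out: list[CGC] = []
    for contig_id in sorted(by_contig):
        contig_roles = sorted(by_contig[contig_id], key=lambda r: r.rank)
        out.extend(detect_cgcs(contig_roles, max_gap=max_gap))
    return out


def cgc_fractions(
    roles: Sequence[GeneRole],
    cgcs: Sequence[CGC],
    calls: Mapping[str, CazymeCall],
) -> dict[str, float | None]:
    """Per-genome co-localisation fractions.

    * ``frac_cazymes_in_cgc`` — classified CAZyme genes inside any
      cluster span / all classified CAZyme genes;
    * ``frac_gh_in_cgc`` — same restricted to genes carrying >=1 GH
      module;
    * ``frac_hypothetical_in_cgc`` — hypothetical-product genes inside
      spans / all genes inside spans;
    * ``frac_unassigned_in_cgc`` — genes inside spans that are neither
      CAZyme nor auxiliary / all genes inside spans.

    Empty denominators give ``None``.
    """
    in_span: set[tuple[str, int]] = set()
    for c in cgcs:
        for r in c.member_ranks:
            in_span.add((c.contig_id, r))

    def inside(g: GeneRole) -> bool:
        return (g.contig_id, g.rank) in in_span

    caz = [g for g in roles if g.role == ROLE_CAZYME]
    gh = [
        g
        for g in caz
        if any(m.cazy_class == "GH" for m in calls[g.gene_id].modules)
    ]
    span_genes = [g for g in roles if inside(g)]

    def frac(num: int, den: int) -> float | None:
        return None if den == 0 else num / den

    return {
        "frac_cazymes_in_cgc": frac(sum(inside(g) for g in caz), len(caz)),
        "frac_gh_in_cgc": frac(sum(inside(g) for g in gh), len(gh)),
        "frac_hypothetical_in_cgc": frac(
            sum(g.is_hypothetical for g in span_genes), len(span_genes)
        ),
        "frac_unassigned_in_cgc": frac(
            sum(g.role == ROLE_OTHER for g in span_genes), len(span_genes)
        ),
    }


def write_cgc_tsv(
    cgcs: Sequence[CGC], roles_by_genome: Mapping[str, Sequence[GeneRole]], path: str | Path
) -> None:
    rank_to_gene = {
        (r.genome_id, r.contig_id, r.rank): r.gene_id
        for roles in roles_by_genome.values()
        for r in roles
    }
    with open(path, "w") as fh:
        fh.write(
            "genome_id\tcontig_id\tcgc_id\tfirst_gene\tlast_gene\t"
            "n_cazymes\tn_auxiliary\tn_other\tmember_gene_ids\n"
        )
        for c in cgcs:
            members = [
                rank_to_gene[(c.genome_id, c.contig_id, r)] for r in c.member_ranks
            ]
            fh.write(
                f"{c.genome_id}\t{c.contig_id}\t{c.cgc_id}\t{members[0]}\t{members[-1]}\t"
                f"{c.n_cazymes}\t{c.n_auxiliary}\t{c.n_other}\t{';'.join(members)}\n"
            )


def write_cgc_bed(
    cgcs: Sequence[CGC], genes_by_genome: Mapping[str, Sequence[GeneRecord]], path: str | Path
) -> None:
    """BED (0-based half-open) spans of clusters in genome coordinates."""
    coord = {
        (g.genome_id, g.contig_id, g.rank): (g.start, g.end)
        for genes in genes_by_genome.values()
        for g in genes
    }
    with open(path, "w") as fh:
        for c in cgcs:
            start = coord[(c.genome_id, c.contig_id, c.first_rank)][0]
            end = coord[(c.genome_id, c.contig_id, c.last_rank)][1]
            fh.write(f"{c.contig_id}\t{start - 1}\t{end}\t{c.cgc_id}\n")
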