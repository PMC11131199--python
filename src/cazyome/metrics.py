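"""Per-genome CAZyome summaries: diversity, coding frequency, quality
filtering, rarity, multi-modularity and GH–CBM diversity correlation."""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .consensus import CazymeCall, STATUS_CLASSIFIED, unclassified_ratio
from .io import GenomeMetadata

OTHER_CLASS = "other class"


def family_diversity(
    calls: Iterable[CazymeCall], cazy_class: str, granularity: str = "family"
) -> int:
    """Number of distinct families (or subfamily-distinct labels) of one
    CAZyme class among a genome's classified calls."""
    labels: set[str] = set()
    for c in calls:
        if c.status != STATUS_CLASSIFIED:
            continue
        for m in c.modules:
            if m.cazy_class == cazy_class:
                labels.add(m.label if granularity == "subfamily" else m.family_label)
    return len(labels)


def quality_filter(
    metadata: Sequence[GenomeMetadata],
    calls_by_genome: Mapping[str, Mapping[str, CazymeCall]],
    min_completeness: float = 75.0,
    max_contamination: float = 10.0,
    min_cazymes: int = 10,
) -> tuple[list[str], pd.DataFrame]:
    """Keep genomes with completeness strictly above ``min_completeness``
    %, contamination strictly below ``max_contamination`` % and at least
    ``min_cazymes`` classified CAZyme genes.

    Returns (retained genome ids, exclusion log naming the first failed
    criterion per excluded genome). A genome present in ``calls`` but
    absent from ``metadata`` is a hard error.
    """
    meta_ids = {m.genome_id for m in metadata}
    missing = set(calls_by_genome) - meta_ids
    if missing:
        raise KeyError(f"genomes with calls but no metadata: {sorted(missing)}")

    retained, log_rows = [], []
    for m in metadata:
        n_caz = sum(
            1
            for c in calls_by_genome.get(m.genome_id, {}).values()
            if c.status == STATUS_CLASSIFIED
        )
        if not m.completeness > min_completeness:
            reason = f"completeness {m.completeness} <= {min_completeness}"
        elif not m.contamination < max_contamination:
            reason = f"contamination {m.contamination} >= {max_contamination}"
        elif n_caz < min_cazymes:
            reason = f"cazyme_count {n_caz} < {min_cazymes}"
        else:
            retained.append(m.genome_id)
            continue
        log_rows.append({"genome_id": m.genome_id, "reason": reason})
    return retained, pd.DataFrame(log_rows, columns=["genome_id", "reason"])


def group_small_classes(
    metadata: Sequence[GenomeMetadata], min_n: int = 10
) -> dict[str, str]:
    """Relabel taxonomy classes with fewer than ``min_n`` genomes as
    "other class". Returns genome_id -> (possibly relabelled) class."""
    counts = Counter(m.tax_class for m in metadata)
    return {
        m.genome_id: m.tax_class if counts[m.tax_class] >= min_n else OTHER_CLASS
        for m in metadata
    }


def rare_families(presence: pd.DataFrame, threshold: float = 0.05) -> list[str]:
    """Families present in strictly fewer than ``threshold`` of genomes.

    ``presence`` is a genomes x families 0/1 matrix.
    """
    if presence.empty:
        raise ValueError("empty presence matrix")
    occupancy = (presence > 0).mean(axis=0)
    return sorted(occupancy.index[occupancy < threshold])


def multimodularity(calls: Iterable[CazymeCall]) -> dict:
    """Multi-modular gene count, module-count distribution and number of
    unique (order-insensitive) module combinations with >=2 modules."""
    dist: Counter[int] = Counter()
    combos: set[tuple] = set()
    n_multi = 0
    for c in calls:
        if c.status != STATUS_CLASSIFIED:
            continue
        dist[c.n_modules] += 1
        if c.n_modules >= 2:
            n_multi += 1
            combos.add(tuple(sorted(Counter(m.label for m in c.modules).items())))
    return {
        "n_multimodular": n_multi,
        "module_count_distribution": dict(sorted(dist.items())),
        "unique_combinations": len(combos),
    }


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho at small n."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    n = len(rx)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def gh_cbm_correlation(
    gh_diversity: Sequence[float], cbm_diversity: Sequence[float]
) -> tuple[float | None, float | None]:
    """Spearman rank correlation between per-genome GH and CBM family
    diversities, with average-rank tie handling.

    Two-sided p from the t approximation for n >= 10 and from the exact
    permutation distribution for n < 10, where the approximation is
    unreliable. Zero variance in either vector gives (None, None).
    """
    x = np.asarray(gh_diversity, dtype=float)
    y = np.asarray(cbm_diversity, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("need at least 3 genomes")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None, None
    rho, p = sps.spearmanr(x, y)
    if len(x) < 10:
        p = _exact_spearman_p(x, y, rho)
    return float(rho), float(p)


@dataclass(frozen=True)
class GenomeCazyomeSummary:
    genome_id: str
    diversity_family: dict[str, int]  # per class: GH/PL/CE/AA/CBM
    diversity_subfamily: dict[str, int]
    n_cazyme_genes: int
    coding_frequency: float  # percent
    gh_cbm_frequency: float  # percent
    trend: str  # T1 (> 2%) or T2 (<= 2%)
    n_multimodular: int
    n_unique_module_combinations: int
    unclassified_ratio: float | None


def summarise_genome(
    genome_id: str,
    calls: Mapping[str, CazymeCall],
    n_proteins: int,
    trend_threshold: float = 2.0,
) -> GenomeCazyomeSummary:
    """Build the per-genome summary. ``n_proteins`` is the metadata
    protein count (prodigal), not the number of genes seen here.

    Coding frequency counts classified CAZyme genes. The T1/T2 trend is
    split on GH+CBM coding frequency: strictly above the threshold is
    T1, the boundary goes to T2.
    """
    call_list = list(calls.values())
    classified = [c for c in call_list if c.status == STATUS_CLASSIFIED]
    n_caz = len(classified)
    n_gh_cbm = sum(
        1
        for c in classified
        if any(m.cazy_class in ("GH", "CBM") for m in c.modules)
    )
    coding_freq = 100.0 * n_caz / n_proteins
    gh_cbm_freq = 100.0 * n_gh_cbm / n_proteins
    mm = multimodularity(call_list)
    return GenomeCazyomeSummary(
        genome_id=genome_id,
        diversity_family={
            cz: family_diversity(call_list, cz, "family") for cz in ("GH", "PL", "CE", "AA", "CBM")
        },
        diversity_subfamily={
            cz: family_diversity(call_list, cz, "subfamily")
            for cz in ("GH", "PL", "CE", "AA", "CBM")
        },
        n_cazyme_genes=n_caz,
        coding_frequency=coding_freq,
        gh_cbm_frequency=gh_cbm_freq,
        trend="T1" if gh_cbm_freq > trend_threshold else "T2",
        n_multimodular=mm["n_multimodular"],
        n_unique_module_combinations=mm["unique_combinations"],
        unclassified_ratio=unclassified_ratio(call_list),
    )


def summaries_to_frame(summaries: Sequence[GenomeCazyomeSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "genome_id": s.genome_id,
            "n_cazyme_genes": s.n_cazyme_genes,
            "coding_frequency": s.coding_frequency,
            "gh_cbm_frequency": s.gh_cbm_frequency,
            "trend": s.trend,
            "n_multimodular": s.n_multimodular,
            "n_unique_module_combinations": s.n_unique_module_combinations,
            "unclassified_ratio": s.unclassified_ratio,
        }
        for cz, v in s.diversity_family.items():
            row[f"div_family_{cz}"] = v
        for cz, v in s.diversity_subfamily.items():
            row[f"div_subfamily_{cz}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def taxon_aggregate(
    summary_frame: pd.DataFrame, groups: Mapping[str, str]
) -> pd.DataFrame:
    """Mean +/- sd of each numeric metric per taxon group ("47 +/- 19"
    style reporting). ``groups`` maps genome_id -> group label."""
    df = summary_frame.copy()
    df["group"] = df["genome_id"].map(groups)
    numeric = df.select_dtypes(include=[np.number]).columns
    agg = df.groupby("group")[list(numeric)].agg(["mean", "std", "count"])
    agg.columns = ["_".join(col) for col in agg.columns]
    return agg.reset_index()
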