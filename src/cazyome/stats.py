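"""Comparative statistics on genomes x CAZyme-family profiles.

The comparative layer works on a presence/absence (or count) matrix of
CAZyme families per genome: Jaccard distances, principal coordinate
analysis, PERMANOVA and ANOSIM group tests, per-family Kruskal–Wallis
enrichment with Benjamini–Hochberg FDR control, and an LEfSe-style
linear-discriminant effect size on library-size-normalised profiles.

PERMANOVA and ANOSIM are delegated to scikit-bio (seeded). PCoA is
computed here by Gower double-centering so that the full eigenvalue
spectrum — including negative eigenvalues of non-Euclidean distance
matrices — is reported rather than truncated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats as sps
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as _skbio_anosim
from skbio.stats.distance import permanova as _skbio_permanova

from .consensus import CazymeCall, STATUS_CLASSIFIED


# ---------------------------------------------------------------------------
# profile construction


def profile_matrix(
    calls_by_genome: Mapping[str, Mapping[str, CazymeCall]],
    granularity: str = "family",
    cazy_classes: Sequence[str] | None = None,
    counts: bool = False,
) -> pd.DataFrame:
    """Genomes x family-labels matrix from consensus calls.

    Values are presence (0/1) by default, or module counts with
    ``counts=True``. ``cazy_classes`` restricts the columns (e.g.
    ``("GH",)`` for a GH-only ordination).
    """
    rows: dict[str, dict[str, int]] = {}
    for genome_id, calls in calls_by_genome.items():
        row: dict[str, int] = {}
        for c in calls.values():
            if c.status != STATUS_CLASSIFIED:
                continue
            for m in c.modules:
                if cazy_classes is not None and m.cazy_class not in cazy_classes:
                    continue
                label = m.label if granularity == "subfamily" else m.family_label
                row[label] = row.get(label, 0) + 1
        rows[genome_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df = df.reindex(index=list(rows), fill_value=0).fillna(0).astype(int)
    df = df.reindex(sorted(df.columns), axis=1)
    df.index.name = "genome_id"
    if not counts:
        df = (df > 0).astype(int)
    return df


# ---------------------------------------------------------------------------
# distances and ordination


def jaccard_matrix(presence: pd.DataFrame) -> DistanceMatrix:
    """Jaccard distance 1 - |A∩B| / |A∪B| over family sets.

    Two genomes with empty family sets get distance 0 (with a warning):
    identical emptiness is treated as identity.
    """
    x = (presence.to_numpy() > 0).astype(float)
    inter = x @ x.T
    sizes = x.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    if np.any(union == 0):
        warnings.warn("genome pair with two empty family sets: distance set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.where(union > 0, inter / np.where(union == 0, 1, union), 1.0)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)  # enforce exact symmetry
    return DistanceMatrix(d, ids=list(presence.index))


@dataclass(frozen=True)
class OrdinationResult:
    coordinates: pd.DataFrame  # genomes x axes (positive-eigenvalue axes)
    eigenvalues: np.ndarray  # full spectrum, sorted descending
    proportion_explained: np.ndarray  # over positive eigenvalues


def pcoa(distance_matrix: DistanceMatrix | np.ndarray, n_axes: int | None = None,
         ids: Sequence[str] | None = None) -> OrdinationResult:
    """Principal coordinate analysis by Gower double-centering.

    Coordinates are eigenvectors scaled by sqrt of their (positive)
    eigenvalues; negative eigenvalues are retained in ``eigenvalues``
    so non-Euclidean input is visible, but contribute no axes.
    """
    if isinstance(distance_matrix, DistanceMatrix):
        d = distance_matrix.data
        ids = list(distance_matrix.ids)
    else:
        d = np.asarray(distance_matrix, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if ids is None:
            ids = [str(i) for i in range(d.shape[0])]
    n = d.shape[0]
    a = -0.5 * d**2
    centre = np.eye(n) - np.ones((n, n)) / n
    b = centre @ a @ centre
    eigvals, eigvecs = sla.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-10
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    if n_axes is not None:
        coords = coords[:, :n_axes]
    total_pos = eigvals[pos].sum()
    prop = eigvals[pos] / total_pos if total_pos > 0 else eigvals[pos]
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(ids), columns=cols),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# group tests


@dataclass(frozen=True)
class GroupTestResult:
    method: str
    statistic: float
    p_value: float
    n_permutations: int


def _check_groups(dm: DistanceMatrix, groups: Sequence[str]) -> None:
    if len(groups) != dm.shape[0]:
        raise ValueError("grouping length must match distance matrix size")
    counts = pd.Series(list(groups)).value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = counts.index[counts < 2].tolist()
        raise ValueError(f"groups with fewer than 2 members: {small}")


def permanova(
    dm: DistanceMatrix, groups: Sequence[str], n_permutations: int = 999, seed: int = 0
) -> GroupTestResult:
    """Permutational MANOVA pseudo-F with label-permutation p-value
    (p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations))."""
    _check_groups(dm, groups)
    res = _skbio_permanova(dm, list(groups), permutations=n_permutations, seed=seed)
    return GroupTestResult("PERMANOVA", float(res["test statistic"]), float(res["p-value"]),
                           n_permutations)


def anosim(
    dm: DistanceMatrix, groups: Sequence[str], n_permutations: int = 999, seed: int = 0
) -> GroupTestResult:
    """ANOSIM R (mean between-group minus within-group distance ranks,
    scaled by M/2, M = n(n-1)/2) with permutation p-value."""
    _check_groups(dm, groups)
    res = _skbio_anosim(dm, list(groups), permutations=n_permutations, seed=seed)
    return GroupTestResult("ANOSIM", float(res["test statistic"]), float(res["p-value"]),
                           n_permutations)


# ---------------------------------------------------------------------------
# enrichment


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    adjusted p_(i) = min_{j >= i} ( p_(j) * m / j ), clipped at 1, on
    the ascending-sorted p-values; NaNs pass through untouched and do
    not count towards m.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    back = np.empty(m)
    back[order] = adj
    out[ok] = back
    return out


def kw_enrichment(
    profile: pd.DataFrame,
    groups: Mapping[str, str] | Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-family Kruskal–Wallis test across groups with BH adjustment.

    ``profile`` is genomes x families (presence or counts). Families
    constant across all genomes are skipped (p = NaN, ``skipped``
    True). Returns one row per family with per-group means, the
    tie-corrected H statistic, raw and adjusted p, the group with the
    highest mean, and a ``significant`` flag at ``alpha`` on the
    adjusted p.
    """
    if isinstance(groups, Mapping):
        labels = np.array([groups[g] for g in profile.index])
    else:
        labels = np.asarray(list(groups))
        if len(labels) != len(profile):
            raise ValueError("grouping length must match profile rows")
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    masks = {u: labels == u for u in uniq}

    rows = []
    x = profile.to_numpy(dtype=float)
    for j, fam in enumerate(profile.columns):
        col = x[:, j]
        means = {u: col[masks[u]].mean() for u in uniq}
        if np.ptp(col) == 0:
            rows.append(
                {"family_label": fam, **{f"mean_{u}": means[u] for u in uniq},
                 "kw_statistic": np.nan, "p_value": np.nan, "skipped": True}
            )
            continue
        h, p = sps.kruskal(*(col[masks[u]] for u in uniq))
        rows.append(
            {"family_label": fam, **{f"mean_{u}": means[u] for u in uniq},
             "kw_statistic": h, "p_value": p, "skipped": False}
        )
    df = pd.DataFrame(rows)
    df["p_adjusted"] = bh_adjust(df["p_value"].to_numpy())
    df["enriched_group"] = [
        max(uniq, key=lambda u: r[f"mean_{u}"]) for _, r in df.iterrows()
    ]
    df["significant"] = df["p_adjusted"] < alpha
    return df


def lda_effect_size(
    profile: pd.DataFrame,
    groups: Mapping[str, str] | Sequence[str],
    kw_alpha: float = 0.05,
    n_bootstrap: int = 30,
    subsample: float = 2 / 3,
    seed: int = 0,
    scale: float = 1e6,
) -> pd.DataFrame:
    """LEfSe-style log10 linear-discriminant effect sizes.

    Profiles are normalised per genome to a constant library size
    (``scale``, per-million by default, matching LEfSe's convention —
    this is what puts scores on the familiar 0–6 log10 scale). Families
    passing a Kruskal–Wallis screen at raw p < ``kw_alpha`` get an
    effect size: the absolute between-class mean difference of the
    normalised abundance along the (one-dimensional, per-family)
    discriminant, averaged over bootstrap rounds that subsample each
    class. Reported as log10; multi-group inputs use the maximum
    pairwise class-mean difference.
    """
    if isinstance(groups, Mapping):
        labels = np.array([groups[g] for g in profile.index])
    else:
        labels = np.asarray(list(groups))
    uniq = sorted(set(labels))
    rng = np.random.default_rng(seed)

    x = profile.to_numpy(dtype=float)
    row_sums = x.sum(axis=1, keepdims=True)
    row_sums[row_sums == 0] = 1.0
    xn = x / row_sums * scale

    # raw-p KW screen (LEfSe screens before sizing effects)
    keep = []
    for j in range(x.shape[1]):
        col = x[:, j]
        if np.ptp(col) == 0:
            continue
        try:
            _, p = sps.kruskal(*(col[labels == u] for u in uniq))
        except ValueError:
            continue
        if p < kw_alpha:
            keep.append(j)

    idx_by_group = {u: np.flatnonzero(labels == u) for u in uniq}
    rows = []
    for j in keep:
        col = xn[:, j]
        effects = []
        degenerate = False
        for _ in range(n_bootstrap):
            means = {}
            for u in uniq:
                idx = idx_by_group[u]
                take = max(2, int(round(subsample * len(idx))))
                sub = rng.choice(idx, size=min(take, len(idx)), replace=False)
                means[u] = col[sub].mean()
            pair_diffs = [
                abs(means[a] - means[b])
                for k, a in enumerate(uniq)
                for b in uniq[k + 1:]
            ]
            effects.append(max(pair_diffs))
        effect = float(np.mean(effects))
        if effect <= 0:
            degenerate = True
            effect = np.finfo(float).tiny
        score = float(np.log10(max(effect, 1.0)))
        means_all = {u: col[idx_by_group[u]].mean() for u in uniq}
        rows.append(
            {
                "family_label": profile.columns[j],
                "effect_size": effect,
                "lda_score": score,
                "enriched_group": max(uniq, key=lambda u: means_all[u]),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(
        rows, columns=["family_label", "effect_size", "lda_score", "enriched_group", "degenerate"]
    )
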