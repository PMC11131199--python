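"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results from first principles (window
enumeration, step-up definition, rank formulas) and share no code with
the implementations they check.
"""

from __future__ import annotations

import numpy as np

from cazyome.cgc import ROLE_AUXILIARY, ROLE_CAZYME, GeneRole


def make_contig(roles: list[str], genome_id: str = "G", contig_id: str = "c") -> list[GeneRole]:
    """Build a GeneRole contig from a role-string list like ['CAZ','OTH',...]."""
    full = {"CAZ": ROLE_CAZYME, "AUX": ROLE_AUXILIARY, "OTH": "OTHER"}
    return [
        GeneRole(f"{genome_id}_{i:04d}", genome_id, contig_id, i, full[r])
        for i, r in enumerate(roles)
    ]


def brute_force_cgcs(roles: list[str], max_gap: int) -> list[tuple[int, int]]:
    """Enumerate every contiguous window, keep maximal valid ones.

    A window [i, j] is valid iff it starts and ends on signature genes,
    no two consecutive signature genes inside are separated by more
    than ``max_gap`` other genes, and it contains >=1 CAZyme plus
    either an auxiliary gene or a second CAZyme. Returns (first, last)
    rank spans sorted by position.
    """
    n = len(roles)
    sig = [i for i, r in enumerate(roles) if r in ("CAZ", "AUX")]
    sig_set = set(sig)

    def valid(i: int, j: int) -> bool:
        if i not in sig_set or j not in sig_set:
            return False
        inner = [k for k in sig if i <= k <= j]
        for a, b in zip(inner, inner[1:]):
            if b - a - 1 > max_gap:
                return False
        n_caz = sum(1 for k in inner if roles[k] == "CAZ")
        n_aux = len(inner) - n_caz
        return n_caz >= 1 and (n_aux >= 1 or n_caz >= 2)

    windows = [(i, j) for i in range(n) for j in range(i, n) if valid(i, j)]
    maximal = [
        w
        for w in windows
        if not any(
            v != w and v[0] <= w[0] and w[1] <= v[1] for v in windows
        )
    ]
    return sorted(maximal)


def brute_force_bh(p_values: np.ndarray) -> np.ndarray:
    """Step-up BH by explicit double loop over sorted ranks."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    out = np.empty(m)
    for pos in range(m):  # pos = rank-1 in sorted order
        candidates = [p[order[j]] * m / (j + 1) for j in range(pos, m)]
        out[order[pos]] = min(1.0, min(candidates))
    return out


def spearman_rho_from_ranks(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of average ranks — the definitional route."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])
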