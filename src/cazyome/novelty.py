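"""Novelty scoring of CAZymes from best-hit identity tables.

Each classified CAZyme is searched against a reference CAZyme sequence
set (DIAMOND/BLAST, tabular output); the amino-acid identity of the
best hit measures how close the protein is to anything previously
characterised. Proteins under a low-identity threshold (default 30%)
are flagged as putatively novel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AlignmentHit

DEFAULT_LOW_IDENTITY = 30.0


@dataclass(frozen=True)
class NoveltyRecord:
    gene_id: str
    best_hit_subject: str | None
    best_identity: float | None  # percent; None when no hits
    family_label: str
    low_identity_flag: bool


def best_hits(
    hits: Iterable[AlignmentHit],
    queries: Sequence[str] | None = None,
    family_by_gene: Mapping[str, str] | None = None,
    low_identity: float = DEFAULT_LOW_IDENTITY,
) -> list[NoveltyRecord]:
    """Pick each query's best hit: maximal bitscore, ties broken by
    higher identity, then lexicographically smallest subject id.

    ``queries`` optionally fixes the output universe (queries without
    hits get a record with missing identity and flag False); otherwise
    queries are whatever appears in ``hits``. Selection is independent
    of input row order.
    """
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        cur = best.get(h.query)
        if cur is None:
            best[h.query] = h
            continue
        key_new = (h.bitscore, h.identity, [-ord(c) for c in h.subject])
        key_cur = (cur.bitscore, cur.identity, [-ord(c) for c in cur.subject])
        if key_new > key_cur:
            best[h.query] = h
    if queries is None:
        queries = sorted(best)
    fam = family_by_gene or {}
    out = []
    for q in queries:
        h = best.get(q)
        if h is None:
            out.append(NoveltyRecord(q, None, None, fam.get(q, ""), False))
        else:
            out.append(
                NoveltyRecord(
                    q, h.subject, h.identity, fam.get(q, ""), h.identity < low_identity
                )
            )
    return out


def novelty_summary(
    records: Sequence[NoveltyRecord],
    grouping: Mapping[str, str] | None = None,
    low_identity: float = DEFAULT_LOW_IDENTITY,
) -> pd.DataFrame:
    """Median / IQR / fraction-below-threshold of best-hit identities,
    per group (``grouping``: gene_id -> group; default: per family
    label). Genes without hits are excluded; empty groups are skipped.
    """
    rows: dict[str, list[float]] = {}
    for r in records:
        if r.best_identity is None:
            continue
        key = grouping.get(r.gene_id, "") if grouping is not None else r.family_label
        rows.setdefault(key, []).append(r.best_identity)
    out = []
    for key in sorted(rows):
        vals = np.array(rows[key])
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        out.append(
            {
                "group": key,
                "n": len(vals),
                "median_identity": med,
                "iqr": q3 - q1,
                "fraction_low_identity": float((vals < low_identity).mean()),
            }
        )
    return pd.DataFrame(
        out, columns=["group", "n", "median_identity", "iqr", "fraction_low_identity"]
    )
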