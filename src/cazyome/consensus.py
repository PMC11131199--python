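"""Consensus CAZyme calling from three-tool annotations.

dbCAN-style annotation runs three tools per gene (HMMER against family
HMMs, Hotpep peptide matching, DIAMOND sequence search). The consensus
rule used throughout this package is:

* a gene is a **classified** CAZyme iff HMMER hit it — the HMMER labels
  define its module list, one module per label, with multiple labels
  treated as separate functional domains/modules of one protein;
* a gene hit only by DIAMOND and/or Hotpep is an **unclassified**
  CAZyme: there is CAZyme evidence but no family assignment;
* everything else has status **none**.

Glycosyltransferases (GT) build rather than break glycosidic bonds and
are excluded from degradation analyses by default: GT modules are
removed *before* the status is decided, and a gene left with no non-GT
evidence gets status ``none``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

CAZY_CLASSES = ("GH", "GT", "PL", "CE", "AA", "CBM")

_LABEL_RE = re.compile(r"^(GH|GT|PL|CE|AA|CBM)(\d+)(?:_(\d+))?$")

TOOLS = ("HMMER", "Hotpep", "DIAMOND")

STATUS_CLASSIFIED = "classified"
STATUS_UNCLASSIFIED = "unclassified"
STATUS_NONE = "none"


class LabelError(ValueError):
    """A CAZyme family label does not parse under the label grammar."""


@dataclass(frozen=True, order=True)
class CazymeModule:
    """One CAZyme module: class + family + optional subfamily.

    ``GH5_2`` is family 5 of the glycoside hydrolases, subfamily 2;
    ``CBM50`` is carbohydrate-binding module family 50 (no subfamily).
    """

    cazy_class: str
    family: int
    subfamily: int | None = None

    def __post_init__(self) -> None:
        if self.cazy_class not in CAZY_CLASSES:
            raise LabelError(f"unknown CAZyme class {self.cazy_class!r}")
        if self.family <= 0:
            raise LabelError(f"family number must be positive, got {self.family}")

    @classmethod
    def parse(cls, label: str) -> "CazymeModule":
        m = _LABEL_RE.match(label.strip())
        if m is None:
            raise LabelError(f"invalid CAZyme family label {label!r}")
        cz, fam, sub = m.group(1), int(m.group(2)), m.group(3)
        return cls(cz, fam, int(sub) if sub is not None else None)

    @property
    def label(self) -> str:
        base = f"{self.cazy_class}{self.family}"
        return base if self.subfamily is None else f"{base}_{self.subfamily}"

    @property
    def family_label(self) -> str:
        """Label at family granularity (subfamily dropped): GH5_2 -> GH5."""
        return f"{self.cazy_class}{self.family}"


def parse_labels(labels: Iterable[str]) -> tuple[CazymeModule, ...]:
    return tuple(CazymeModule.parse(l) for l in labels)


@dataclass(frozen=True)
class ToolHits:
    """Per-gene family labels reported by each of the three tools."""

    gene_id: str
    hmmer: tuple[str, ...] = ()
    hotpep: tuple[str, ...] = ()
    diamond: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        # validate eagerly so downstream code never sees a bad label
        for tool_labels in (self.hmmer, self.hotpep, self.diamond):
            for lab in tool_labels:
                CazymeModule.parse(lab)


@dataclass(frozen=True)
class CazymeCall:
    """Consensus call for one gene."""

    gene_id: str
    status: str
    modules: tuple[CazymeModule, ...] = ()
    supporting_tools: frozenset = field(default_factory=frozenset)

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    @property
    def is_classified(self) -> bool:
        return self.status == STATUS_CLASSIFIED

    def module_labels(self, granularity: str = "subfamily") -> tuple[str, ...]:
        if granularity == "subfamily":
            return tuple(m.label for m in self.modules)
        if granularity == "family":
            return tuple(m.family_label for m in self.modules)
        raise ValueError(f"unknown granularity {granularity!r}")


def call_consensus(hits: ToolHits, exclude_gt: bool = True) -> CazymeCall:
    """Resolve one gene's three-tool hits into a consensus call.

    HMMER defines modules; DIAMOND/Hotpep without HMMER means
    "unclassified"; GT modules are stripped first when ``exclude_gt``.
    A gene whose HMMER hits were all GT keeps status ``none`` even when
    other tools carry non-GT evidence: HMMER presence decides the
    classified/unclassified split before exclusion results are known.
    """
    hmmer = parse_labels(hits.hmmer)
    hotpep = parse_labels(hits.hotpep)
    diamond = parse_labels(hits.diamond)

    if exclude_gt:
        keep = lambda mods: tuple(m for m in mods if m.cazy_class != "GT")
        hmmer_kept, hotpep_kept, diamond_kept = keep(hmmer), keep(hotpep), keep(diamond)
    else:
        hmmer_kept, hotpep_kept, diamond_kept = hmmer, hotpep, diamond

    if hmmer:  # HMMER hit the gene (before exclusion)
        if hmmer_kept:
            tools = {"HMMER"}
            if hotpep_kept:
                tools.add("Hotpep")
            if diamond_kept:
                tools.add("DIAMOND")
            return CazymeCall(hits.gene_id, STATUS_CLASSIFIED, hmmer_kept, frozenset(tools))
        return CazymeCall(hits.gene_id, STATUS_NONE)

    tools = set()
    if hotpep_kept:
        tools.add("Hotpep")
    if diamond_kept:
        tools.add("DIAMOND")
    if tools:
        return CazymeCall(hits.gene_id, STATUS_UNCLASSIFIED, (), frozenset(tools))
    return CazymeCall(hits.gene_id, STATUS_NONE)


def call_genome(hits: Iterable[ToolHits], exclude_gt: bool = True) -> dict[str, CazymeCall]:
    """Consensus-call every gene in an overview table, keyed by gene_id."""
    return {h.gene_id: call_consensus(h, exclude_gt=exclude_gt) for h in hits}


def unclassified_ratio(calls: Iterable[CazymeCall]) -> float | None:
    """unclassified / (classified + unclassified); None if no CAZymes."""
    n_c = n_u = 0
    for c in calls:
        if c.status == STATUS_CLASSIFIED:
            n_c += 1
        elif c.status == STATUS_UNCLASSIFIED:
            n_u += 1
    total = n_c + n_u
    return None if total == 0 else n_u / total


def consensus_truth_table(exclude_gt: bool = True) -> pd.DataFrame:
    """Exhaustive table of the 8 tool-presence combinations and the status
    each produces under :func:`call_consensus` (with a non-GT label)."""
    rows = []
    for h in (0, 1):
        for p in (0, 1):
            for d in (0, 1):
                hits = ToolHits(
                    "g",
                    hmmer=("GH13",) if h else (),
                    hotpep=("GH13",) if p else (),
                    diamond=("GH13",) if d else (),
                )
                call = call_consensus(hits, exclude_gt=exclude_gt)
                rows.append({"HMMER": h, "Hotpep": p, "DIAMOND": d, "status": call.status})
    return pd.DataFrame(rows)


def calls_to_frame(calls_by_genome: Mapping[str, Mapping[str, CazymeCall]]) -> pd.DataFrame:
    """Flatten per-genome calls into the per-gene calls table
    (genome_id, gene_id, status, modules, n_modules, tools)."""
    rows = []
    for genome_id, calls in calls_by_genome.items():
        for gene_id, c in calls.items():
            rows.append(
                {
                    "genome_id": genome_id,
                    "gene_id": gene_id,
                    "status": c.status,
                    "modules": ";".join(m.label for m in c.modules),
                    "n_modules": c.n_modules,
                    "tools": ";".join(sorted(c.supporting_tools)),
                }
            )
    return pd.DataFrame(
        rows, columns=["genome_id", "gene_id", "status", "modules", "n_modules", "tools"]
    )
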