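"""Substrate and biomass categorisation of GH/PL modules, and
secretion profiling from signal-peptide predictions.

Glycoside hydrolase (GH) and polysaccharide lyase (PL) families are
mapped to the biomass they chiefly degrade (algal, plant, algal/plant,
other) and a finer substrate category (algal polysaccharides, glucans,
oligosaccharides, lignocellulose, NAG-based, pectin, other). The map is
a user-supplied table; the shipped default covers a small set of
well-characterised families and is meant for demonstrations and tests,
not as an authoritative functional annotation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .consensus import CazymeCall, CazymeModule, STATUS_CLASSIFIED
from .io import FormatError, SignalPeptideCall

BIOMASS_CATEGORIES = ("algal", "plant", "algal/plant", "other")
SUBSTRATE_CATEGORIES = (
    "algal polysaccharides",
    "glucans",
    "oligosaccharides",
    "lignocellulose",
    "NAG-based",
    "pectin",
    "other",
)
UNASSIGNED = "unassigned"

# Minimal demonstration map: family -> (biomass, substrate).
_DEFAULT_ENTRIES: dict[str, tuple[str, str]] = {
    # algal polysaccharide degraders (agar, carrageenan, fucoidan, ulvan)
    "GH29": ("algal", "algal polysaccharides"),
    "GH95": ("algal", "algal polysaccharides"),
    "GH107": ("algal", "algal polysaccharides"),
    "GH118": ("algal", "algal polysaccharides"),
    "GH139": ("algal", "algal polysaccharides"),
    "GH141": ("algal", "algal polysaccharides"),
    "GH151": ("algal", "algal polysaccharides"),
    "GH168": ("algal", "algal polysaccharides"),
    "PL6": ("algal", "algal polysaccharides"),
    "PL7": ("algal", "algal polysaccharides"),
    "PL17": ("algal", "algal polysaccharides"),
    # lignocellulose backbone/side-chain
    "GH5": ("plant", "lignocellulose"),
    "GH8": ("plant", "lignocellulose"),
    "GH9": ("plant", "lignocellulose"),
    "GH10": ("plant", "lignocellulose"),
    "GH11": ("plant", "lignocellulose"),
    "GH43": ("plant", "lignocellulose"),
    "GH44": ("plant", "lignocellulose"),
    "GH45": ("plant", "lignocellulose"),
    "GH48": ("plant", "lignocellulose"),
    "GH51": ("plant", "lignocellulose"),
    "GH54": ("plant", "lignocellulose"),
    "GH62": ("plant", "lignocellulose"),
    "GH134": ("plant", "lignocellulose"),
    # storage/cellular alpha-glucans
    "GH13": ("plant", "glucans"),
    "GH15": ("plant", "glucans"),
    "GH57": ("plant", "glucans"),
    "GH77": ("plant", "glucans"),
    # oligosaccharide mop-up
    "GH1": ("algal/plant", "oligosaccharides"),
    "GH2": ("algal/plant", "oligosaccharides"),
    "GH3": ("algal/plant", "oligosaccharides"),
    "GH31": ("algal/plant", "oligosaccharides"),
    "GH38": ("algal/plant", "oligosaccharides"),
    "GH47": ("algal/plant", "oligosaccharides"),
    # chitin / peptidoglycan (N-acetylglucosamine based)
    "GH18": ("other", "NAG-based"),
    "GH19": ("other", "NAG-based"),
    "GH20": ("other", "NAG-based"),
    "GH102": ("other", "NAG-based"),
    # pectin
    "GH28": ("plant", "pectin"),
    "PL1": ("plant", "pectin"),
    "PL9": ("plant", "pectin"),
    "PL11": ("plant", "pectin"),
}


class SubstrateMap:
    """family label -> (biomass category, substrate category) lookup.

    Labels may be at family (``GH5``) or subfamily (``GH5_2``)
    granularity; lookups try the exact label first, then its parent
    family.
    """

    def __init__(self, entries: Mapping[str, tuple[str, str]]):
        self._entries: dict[str, tuple[str, str]] = {}
        for label, (biomass, substrate) in entries.items():
            CazymeModule.parse(label)
            if biomass not in BIOMASS_CATEGORIES:
                raise FormatError(f"{label}: unknown biomass category {biomass!r}")
            if substrate not in SUBSTRATE_CATEGORIES:
                raise FormatError(f"{label}: unknown substrate category {substrate!r}")
            if label in self._entries:
                raise FormatError(f"duplicate substrate map entry for {label}")
            self._entries[label] = (biomass, substrate)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, label: str) -> bool:
        return label in self._entries

    def lookup(self, module: CazymeModule) -> tuple[str, str]:
        """Return (biomass, substrate) or (unassigned, unassigned)."""
        hit = self._entries.get(module.label)
        if hit is None and module.subfamily is not None:
            hit = self._entries.get(module.family_label)
        return hit if hit is not None else (UNASSIGNED, UNASSIGNED)

    @classmethod
    def default(cls) -> "SubstrateMap":
        return cls(_DEFAULT_ENTRIES)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SubstrateMap":
        entries: dict[str, tuple[str, str]] = {}
        with open(path) as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader, None)
            expected = ["family_label", "biomass_category", "substrate_category"]
            if header is None or [h.strip() for h in header] != expected:
                raise FormatError(f"{path}: expected header {expected}, got {header}")
            for row in reader:
                if not row:
                    continue
                label = row[0].strip()
                if label in entries:
                    raise FormatError(f"{path}: duplicate substrate map entry for {label}")
                entries[label] = (row[1].strip(), row[2].strip())
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["family_label", "biomass_category", "substrate_category"])
            for label in sorted(self._entries):
                b, s = self._entries[label]
                w.writerow([label, b, s])


@dataclass(frozen=True)
class ModuleAnnotation:
    gene_id: str
    module: CazymeModule
    biomass_category: str
    substrate_category: str

    @property
    def assigned(self) -> bool:
        return self.substrate_category != UNASSIGNED


def assign_substrates(
    calls: Iterable[CazymeCall], substrate_map: SubstrateMap
) -> list[ModuleAnnotation]:
    """Annotate every GH/PL module of classified genes with categories.

    Non-GH/PL modules (CE, AA, CBM) are skipped; unmapped families get
    the sentinel ``unassigned`` category.
    """
    out = []
    for call in calls:
        if call.status != STATUS_CLASSIFIED:
            continue
        for module in call.modules:
            if module.cazy_class not in ("GH", "PL"):
                continue
            biomass, substrate = substrate_map.lookup(module)
            out.append(ModuleAnnotation(call.gene_id, module, biomass, substrate))
    return out


def assigned_ratio(annotations: Sequence[ModuleAnnotation]) -> float | None:
    """Mapped GH/PL modules / all GH/PL modules; None when there are none.

    The unit is the module: a bifunctional GH5+GH10 protein contributes
    two modules.
    """
    if not annotations:
        return None
    return sum(a.assigned for a in annotations) / len(annotations)


def category_counts(annotations: Sequence[ModuleAnnotation]) -> dict[str, int]:
    counts = {c: 0 for c in SUBSTRATE_CATEGORIES}
    counts[UNASSIGNED] = 0
    for a in annotations:
        counts[a.substrate_category] += 1
    return counts


def secretion_ratio(
    annotations: Sequence[ModuleAnnotation],
    sp_calls: Mapping[str, SignalPeptideCall],
    category: str,
    sp_types: set[str] | None = None,
) -> float | None:
    """Fraction of genes in one substrate category with a signal peptide.

    The unit is the gene (a signal peptide belongs to the whole
    protein); a gene whose modules map to several categories counts
    once in each. ``sp_types=None`` accepts any type except NONE.
    Genes without a signal-peptide record count as NONE. Returns None
    for a category with no genes.
    """
    genes = {a.gene_id for a in annotations if a.substrate_category == category}
    if not genes:
        return None

    def secreted(gene_id: str) -> bool:
        call = sp_calls.get(gene_id)
        if call is None or call.sp_type == "NONE":
            return False
        return True if sp_types is None else call.sp_type in sp_types

    return sum(secreted(g) for g in genes) / len(genes)


def substrate_profile(
    genome_id: str,
    annotations: Sequence[ModuleAnnotation],
    sp_calls: Mapping[str, SignalPeptideCall],
    sp_types: set[str] | None = None,
) -> dict:
    """Per-genome substrate profile row: category counts, assigned
    ratio and per-category secretion ratios."""
    row: dict = {"genome_id": genome_id}
    counts = category_counts(annotations)
    for cat in SUBSTRATE_CATEGORIES:
        row[f"n_{cat}"] = counts[cat]
    row["n_unassigned"] = counts[UNASSIGNED]
    row["assigned_ratio"] = assigned_ratio(annotations)
    for cat in SUBSTRATE_CATEGORIES:
        row[f"secretion_{cat}"] = secretion_ratio(annotations, sp_calls, cat, sp_types)
    return row
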