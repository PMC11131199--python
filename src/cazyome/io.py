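"""Readers and writers for the tabular formats the pipeline consumes.

All inputs are products of upstream tools the pipeline does not run
itself: prodigal gene calls carried as GFF3, dbCAN2 ``overview.txt``
style consensus tables, signalP6 predictions, DIAMOND/BLAST tabular
best hits (outfmt6) and a genome metadata table. Validation is strict:
malformed coordinates, out-of-range percentages and unknown family
labels are hard errors, not warnings.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .consensus import CazymeModule, LabelError, ToolHits

logger = logging.getLogger(__name__)

SP_TYPES = ("SP", "LIPO", "TAT", "TATLIPO", "PILIN", "NONE")

# dbCAN2's HMMER column decorates labels with domain ranges, e.g. GH5_2(23-301)
_RANGE_SUFFIX_RE = re.compile(r"\(\d+-\d+\)$")


class FormatError(ValueError):
    """Raised for malformed or out-of-contract input files."""


@dataclass(frozen=True)
class GeneRecord:
    """One protein-coding gene.

    ``rank`` is the 0-based position of the gene in the order of genes
    along its contig (ascending start); all neighbourhood logic in the
    package works on ranks, never on base-pair coordinates.
    """

    genome_id: str
    contig_id: str
    gene_id: str
    start: int  # 1-based, inclusive
    end: int  # inclusive, end >= start
    strand: str
    rank: int
    product: str = ""
    aa_length: int = 1

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise FormatError(f"gene {self.gene_id}: end {self.end} < start {self.start}")
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.rank < 0:
            raise FormatError(f"gene {self.gene_id}: negative rank")
        if self.aa_length <= 0:
            raise FormatError(f"gene {self.gene_id}: aa_length must be positive")


@dataclass(frozen=True)
class SignalPeptideCall:
    gene_id: str
    sp_type: str
    probability: float

    def __post_init__(self) -> None:
        if self.sp_type not in SP_TYPES:
            raise FormatError(f"{self.gene_id}: unknown signal peptide type {self.sp_type!r}")
        if not 0.0 <= self.probability <= 1.0:
            raise FormatError(
                f"{self.gene_id}: signal peptide probability {self.probability} outside [0,1]"
            )

    @property
    def has_signal_peptide(self) -> bool:
        return self.sp_type != "NONE"


@dataclass(frozen=True)
class GenomeMetadata:
    genome_id: str
    tax_class: str
    tax_order: str
    tax_family: str
    habitat: str
    completeness: float  # percent
    contamination: float  # percent
    genome_size_bp: int
    n_proteins: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness <= 100.0:
            raise FormatError(
                f"{self.genome_id}: completeness {self.completeness} outside [0,100]"
            )
        if self.contamination < 0.0:
            raise FormatError(f"{self.genome_id}: negative contamination")
        if self.n_proteins <= 0:
            raise FormatError(f"{self.genome_id}: n_proteins must be positive")


@dataclass(frozen=True)
class AlignmentHit:
    """One outfmt6 row; only the 4 consumed fields are typed."""

    query: str
    subject: str
    identity: float  # percent
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise FormatError(
                f"hit {self.query}->{self.subject}: identity {self.identity} outside [0,100]"
            )


# ---------------------------------------------------------------------------
# GFF3


def _assign_ranks(raw: list[tuple[str, int, int, str, str, str]], genome_id: str) -> list[GeneRecord]:
    by_contig: dict[str, list] = {}
    for row in raw:
        by_contig.setdefault(row[0], []).append(row)
    out: list[GeneRecord] = []
    for contig_id in sorted(by_contig):
        rows = sorted(by_contig[contig_id], key=lambda r: (r[1], r[2], r[3]))
        for rank, (cid, start, end, gene_id, strand, product) in enumerate(rows):
            aa = max(1, (end - start + 1) // 3 - 1)
            out.append(
                GeneRecord(genome_id, cid, gene_id, start, end, strand, rank, product, aa)
            )
    return out


def read_gff(path: str | Path, genome_id: str | None = None) -> list[GeneRecord]:
    """Read CDS features from a prodigal-style GFF3 file.

    Ranks are assigned per contig by ascending start (ties: end, then
    gene_id). ``genome_id`` defaults to the file stem.
    """
    path = Path(path)
    if genome_id is None:
        genome_id = path.stem
    raw = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF columns, got {len(fields)}")
            contig, _src, ftype, start_s, end_s, _score, strand, _frame, attrs = fields
            if ftype != "CDS":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if end < start:
                raise FormatError(f"{path}:{lineno}: end {end} < start {start}")
            attr_d = {}
            for item in attrs.strip(";").split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attr_d[k.strip()] = v.strip()
            gene_id = attr_d.get("ID")
            if gene_id is None:
                raise FormatError(f"{path}:{lineno}: CDS feature without ID attribute")
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            raw.append((contig, start, end, gene_id, strand, attr_d.get("product", "")))
    if not raw:
        logger.warning("no CDS features in %s", path)
        return []
    return _assign_ranks(raw, genome_id)


def write_gff(genes: Sequence[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.contig_id, g.rank)):
            attrs = f"ID={g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(
                f"{g.contig_id}\tcazyome\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# dbCAN2 overview

_OVERVIEW_COLS = ["GeneID", "HMMER", "Hotpep", "DIAMOND", "#ofTools"]


def _split_labels(cell: str) -> tuple[str, ...]:
    cell = cell.strip()
    if cell in ("-", ""):
        return ()
    labels = []
    for part in cell.split("+"):
        part = _RANGE_SUFFIX_RE.sub("", part.strip())
        CazymeModule.parse(part)  # grammar gate
        labels.append(part)
    return tuple(labels)


def read_dbcan_overview(path: str | Path, on_error: str = "raise") -> list[ToolHits]:
    """Read a dbCAN2 5-column overview table into per-gene tool hits.

    ``-`` means no hit; several families on one gene are joined by
    ``+``; a trailing HMMER domain range ``(23-301)`` is stripped. The
    ``#ofTools`` column is ignored (recomputed downstream).
    ``on_error`` is ``"raise"`` (default) or ``"skip"`` for rows with
    labels that violate the grammar.
    """
    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")
    path = Path(path)
    out: list[ToolHits] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != _OVERVIEW_COLS:
            raise FormatError(
                f"{path}: expected dbCAN2 overview header {_OVERVIEW_COLS}, got {header}"
            )
        for lineno, row in enumerate(reader, 2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns, got {len(row)}")
            gene_id = row[0].strip()
            try:
                out.append(
                    ToolHits(
                        gene_id,
                        hmmer=_split_labels(row[1]),
                        hotpep=_split_labels(row[2]),
                        diamond=_split_labels(row[3]),
                    )
                )
            except LabelError as exc:
                if on_error == "raise":
                    raise FormatError(f"{path}:{lineno}: gene {gene_id}: {exc}") from exc
                logger.warning("skipping gene %s: %s", gene_id, exc)
    return out


def write_dbcan_overview(hits: Sequence[ToolHits], path: str | Path) -> None:
    def join(labels: tuple[str, ...]) -> str:
        return "+".join(labels) if labels else "-"

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_OVERVIEW_COLS)
        for h in hits:
            n_tools = sum(bool(x) for x in (h.hmmer, h.hotpep, h.diamond))
            w.writerow([h.gene_id, join(h.hmmer), join(h.hotpep), join(h.diamond), n_tools])


# ---------------------------------------------------------------------------
# signalP

_SIGNALP_COLS = ["gene_id", "sp_type", "probability"]


def read_signalp(path: str | Path) -> list[SignalPeptideCall]:
    path = Path(path)
    out = []
    seen: set[str] = set()
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != _SIGNALP_COLS:
            raise FormatError(f"{path}: expected signalP header {_SIGNALP_COLS}, got {header}")
        for lineno, row in enumerate(reader, 2):
            if not row:
                continue
            if len(row) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            gene_id = row[0].strip()
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate signal peptide record {gene_id}")
            seen.add(gene_id)
            try:
                prob = float(row[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric probability") from None
            out.append(SignalPeptideCall(gene_id, row[1].strip(), prob))
    return out


def write_signalp(calls: Sequence[SignalPeptideCall], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_SIGNALP_COLS)
        for c in calls:
            w.writerow([c.gene_id, c.sp_type, format(c.probability, "g")])


# ---------------------------------------------------------------------------
# metadata

_METADATA_COLS = [
    "genome_id",
    "tax_class",
    "tax_order",
    "tax_family",
    "habitat",
    "completeness",
    "contamination",
    "genome_size_bp",
    "n_proteins",
]


def read_metadata(path: str | Path) -> list[GenomeMetadata]:
    path = Path(path)
    out = []
    seen: set[str] = set()
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != _METADATA_COLS:
            raise FormatError(
                f"{path}: expected metadata header {_METADATA_COLS}, got {reader.fieldnames}"
            )
        for row in reader:
            gid = row["genome_id"].strip()
            if gid in seen:
                raise FormatError(f"{path}: duplicate genome_id {gid}")
            seen.add(gid)
            out.append(
                GenomeMetadata(
                    gid,
                    row["tax_class"].strip(),
                    row["tax_order"].strip(),
                    row["tax_family"].strip(),
                    row["habitat"].strip(),
                    float(row["completeness"]),
                    float(row["contamination"]),
                    int(row["genome_size_bp"]),
                    int(row["n_proteins"]),
                )
            )
    return out


def write_metadata(records: Sequence[GenomeMetadata], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_METADATA_COLS)
        for m in records:
            w.writerow(
                [
                    m.genome_id,
                    m.tax_class,
                    m.tax_order,
                    m.tax_family,
                    m.habitat,
                    format(m.completeness, "g"),
                    format(m.contamination, "g"),
                    m.genome_size_bp,
                    m.n_proteins,
                ]
            )


# ---------------------------------------------------------------------------
# outfmt6


def read_outfmt6(path: str | Path) -> list[AlignmentHit]:
    """Read BLAST/DIAMOND tabular output (12 standard columns); only
    qseqid, sseqid, pident and bitscore are consumed."""
    path = Path(path)
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(f"{path}:{lineno}: expected 12 outfmt6 columns, got {len(fields)}")
            try:
                hit = AlignmentHit(fields[0], fields[1], float(fields[2]), float(fields[11]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            out.append(hit)
    return out


def write_outfmt6(hits: Sequence[AlignmentHit], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        for h in hits:
            # unconsumed columns written as benign placeholders
            fh.write(
                "\t".join(
                    [
                        h.query,
                        h.subject,
                        format(h.identity, "g"),
                        "100",
                        "0",
                        "0",
                        "1",
                        "100",
                        "1",
                        "100",
                        "1e-50",
                        format(h.bitscore, "g"),
                    ]
                )
                + "\n"
            )
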