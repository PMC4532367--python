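"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are 0-based half-open (BED convention) internally;
any 1-based source must be converted at the reader.  No raw text crosses a
module boundary: every reader returns validated domain types or typed
:class:`pandas.DataFrame` columns.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

GENE_CLASSES = ("protein_coding", "lncRNA", "antisense", "other")

__all__ = [
    "GENE_CLASSES",
    "GenomicInterval",
    "GeneRecord",
    "BedParseError",
    "IntervalValidationError",
    "SchemaError",
    "MotifNotFoundError",
    "PwmParseError",
    "read_bed",
    "write_bed",
    "read_jaspar_pwm",
    "read_table",
    "read_gene_table",
    "write_gene_table",
    "read_fasta",
    "write_fasta",
]


class BedParseError(ValueError):
    """A BED/narrowPeak line could not be parsed."""


class IntervalValidationError(ValueError):
    """An interval violates the coordinate invariants."""


class SchemaError(ValueError):
    """A delimited table is missing required columns."""


class MotifNotFoundError(KeyError):
    """Requested motif id absent from a JASPAR flat file."""


class PwmParseError(ValueError):
    """A JASPAR record is structurally invalid."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval, optionally carrying a summit offset.

    ``summit`` is a 0-based offset from ``start``; when absent, the summit
    defaults to the interval midpoint (consensus intervals have no called
    summit, so analyses centre on the midpoint instead).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    summit: int | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise IntervalValidationError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise IntervalValidationError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise IntervalValidationError(f"invalid strand {self.strand!r}")
        if self.summit is not None and not 0 <= self.summit < self.end - self.start:
            raise IntervalValidationError(
                f"summit offset {self.summit} outside [0, {self.end - self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def summit_offset(self) -> int:
        """Summit offset from start; midpoint when no summit was called."""
        if self.summit is not None:
            return self.summit
        return math.floor((self.start + self.end) / 2) - self.start

    @property
    def summit_position(self) -> int:
        """Absolute 0-based summit coordinate."""
        return self.start + self.summit_offset

    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass(frozen=True)
class GeneRecord:
    """A gene anchored at its TSS, with an Ensembl-style class label."""

    id: str
    tss: int
    strand: str
    chrom: str
    gene_class: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise IntervalValidationError(f"tss must be >= 0, got {self.tss}")
        if self.strand not in {"+", "-"}:
            raise IntervalValidationError(f"gene strand must be +/-, got {self.strand!r}")
        if self.gene_class not in GENE_CLASSES:
            raise IntervalValidationError(
                f"gene_class {self.gene_class!r} not in {GENE_CLASSES}"
            )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+/narrowPeak intervals, preserving file order.

    A numeric 10th field (narrowPeak dialect) is interpreted as the summit
    offset from ``start``; ``-1`` means "no summit called".
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 and fields[5] in {"+", "-"} else "."
            summit: int | None = None
            if len(fields) >= 10:
                try:
                    raw_summit = int(float(fields[9]))
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: non-numeric summit field") from exc
                summit = raw_summit if raw_summit >= 0 else None
            try:
                intervals.append(
                    GenomicInterval(fields[0], start, end, strand, summit, name)
                )
            except IntervalValidationError as exc:
                raise IntervalValidationError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(path: str | Path, intervals: Iterable[GenomicInterval]) -> None:
    """Write intervals as narrowPeak when any summit is set, else BED6."""
    intervals = list(intervals)
    as_narrowpeak = any(iv.summit is not None for iv in intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = iv.name if iv.name is not None else "."
            if as_narrowpeak:
                summit = iv.summit if iv.summit is not None else -1
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}"
                    f"\t0\t-1\t-1\t{summit}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


_BASE_ORDER = "ACGT"


def read_jaspar_pwm(path: str | Path, motif_id: str) -> list[list[float]]:
    """Extract a raw 4 x L count matrix for ``motif_id`` from a JASPAR flat file.

    Rows are returned in A, C, G, T order regardless of the order in the file.
    Both the bracketed (``A [ 1 2 3 ]``) and the bare 4-row layouts are accepted.
    """
    records = _parse_jaspar(path)
    if motif_id not in records:
        raise MotifNotFoundError(
            f"motif {motif_id!r} not found in {path} (have: {sorted(records)})"
        )
    return records[motif_id]


def _parse_jaspar(path: str | Path) -> dict[str, list[list[float]]]:
    records: dict[str, list[list[float]]] = {}
    current_id: str | None = None
    rows: list[tuple[str | None, list[float]]] = []

    def flush() -> None:
        nonlocal rows
        if current_id is None:
            return
        if len(rows) != 4:
            raise PwmParseError(f"motif {current_id}: expected 4 base rows, got {len(rows)}")
        lengths = {len(vals) for _, vals in rows}
        if len(lengths) != 1:
            raise PwmParseError(f"motif {current_id}: rows of unequal length {lengths}")
        labels = [b for b, _ in rows]
        if all(b is not None for b in labels):
            if sorted(labels) != list(_BASE_ORDER):
                raise PwmParseError(f"motif {current_id}: base labels {labels} != A,C,G,T")
            by_base = dict(rows)
            matrix = [by_base[b] for b in _BASE_ORDER]
        else:
            matrix = [vals for _, vals in rows]
        if any(v < 0 for row in matrix for v in row):
            raise PwmParseError(f"motif {current_id}: negative counts")
        records[current_id] = matrix
        rows = []

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                current_id = line[1:].split()[0]
                continue
            if current_id is None:
                continue
            base: str | None = None
            body = line
            head = line.split(None, 1)[0].upper()
            if head in set(_BASE_ORDER) and len(head) == 1:
                base = head
                body = line.split(None, 1)[1] if " " in line or "\t" in line else ""
            body = body.replace("[", " ").replace("]", " ")
            try:
                vals = [float(tok) for tok in body.split()]
            except ValueError as exc:
                raise PwmParseError(f"motif {current_id}: bad matrix line {line!r}") from exc
            if not vals:
                raise PwmParseError(f"motif {current_id}: empty matrix row {line!r}")
            rows.append((base, vals))
    flush()
    return records


def read_table(
    path: str | Path,
    schema: Mapping[str, type] | Sequence[str],
    *,
    sep: str = "\t",
) -> pd.DataFrame:
    """Read a delimited table, enforcing the presence of required columns.

    ``schema`` maps required column names to target dtypes (or is a bare list
    of required names).  Missing values stay as NA; they are never imputed.
    """
    df = pd.read_csv(path, sep=sep)
    if not isinstance(schema, Mapping):
        schema = {name: None for name in schema}
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    for name, dtype in schema.items():
        if dtype is None:
            continue
        if dtype is bool:
            df[name] = df[name].map(_coerce_bool)
        else:
            df[name] = df[name].astype(dtype, errors="raise")
    return df


def _coerce_bool(value: object) -> object:
    if pd.isna(value):
        return pd.NA
    if isinstance(value, str):
        low = value.strip().lower()
        if low in {"true", "t", "yes", "1"}:
            return True
        if low in {"false", "f", "no", "0"}:
            return False
        raise ValueError(f"cannot interpret {value!r} as boolean")
    return bool(value)


_GENE_COLUMNS = ("gene_id", "chrom", "tss", "strand", "gene_class")


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read a TSV gene annotation into validated :class:`GeneRecord` rows."""
    df = read_table(path, {"gene_id": str, "chrom": str, "tss": int, "strand": str,
                           "gene_class": str})
    return [
        GeneRecord(row.gene_id, int(row.tss), row.strand, row.chrom, row.gene_class)
        for row in df.itertuples()
    ]


def write_gene_table(path: str | Path, genes: Iterable[GeneRecord]) -> None:
    df = pd.DataFrame(
        [(g.id, g.chrom, g.tss, g.strand, g.gene_class) for g in genes],
        columns=list(_GENE_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file as an ordered ``{id: uppercase sequence}`` mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
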