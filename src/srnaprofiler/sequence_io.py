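"""Readers and writers for the pipeline's external formats.

FASTQ (PHRED+33), FASTA, a BED-like six-column annotation table
(contig, start, end, name, category, strand; 0-based half-open), and the
tab-separated tables the pipeline emits. RNA alphabets are normalized to
DNA (U -> T) on input so that every downstream comparison is over
{A, C, G, T, N}.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

#: Categories a genomic annotation interval may carry.
ANNOTATION_CATEGORIES = frozenset(
    {"mt", "cp", "mRNA", "rRNA", "tRNA", "snRNA", "snoRNA", "lncRNA", "repeats", "miRNA"}
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

PHRED_OFFSET = 33  # modern Illumina; no autodetection


class ParseError(ValueError):
    """Raised for malformed input records; message names the offending line."""


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert RNA (U) to DNA (T)."""
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadRecord:
    """A single sequencing read with per-base PHRED qualities."""

    id: str
    sequence: str
    quality: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id!r}: empty sequence")
        if len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class CatalogEntry:
    """A mature miRNA with optional precursor context.

    ``family`` is the field-standard family label (e.g. miR167 for
    zma-miR167c); ``variant_suffix`` holds the trailing paralog letters
    used when concatenating representative-group names.
    """

    name: str
    family: str
    mature_seq: str
    precursor_seq: str | None = None

    def __post_init__(self) -> None:
        if not 18 <= len(self.mature_seq) <= 26:
            raise ValueError(
                f"{self.name}: mature length {len(self.mature_seq)} outside [18, 26]"
            )
        if self.precursor_seq is not None and self.mature_seq not in self.precursor_seq:
            raise ValueError(f"{self.name}: mature sequence not found in precursor")

    @property
    def variant_suffix(self) -> str:
        return parse_mirna_name(self.name)[1]

    @property
    def species_prefix(self) -> str:
        """Leading species code of a miRBase-style name ('' when absent)."""
        head = self.name.split("-", 1)[0]
        return head if head.lower() != self.name.lower() and "mir" not in head.lower() else ""


@dataclass(frozen=True)
class AnnotationInterval:
    """A genomic interval carrying an ncRNA category (0-based half-open)."""

    contig: str
    start: int
    end: int
    strand: str
    category: str
    name: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"invalid strand {self.strand!r}")


_NAME_RE = re.compile(r"(?i)(mir)-?(\d+)([a-z]*)")


def parse_mirna_name(name: str) -> tuple[str, str]:
    """Split a miRBase-style name into (family, variant letters).

    The species prefix (anything before the first 'miR') and arm/precursor
    suffixes after a separator are discarded: zma-miR167c -> (miR167, c);
    zma-miR166c-5p -> (miR166, c); miR408 -> (miR408, '').
    """
    m = _NAME_RE.search(name)
    if m is None:
        raise ValueError(f"cannot parse miRNA family from name {name!r}")
    return f"miR{m.group(2)}", m.group(3)


def mirna_family(name: str) -> str:
    return parse_mirna_name(name)[0]


# ---------------------------------------------------------------------------
# FASTQ


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Yield :class:`ReadRecord` from a 4-line-record FASTQ file.

    U is normalized to T; qualities decoded at PHRED+33. Malformed records
    raise :class:`ParseError` naming the line number.
    """
    path = Path(path)
    with path.open() as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            if not header.startswith("@"):
                raise ParseError(f"{path}:{lineno}: expected '@' header, got {header.strip()!r}")
            seq_line = fh.readline()
            plus = fh.readline()
            qual_line = fh.readline()
            if not qual_line:
                raise ParseError(f"{path}:{lineno}: truncated record")
            lineno += 3
            if not plus.startswith("+"):
                raise ParseError(f"{path}:{lineno - 1}: expected '+' separator")
            seq = normalize_sequence(seq_line.strip())
            qual = qual_line.strip()
            if len(qual) != len(seq):
                raise ParseError(
                    f"{path}:{lineno}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            if not seq:
                raise ParseError(f"{path}:{lineno - 2}: empty sequence")
            yield ReadRecord(
                id=header[1:].strip().split()[0],
                sequence=seq,
                quality=tuple(ord(c) - PHRED_OFFSET for c in qual),
            )


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for rec in records:
            qual = "".join(chr(q + PHRED_OFFSET) for q in rec.quality)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} mapping (U -> T)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = normalize_sequence(str(rec.seq))
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# Catalog


def read_catalog(
    fasta_path: str | Path,
    meta_path: str | Path | None = None,
    precursor_fasta: str | Path | None = None,
) -> list[CatalogEntry]:
    """Read a mature-miRNA catalog.

    ``fasta_path`` holds mature sequences. ``meta_path`` optionally maps
    name -> family (TSV with columns ``name`` and ``family``); otherwise the
    family is inferred from the name. ``precursor_fasta`` optionally holds
    precursor (hairpin) sequences keyed by the same names.
    """
    matures = [
        (rec.id, normalize_sequence(str(rec.seq)))
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    ]
    families: dict[str, str] = {}
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", dtype=str)
        families = dict(zip(meta["name"], meta["family"]))
    precursors = read_fasta(precursor_fasta) if precursor_fasta is not None else {}

    entries: list[CatalogEntry] = []
    seen: set[str] = set()
    for name, mature in matures:
        if name in seen:
            raise ParseError(f"duplicate catalog entry {name!r}")
        seen.add(name)
        family = families.get(name) or mirna_family(name)
        entries.append(
            CatalogEntry(
                name=name,
                family=family,
                mature_seq=mature,
                precursor_seq=precursors.get(name),
            )
        )
    return entries


# ---------------------------------------------------------------------------
# Annotations


def read_annotations(path: str | Path) -> list[AnnotationInterval]:
    """Read the BED-like 6-column annotation table."""
    intervals: list[AnnotationInterval] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ParseError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            contig, start, end, name, category, strand = fields
            intervals.append(
                AnnotationInterval(
                    contig=contig,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    category=category,
                    name=name,
                )
            )
    return intervals


def write_annotations(intervals: Iterable[AnnotationInterval], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for iv in intervals:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.category}\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Tables


def _format_float(x: float) -> str:
    """Two decimals, halves rounded away from zero (so -4.385 -> -4.39),
    matching how percentages and fold changes are conventionally printed."""
    return str(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def write_table(rows: pd.DataFrame | Sequence[Mapping[str, object]], path: str | Path) -> None:
    """Write rows as a TSV with a header line; floats rendered with 2
    decimals."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df = df.copy()
    for col in df.columns:
        if pd.api.types.is_float_dtype(df[col]):
            df[col] = df[col].map(_format_float)
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
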