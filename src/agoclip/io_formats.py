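"""Readers and writers for the interval, sequence and expression formats.

All genomic coordinates are 0-based half-open (BED convention), everywhere,
including internal types. Strand is kept throughout; a minus-strand interval
refers to the reverse complement of the plus-strand slice.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

VALID_STRANDS = ("+", "-")

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


class BedParseError(ValueError):
    """Raised when a BED line cannot be parsed into a valid interval."""


class SchemaError(ValueError):
    """Raised when a tabular input lacks a required column."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open.

    Degenerate (zero- or negative-length) intervals are rejected at
    construction so downstream arithmetic never sees them.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Floor midpoint in base coordinates (deterministic for even length)."""
        return (self.start + self.end - 1) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom or self.strand != other.strand:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (DNA or RNA alphabet)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or not self.sequence:
            raise ValueError("SequenceRecord requires non-empty id and sequence")


@dataclass(frozen=True)
class ExpressionRecord:
    """A gene-level log2 fold change (treatment vs control)."""

    gene_id: str
    log2fc: float

    def __post_init__(self) -> None:
        import math

        if not math.isfinite(self.log2fc):
            raise ValueError(f"non-finite log2fc for gene {self.gene_id}")


@dataclass
class BedRecord:
    """A BED line: interval plus optional name/score payload."""

    iv: GenomicInterval
    name: str = "."
    score: float = 0.0


def reverse_complement(seq: str) -> str:
    """Reverse complement; U is treated as T's complement partner (U<->A)."""
    return seq.translate(_COMPLEMENT)[::-1]


def dna_to_rna(seq: str) -> str:
    return seq.replace("T", "U").replace("t", "u")


def read_bed(path: str | os.PathLike, min_fields: int = 6) -> list[BedRecord]:
    """Read a BED file into validated records, preserving input order.

    Lines starting with ``track``, ``browser`` or ``#`` are skipped. Strand
    defaults to ``+`` when fewer than 6 fields are requested/present.
    """
    records: list[BedRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < min_fields:
                raise BedParseError(
                    f"{path}:{lineno}: expected >= {min_fields} fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            strand = fields[5] if len(fields) >= 6 else "+"
            try:
                iv = GenomicInterval(fields[0], start, end, strand)
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            name = fields[3] if len(fields) >= 4 else "."
            try:
                score = float(fields[4]) if len(fields) >= 5 and fields[4] != "." else 0.0
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-numeric score") from exc
            records.append(BedRecord(iv=iv, name=name, score=score))
    return records


def write_bed(records: Iterable[BedRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for rec in records:
            score = rec.score
            score_str = str(int(score)) if float(score).is_integer() else repr(score)
            fh.write(
                f"{rec.iv.chrom}\t{rec.iv.start}\t{rec.iv.end}\t"
                f"{rec.name}\t{score_str}\t{rec.iv.strand}\n"
            )


def read_fasta(path: str | os.PathLike, rna: bool = False) -> list[SequenceRecord]:
    """Read a plain FASTA file.

    With ``rna=True`` any T is normalized to U (miRNA files in the wild mix
    DNA and RNA alphabets).
    """
    records: list[SequenceRecord] = []
    name: str | None = None
    chunks: list[str] = []
    seen: set[str] = set()

    def _flush() -> None:
        if name is None:
            return
        seq = "".join(chunks).upper()
        if rna:
            seq = seq.replace("T", "U")
        if name in seen:
            raise ValueError(f"duplicate FASTA id {name!r} in {path}")
        seen.add(name)
        records.append(SequenceRecord(id=name, sequence=seq))

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
        _flush()
    return records


def extract_sequence(
    genome: Mapping[str, str], iv: GenomicInterval, rna: bool = False
) -> str:
    """Slice a genome dict by interval; minus strand returns the revcomp.

    ``genome`` maps chromosome name to its full plus-strand sequence.
    """
    if iv.chrom not in genome:
        raise KeyError(f"chromosome {iv.chrom!r} not in genome")
    chrom_seq = genome[iv.chrom]
    if iv.end > len(chrom_seq):
        raise IndexError(
            f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
            f"length {len(chrom_seq)}"
        )
    seq = chrom_seq[iv.start : iv.end].upper()
    if iv.strand == "-":
        seq = reverse_complement(seq)
    return dna_to_rna(seq) if rna else seq


def genome_from_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: rec.sequence for rec in read_fasta(path)}


def read_expression_table(path: str | os.PathLike) -> list[ExpressionRecord]:
    """Read a gene_id/log2fc TSV; duplicate gene ids are collapsed by mean."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "log2fc"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    if not pd.api.types.is_numeric_dtype(df["log2fc"]):
        try:
            df["log2fc"] = df["log2fc"].astype(float)
        except ValueError as exc:
            raise BedParseError(f"{path}: non-numeric log2fc") from exc
    collapsed = df.groupby("gene_id", sort=False)["log2fc"].mean()
    return [ExpressionRecord(g, float(v)) for g, v in collapsed.items()]


def write_expression_table(records: Iterable[ExpressionRecord], path) -> None:
    pd.DataFrame(
        [(r.gene_id, r.log2fc) for r in records], columns=["gene_id", "log2fc"]
    ).to_csv(path, sep="\t", index=False)
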