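"""Domain types and standard-format I/O.

Coordinate convention: 0-based, half-open everywhere (BED-style). Count-table
positions are 0-based too; no operation in this package reinterprets
coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

STRANDS = ("+", "-", ".")

_VALID_SEQ = re.compile(r"^[ACGTNacgtn]*$")

#: Columns of a per-cytosine bisulfite count table.
COUNT_COLUMNS = ["chrom", "pos", "strand", "n_unconverted", "n_converted"]

#: Condition labels used throughout the pipeline (file-name safe).
CONDITIONS = ("WT_nodmg", "WT_dmg", "KO_nodmg", "KO_dmg")


class PipelineError(ValueError):
    """Raised for malformed inputs or contract violations."""


@dataclass(frozen=True)
class Interval:
    """A stranded genomic interval, 0-based half-open.

    ``strand`` is ``+``, ``-`` or ``.`` (unstranded, e.g. DRIP peaks).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise PipelineError("Interval chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise PipelineError(
                f"Interval requires 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise PipelineError(f"Invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


class GenomeSequence:
    """Uppercase nucleotide sequences keyed by chromosome name.

    Sequences are plain Python strings over {A, C, G, T, N}; chromosome
    insertion order is preserved.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            if not name:
                raise PipelineError("empty chromosome name")
            if not _VALID_SEQ.match(seq):
                bad = sorted(set(seq) - set("ACGTNacgtn"))
                raise PipelineError(f"non-IUPAC characters in {name!r}: {bad}")
            self._seqs[name] = seq.upper()

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __iter__(self):
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def items(self):
        return self._seqs.items()

    def chroms(self) -> list[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, iv: Interval) -> str:
        seq = self._seqs[iv.chrom]
        if iv.end > len(seq):
            raise PipelineError(
                f"interval [{iv.start},{iv.end}) exceeds {iv.chrom} length {len(seq)}"
            )
        return seq[iv.start : iv.end]

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeSequence) and self._seqs == other._seqs


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a (wrapped or unwrapped) FASTA file into a :class:`GenomeSequence`.

    Rejects duplicate headers and non-IUPAC characters; lowercase input is
    normalised to uppercase.
    """
    path = Path(path)
    if not path.exists():
        raise PipelineError(f"FASTA file not found: {path}")
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise PipelineError(f"duplicate chromosome name {record.id!r} in {path}")
        seqs[record.id] = str(record.seq)
    return GenomeSequence(seqs)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[Interval]:
    """Read BED3/BED6 into a list of :class:`Interval`, input order preserved.

    BED3 lines get strand ``.``; empty intervals (start >= end), non-integer
    coordinates and short lines are rejected with the offending line number.
    """
    path = Path(path)
    if not path.exists():
        raise PipelineError(f"BED file not found: {path}")
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PipelineError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise PipelineError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 else "."
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(Interval(fields[0], start, end, strand, name))
            except PipelineError as exc:
                raise PipelineError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    """Write intervals as BED6; ``read_bed`` round-trips the result exactly."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# TSV tables (counts, calls, grids) — '#' comment headers, tab-separated


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise PipelineError(f"table not found: {path}")
    return pd.read_csv(path, sep="\t", comment="#")


def write_table(df: pd.DataFrame, path: str | Path, header_lines: list[str] | None = None) -> None:
    """Write a TSV with optional '#'-prefixed header lines.

    Floats are rendered with repr-shortest formatting via pandas defaults but
    pinned to a fixed format for byte-stable output across runs.
    """
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.8g")


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a per-cytosine count table (chrom, pos, strand, n_unconverted, n_converted)."""
    df = read_table(path)
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise PipelineError(f"count table {path} missing columns {missing}")
    if (df["n_unconverted"] < 0).any() or (df["n_converted"] < 0).any():
        raise PipelineError(f"negative counts in {path}")
    return df
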