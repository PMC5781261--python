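"""Sequence and table I/O: FASTA/FASTQ readers and writers, label tables.

Parsing is delegated to Biopython's low-level iterators
(:func:`Bio.SeqIO.FastaIO.SimpleFastaParser`,
:func:`Bio.SeqIO.QualityIO.FastqGeneralIterator`); this module adds format
sniffing, gzip transparency, base uppercasing and the package's error
contract (:class:`~spherical.errors.ParseError` naming the offending
record).

Reads are single-end. Paired files can be concatenated and treated as
independent reads; no pairing semantics exist anywhere in the pipeline.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Optional, TextIO, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import ParseError

PathLike = Union[str, os.PathLike]


@dataclass(slots=True)
class Read:
    """One sequencing read.

    ``taxon`` optionally carries a truth label from simulation or a
    user-supplied table; it survives FASTA round trips only via the
    external label table, not the header.
    """

    id: str
    seq: str
    qual: Optional[str] = None
    taxon: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("read id must be non-empty")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(slots=True)
class Contig:
    """One assembled contig with provenance."""

    id: str
    seq: str
    iteration: Optional[int] = None
    k: Optional[int] = None
    mean_cov: float = 0.0

    def __len__(self) -> int:
        return len(self.seq)


def _open_text(path: PathLike) -> TextIO:
    """Open possibly gzip-compressed text, sniffing magic bytes."""
    fh = open(path, "rb")
    magic = fh.read(2)
    fh.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(fh))  # type: ignore[arg-type]
    return io.TextIOWrapper(fh)


def sniff_format(path: PathLike) -> str:
    """Return 'fasta' or 'fastq' from the first non-blank character."""
    with _open_text(path) as fh:
        for line in fh:
            if line.strip():
                c = line.lstrip()[0]
                if c == ">":
                    return "fasta"
                if c == "@":
                    return "fastq"
                raise ParseError(
                    f"{path}: cannot sniff format from leading character {c!r}"
                )
    raise ParseError(f"{path}: empty file, cannot sniff format")


def read_fastx(path: PathLike, format: str = "auto") -> Iterator[Read]:
    """Stream :class:`Read` records from a FASTA or FASTQ file.

    Bases are uppercased; the id is the header up to the first whitespace.
    Malformed records raise :class:`ParseError` naming the approximate line.
    """
    if format == "auto":
        try:
            format = sniff_format(path)
        except ParseError:
            # empty file: empty stream
            with _open_text(path) as fh:
                if not fh.read(1):
                    return
            raise
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {format!r}")

    n = 0
    seen: set[str] = set()
    with _open_text(path) as fh:
        try:
            if format == "fasta":
                for title, seq in SimpleFastaParser(fh):
                    yield _make_read(path, title, seq, None, n, seen)
                    n += 1
            else:
                for title, seq, qual in FastqGeneralIterator(fh):
                    yield _make_read(path, title, seq, qual, n, seen)
                    n += 1
        except ValueError as exc:
            # FASTQ records are 4 lines; the failing record starts at 4n+1.
            line = 4 * n + 1 if format == "fastq" else None
            where = f" (near line {line})" if line else ""
            raise ParseError(f"{path}: record {n + 1}{where}: {exc}") from exc


def _make_read(
    path: PathLike, title: str, seq: str, qual: Optional[str], n: int, seen: set[str]
) -> Read:
    rid = title.split()[0] if title.split() else ""
    if not rid:
        raise ParseError(f"{path}: record {n + 1}: empty header")
    if rid in seen:
        raise ParseError(f"{path}: duplicate read id {rid!r} at record {n + 1}")
    seen.add(rid)
    try:
        return Read(id=rid, seq=seq.upper(), qual=qual)
    except ValueError as exc:
        raise ParseError(f"{path}: record {n + 1}: {exc}") from exc


def write_fasta(
    records: Iterable[Union[Read, Contig]], path: PathLike, line_width: int = 70
) -> int:
    """Write records as wrapped FASTA; returns the number written."""
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            if not rec.seq:
                raise ValueError(f"record {rec.id!r} has empty sequence")
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), line_width):
                fh.write(rec.seq[i : i + line_width])
                fh.write("\n")
            n += 1
    return n


def write_fastq(records: Iterable[Read], path: PathLike) -> int:
    """Write reads as 4-line FASTQ; missing qualities become 'I' (Q40)."""
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            if not rec.seq:
                raise ValueError(f"record {rec.id!r} has empty sequence")
            qual = rec.qual if rec.qual is not None else "I" * len(rec.seq)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")
            n += 1
    return n


def read_label_table(path: PathLike) -> dict[str, str]:
    """Read a 2-column TSV mapping read/contig id to taxon label.

    '#'-prefixed lines are comments. A duplicate id mapped to two different
    taxa is an error; a consistent duplicate is tolerated.
    """
    labels: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped.strip() or stripped.lstrip().startswith("#"):
                continue
            parts = stripped.split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns, "
                    f"got {len(parts)}"
                )
            rid, taxon = parts[0].strip(), parts[1].strip()
            if not rid or not taxon:
                raise ParseError(f"{path}: line {lineno}: empty id or taxon")
            if rid in labels and labels[rid] != taxon:
                raise ParseError(
                    f"{path}: line {lineno}: id {rid!r} mapped to both "
                    f"{labels[rid]!r} and {taxon!r}"
                )
            labels[rid] = taxon
    return labels


def write_label_table(labels: Mapping[str, str], path: PathLike) -> int:
    with open(path, "w") as fh:
        for rid, taxon in labels.items():
            fh.write(f"{rid}\t{taxon}\n")
    return len(labels)
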