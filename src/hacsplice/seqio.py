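"""Sequence I/O: FASTA, FASTQ, and the counted-unique-sequence FASTA+ dialect.

FASTA+ collapses identical reads into one record whose ID carries the
multiplicity as a trailing ``_<count>`` suffix (e.g. ``Seq1_3`` is a
sequence observed three times).  Collapsing loses nothing that junction
counting needs, and shrinks read sets dramatically.

FASTA and FASTQ parsing is delegated to Biopython; this module only adds
alphabet normalisation (uppercase, U->T) and the FASTA+ header rules.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

_VALID = set("ACGTN")


class SequenceParseError(ValueError):
    """Raised for malformed records; message names the offending record/line."""


def _normalise(seq: str, where: str) -> str:
    s = str(seq).upper().replace("U", "T")
    bad = set(s) - _VALID
    if bad:
        raise SequenceParseError(
            f"{where}: invalid nucleotide symbol(s) {sorted(bad)!r} (alphabet is A/C/G/T/N)"
        )
    if not s:
        raise SequenceParseError(f"{where}: empty sequence")
    return s


@dataclass(frozen=True)
class SeqRecord:
    """A single read or reference sequence.

    qual holds per-base Phred scores when loaded from FASTQ; nothing
    downstream uses it, it is kept only so FASTQ round-trips.
    """

    id: str
    seq: str
    qual: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", _normalise(self.seq, f"record {self.id!r}"))
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise SequenceParseError(
                f"record {self.id!r}: quality length {len(self.qual)} != sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class CountedSeq:
    """A unique sequence with its multiplicity in the original read set."""

    id: str
    seq: str
    count: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", _normalise(self.seq, f"record {self.id!r}"))
        if self.count < 1:
            raise ValueError(f"record {self.id!r}: count must be >= 1, got {self.count}")


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Load a FASTA file (optionally gzipped) in file order."""
    with _open_text(path) as fh:
        try:
            return [SeqRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]
        except ValueError as exc:  # Biopython raises ValueError on malformed input
            raise SequenceParseError(f"{path}: {exc}") from exc


def read_fastq(path: str | Path) -> list[SeqRecord]:
    """Load a FASTQ file (Sanger quality encoding, optionally gzipped)."""
    with _open_text(path) as fh:
        try:
            return [
                SeqRecord(
                    rec.id,
                    str(rec.seq),
                    tuple(rec.letter_annotations["phred_quality"]),
                )
                for rec in SeqIO.parse(fh, "fastq")
            ]
        except ValueError as exc:
            raise SequenceParseError(f"{path}: {exc}") from exc


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n")


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            qual = rec.qual if rec.qual is not None else (40,) * len(rec.seq)
            qstr = "".join(chr(q + 33) for q in qual)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qstr}\n")


_COUNT_SUFFIX = re.compile(r"^(?P<stem>.*)_(?P<count>\d+)$")


def parse_fastaplus_id(header_id: str) -> tuple[str, int]:
    """Split a FASTA+ ID into (stem, count).

    Only the suffix after the LAST underscore is the count; ``read_07``
    therefore has count 7.
    """
    m = _COUNT_SUFFIX.match(header_id)
    if m is None:
        raise SequenceParseError(
            f"FASTA+ header {header_id!r} lacks a parseable trailing _<count> suffix"
        )
    return m.group("stem"), int(m.group("count"))


def read_fastaplus(path: str | Path) -> list[CountedSeq]:
    """Load a FASTA+ file; counts come from the trailing ``_<count>`` ID suffix."""
    out = []
    for rec in read_fasta(path):
        _, count = parse_fastaplus_id(rec.id)
        if count < 1:
            raise SequenceParseError(f"FASTA+ header {rec.id!r}: count must be >= 1")
        out.append(CountedSeq(rec.id, rec.seq, count))
    _check_unique(out)
    return out


def write_fastaplus(counted: Sequence[CountedSeq], path: str | Path) -> None:
    """Write counted sequences with IDs ``Seq<k>_<count>``, k a 1-based index."""
    _check_unique(counted)
    with _open_text(path, "wt") as fh:
        for k, cs in enumerate(counted, start=1):
            fh.write(f">Seq{k}_{cs.count}\n{cs.seq}\n")


def _check_unique(counted: Iterable[CountedSeq]) -> None:
    seen: set[str] = set()
    for cs in counted:
        if cs.seq in seen:
            raise ValueError(f"duplicate sequence in counted set (id {cs.id!r})")
        seen.add(cs.seq)


def collapse_to_counted(seqs: Iterable[str]) -> list[CountedSeq]:
    """Deduplicate plain sequences into CountedSeqs, first-seen order."""
    counts: dict[str, int] = {}
    for s in seqs:
        counts[s] = counts.get(s, 0) + 1
    return [
        CountedSeq(f"Seq{k}_{n}", s, n) for k, (s, n) in enumerate(counts.items(), start=1)
    ]


def total_multiplicity(counted: Iterable[CountedSeq]) -> int:
    return sum(cs.count for cs in counted)
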