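"""Read cleaning ahead of junction mapping.

Order of operations, applied per read:

1. trim the maximal terminal run of 3' A's (library-added poly-A tails);
2. drop reads containing any ambiguous base (non-ACGT);
3. drop reads shorter than ``min_len`` (default 50 nt);
4. collapse identical survivors into counted unique sequences.

The retained-nucleotide total is tracked so downstream counts can be
normalised per kilobase of processed data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .seqio import CountedSeq, SeqRecord, collapse_to_counted

_ACGT = set("ACGT")


@dataclass(frozen=True)
class PreprocessParams:
    min_len: int = 50
    trim_polya: bool = True
    drop_ambiguous: bool = True

    def __post_init__(self) -> None:
        if self.min_len < 1:
            raise ValueError(f"min_len must be >= 1, got {self.min_len}")


@dataclass(frozen=True)
class DatasetStats:
    """Bookkeeping for per-kilobase normalisation of mapped-read counts."""

    reads_in: int
    reads_kept: int
    nucleotides_kept: int

    @property
    def kilobases_kept(self) -> float:
        return self.nucleotides_kept / 1000.0


def trim_polya(seq: str) -> str:
    """Remove the maximal terminal run of A's; internal runs are untouched."""
    return seq.rstrip("A")


def preprocess_reads(
    records: Iterable[SeqRecord], params: PreprocessParams = PreprocessParams()
) -> tuple[list[CountedSeq], DatasetStats]:
    """Clean and deduplicate reads; returns counted sequences plus stats."""
    kept: list[str] = []
    n_in = 0
    for rec in records:
        n_in += 1
        seq = trim_polya(rec.seq) if params.trim_polya else rec.seq
        if params.drop_ambiguous and (set(seq) - _ACGT):
            continue
        if len(seq) < params.min_len:
            continue
        kept.append(seq)
    counted = collapse_to_counted(kept)
    stats = DatasetStats(
        reads_in=n_in,
        reads_kept=len(kept),
        nucleotides_kept=sum(len(s) for s in kept),
    )
    return counted, stats
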