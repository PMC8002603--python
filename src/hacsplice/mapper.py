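"""Ungapped read-to-query mapping with an explicit E-value model.

Reads are matched against 40 nt junction queries by the longest shared
ungapped run.  A hit is retained when its run length w reaches
``min_match``, its E-value passes both the run-wide cutoff and the
critical E-value implied by ``min_match``, and the matched query interval
spans the junction (sites 20/21 of the query; for the Target query the
stop triplet at sites 21-23).

The E-value of a w nt exact run between a read of length L and a query of
length q, against a database of N reads, is

    E = (q - w) * N * (L - w) * 2**(-2 w)

i.e. the number of alignment start positions times the chance of w
consecutive base matches under a uniform base model.  The critical
E-value is this expression evaluated at w = min_match; because E decreases
strictly in w, a hit at exactly w = min_match sits on the critical value
and is kept (the comparison is <= against the critical E, < against the
run-wide cutoff).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .gene_model import JunctionQuerySet, QUERY_LEN
from .seqio import CountedSeq, total_multiplicity
from .splicing_metrics import JunctionCounts

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MapperParams:
    min_match: int = 25
    e_cutoff: float = 1e-7
    max_mismatch_in_extension: int = 0
    search_reverse_complement: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.min_match <= QUERY_LEN:
            raise ValueError(f"min_match must be in [1, {QUERY_LEN}], got {self.min_match}")
        if self.max_mismatch_in_extension < 0:
            raise ValueError("max_mismatch_in_extension must be >= 0")


@dataclass(frozen=True)
class Hit:
    """An ungapped match of a read onto a query (1-based inclusive query coords)."""

    read_id: str
    query_name: str
    q_start: int
    q_end: int
    match_len: int
    strand: str  # '+' or '-'
    evalue: float | None = None

    def __post_init__(self) -> None:
        if self.q_end - self.q_start + 1 != self.match_len:
            raise ValueError("q_end - q_start + 1 must equal match_len")


def evalue(n_reads: int, read_len: int, query_len: int, match_len: int) -> float:
    """Expected number of chance ungapped matches of length ``match_len``.

    Zero when the match consumes the whole query or the whole read (no
    alternative placements remain on that side).
    """
    if match_len > min(read_len, query_len):
        raise ValueError(
            f"match length {match_len} exceeds min(read={read_len}, query={query_len})"
        )
    return (query_len - match_len) * n_reads * (read_len - match_len) * 2.0 ** (-2 * match_len)


def _longest_run_exact(read: str, query: str) -> tuple[int, int] | None:
    """Longest exact shared run; returns (w, q_end 1-based) with smallest q_start tie-break."""
    n, m = len(read), len(query)
    if n == 0 or m == 0:
        return None
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    match = r[:, None] == q[None, :]
    run = np.zeros(m, dtype=np.int32)
    best_w = 0
    best_qstart = m + 1
    for i in range(n):
        shifted = np.empty(m, dtype=np.int32)
        shifted[0] = 0
        shifted[1:] = run[:-1]
        run = np.where(match[i], shifted + 1, 0)
        row_max = int(run.max())
        if row_max > 0 and row_max >= best_w:
            ends = np.flatnonzero(run == row_max)
            qstart = int(ends[0]) - row_max + 2  # 1-based
            if row_max > best_w or qstart < best_qstart:
                best_w = row_max
                best_qstart = qstart
    if best_w == 0:
        return None
    return best_w, best_qstart + best_w - 1


def _longest_run_with_mismatches(read: str, query: str, k: int) -> tuple[int, int] | None:
    """Longest ungapped block with <= k internal mismatches, ends anchored on matches.

    Plain per-diagonal enumeration; used only when mismatch tolerance is
    switched on, where inputs are short.
    """
    n, m = len(read), len(query)
    best: tuple[int, int] | None = None  # (w, q_start)
    for d in range(-(n - 1), m):  # diagonal: j = i + d
        i0 = max(0, -d)
        j0 = i0 + d
        length = min(n - i0, m - j0)
        if length <= 0:
            continue
        eq = [read[i0 + t] == query[j0 + t] for t in range(length)]
        prefix = [0]
        for e in eq:
            prefix.append(prefix[-1] + (0 if e else 1))
        for a in range(length):
            if not eq[a]:
                continue
            for b in range(length - 1, a - 1, -1):
                if not eq[b]:
                    continue
                if prefix[b + 1] - prefix[a] <= k:
                    w = b - a + 1
                    q_start = j0 + a + 1
                    if best is None or w > best[0] or (w == best[0] and q_start < best[1]):
                        best = (w, q_start)
                    break  # longest block for this start found
    if best is None:
        return None
    return best[0], best[1] + best[0] - 1


def best_ungapped_match(
    read: str, query: str, params: MapperParams = MapperParams()
) -> Hit | None:
    """Longest shared ungapped run between read and query, both strands.

    Ties are broken toward the smaller q_start, then the forward strand.
    Returns None when the longest run falls short of ``min_match``.
    """
    candidates: list[tuple[int, int, str]] = []  # (w, q_start, strand)

    def scan(seq: str, strand: str) -> None:
        if params.max_mismatch_in_extension == 0:
            res = _longest_run_exact(seq, query)
        else:
            res = _longest_run_with_mismatches(seq, query, params.max_mismatch_in_extension)
        if res is not None:
            w, q_end = res
            candidates.append((w, q_end - w + 1, strand))

    scan(read, "+")
    if params.search_reverse_complement:
        scan(revcomp(read), "-")
    if not candidates:
        return None
    # max w, then min q_start, then '+' over '-'
    w, q_start, strand = max(candidates, key=lambda c: (c[0], -c[1], c[2] == "+"))
    if w < params.min_match:
        return None
    return Hit(
        read_id="",
        query_name="",
        q_start=q_start,
        q_end=q_start + w - 1,
        match_len=w,
        strand=strand,
    )


_JUNCTION_SPAN = {"EE": (20, 21), "EI5": (20, 21), "EI3": (20, 21), "Target": (21, 23)}

_PREFILTER_K = 13


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def spans_junction(query_name: str, q_start: int, q_end: int) -> bool:
    """True when the matched query interval covers the junction (or stop triplet)."""
    left, right = _JUNCTION_SPAN[query_name]
    return q_start <= left and q_end >= right


def count_junction_reads(
    readset: Sequence[CountedSeq],
    queries: JunctionQuerySet,
    params: MapperParams = MapperParams(),
) -> tuple[JunctionCounts, pd.DataFrame]:
    """Map a counted read set onto the junction queries and tally multiplicities.

    The E-value database size N is the total read multiplicity of the set.
    A read may count toward several queries (the unspliced queries share
    intron sequence).  Returns the per-query counts and a table of retained
    hits.
    """
    n_db = total_multiplicity(readset)
    if n_db == 0:
        logger.warning("empty read set: all junction counts are zero")

    qdict = queries.as_dict()
    use_prefilter = (
        params.max_mismatch_in_extension == 0 and params.min_match >= _PREFILTER_K
    )
    prefilter: dict[str, set[str]] = {}
    if use_prefilter:
        for name, qseq in qdict.items():
            km = _kmers(qseq, _PREFILTER_K)
            if params.search_reverse_complement:
                km |= _kmers(revcomp(qseq), _PREFILTER_K)
            prefilter[name] = km

    counts = {name: 0 for name in qdict}
    rows = []
    for cs in readset:
        read_kmers = _kmers(cs.seq, _PREFILTER_K) if use_prefilter else None
        for name, qseq in qdict.items():
            if use_prefilter and read_kmers is not None and not (read_kmers & prefilter[name]):
                continue
            hit = best_ungapped_match(cs.seq, qseq, params)
            if hit is None:
                continue
            ev = evalue(n_db, len(cs.seq), len(qseq), hit.match_len)
            critical = evalue(n_db, len(cs.seq), len(qseq), params.min_match)
            if ev >= params.e_cutoff or ev > critical:
                continue
            if not spans_junction(name, hit.q_start, hit.q_end):
                continue
            counts[name] += cs.count
            rows.append(
                {
                    "read_id": cs.id,
                    "count": cs.count,
                    "query": name,
                    "strand": hit.strand,
                    "q_start": hit.q_start,
                    "q_end": hit.q_end,
                    "match_len": hit.match_len,
                    "evalue": ev,
                }
            )
    hits = pd.DataFrame(
        rows,
        columns=["read_id", "count", "query", "strand", "q_start", "q_end", "match_len", "evalue"],
    )
    jc = JunctionCounts(
        n_ee=counts["EE"],
        n_ei5=counts["EI5"],
        n_ei3=counts["EI3"],
        n_target=counts.get("Target", 0),
    )
    return jc, hits
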