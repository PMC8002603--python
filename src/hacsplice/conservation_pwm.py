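"""Per-site conservation summaries and splice-junction position weight matrices.

Conservation scores (posterior probabilities in [0, 1], one per reference
site, e.g. a PhastCons track) are summarised two ways:

* region means — one arithmetic mean per gene region (exon 1, degron,
  intron downstream of STOP1, exon 2, UTR);
* sliding-window means — mean score of every window of a fixed width
  (default 32 nt, the reference degron length) advanced one site at a
  time; a window wholly inside one region takes that region's label,
  otherwise it is labelled ``boundary``.

Scores may be loaded from a two-column site/score text track, projected
onto a reference from alignment-column scores, or computed internally as
the per-column identity fraction of a multiple alignment (the fraction of
non-gap residues matching the column majority) — a deliberately simple
stand-in for phylogenetic conservation models, which are out of scope.

Splice junctions are modelled by a position weight matrix over 30 nt
windows (15 nt on each side of the junction) with per-column pseudocounts
and log2-odds scoring against the pooled training-base background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from heapq import nlargest
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .degron import DegronResult
from .gene_model import GeneModel

REGIONS = ("utr", "exon1", "degron", "intron_downstream", "exon2")

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

JUNCTION_FLANK = 15
JUNCTION_WINDOW = 2 * JUNCTION_FLANK


@dataclass(frozen=True)
class ConservationTrack:
    """Per-reference-site conservation scores with region labels."""

    ref_id: str
    scores: np.ndarray  # float in [0, 1], length = reference length
    region_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))
        if len(self.scores) != len(self.region_labels):
            raise ValueError(
                f"{len(self.scores)} scores but {len(self.region_labels)} region labels"
            )

    def __len__(self) -> int:
        return len(self.scores)


def label_sites(g: GeneModel, degron: DegronResult | None = None) -> tuple[str, ...]:
    """Region label per site of the unspliced transcript.

    The degron occupies intron sites 1 through the end of STOP1 when a
    FOUND DegronResult is supplied; otherwise the whole intron is labelled
    ``intron_downstream``.
    """
    degron_len = 0
    if degron is not None and degron.stop1_intron_pos is not None:
        degron_len = degron.stop1_intron_pos + 2
    labels: list[str] = []
    labels += ["utr"] * len(g.utr5)
    labels += ["exon1"] * len(g.exon1)
    labels += ["degron"] * degron_len
    labels += ["intron_downstream"] * (len(g.intron) - degron_len)
    labels += ["exon2"] * len(g.exon2)
    labels += ["utr"] * len(g.utr3)
    return tuple(labels)


def project_to_reference(
    msa: dict[str, str], column_scores: Sequence[float], ref_id: str,
    region_labels: Sequence[str] | None = None,
) -> ConservationTrack:
    """Drop alignment columns where the reference is gapped, index by reference site."""
    if ref_id not in msa:
        raise ValueError(f"reference {ref_id!r} absent from alignment")
    ref = msa[ref_id]
    widths = {len(s) for s in msa.values()}
    if len(widths) != 1:
        raise ValueError("alignment rows have unequal widths")
    if len(column_scores) != len(ref):
        raise ValueError(
            f"{len(column_scores)} column scores for alignment width {len(ref)}"
        )
    keep = [i for i, c in enumerate(ref) if c != "-"]
    scores = np.asarray([column_scores[i] for i in keep], dtype=float)
    if region_labels is None:
        labels: tuple[str, ...] = ("unlabeled",) * len(keep)
    else:
        if len(region_labels) != len(keep):
            raise ValueError(
                f"{len(region_labels)} region labels for {len(keep)} reference sites"
            )
        labels = tuple(region_labels)
    return ConservationTrack(ref_id=ref_id, scores=scores, region_labels=labels)


def column_identity_scores(msa: dict[str, str]) -> np.ndarray:
    """Per-column identity fraction: share of non-gap residues equal to the majority.

    Columns that are entirely gaps score 0.  Majority ties resolve
    alphabetically, which does not change the returned fraction.
    """
    widths = {len(s) for s in msa.values()}
    if len(widths) != 1:
        raise ValueError("alignment rows have unequal widths")
    (width,) = widths
    out = np.zeros(width)
    rows = list(msa.values())
    for j in range(width):
        col = [r[j] for r in rows if r[j] != "-"]
        if not col:
            continue
        best = max(sorted(set(col)), key=col.count)
        out[j] = col.count(best) / len(col)
    return out


def region_means(track: ConservationTrack) -> dict[str, float]:
    """Arithmetic mean score per region label; empty regions are omitted."""
    sums: dict[str, list[float]] = {}
    for s, lab in zip(track.scores, track.region_labels):
        sums.setdefault(lab, []).append(float(s))
    return {lab: float(np.mean(v)) for lab, v in sums.items()}


def window_means(
    track: ConservationTrack, window: int = 32, step: int = 1
) -> list[tuple[int, float, str]]:
    """Sliding-window means as (1-based start, mean, label) tuples.

    A window whose sites all share one region label takes that label;
    windows that straddle region boundaries are labelled ``boundary``.
    """
    n = len(track)
    if window > n:
        raise ValueError(f"window {window} exceeds track length {n}")
    csum = np.concatenate(([0.0], np.cumsum(track.scores)))
    out = []
    for start in range(0, n - window + 1, step):
        mean = (csum[start + window] - csum[start]) / window
        labels = set(track.region_labels[start : start + window])
        label = labels.pop() if len(labels) == 1 else "boundary"
        out.append((start + 1, float(mean), label))
    return out


def read_score_track(path: str | Path) -> np.ndarray:
    """Load a site/score text track (two whitespace-separated columns, 1-based sites).

    Lines starting with '#' or wiggle declarations are skipped; sites must
    be contiguous from 1.
    """
    sites: list[int] = []
    scores: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "fixedStep", "variableStep")):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}: expected 'site score' lines, got {line!r}")
            sites.append(int(parts[0]))
            scores.append(float(parts[1]))
    if sites != list(range(1, len(sites) + 1)):
        raise ValueError(f"{path}: sites must be contiguous from 1")
    return np.asarray(scores)


@dataclass(frozen=True)
class PWM:
    """Position weight matrix with log2-odds scoring against a background."""

    frequencies: np.ndarray  # (width, 4), rows sum to 1
    background: np.ndarray  # (4,), sums to 1
    log_odds: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        freq = np.asarray(self.frequencies, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if freq.ndim != 2 or freq.shape[1] != 4:
            raise ValueError("frequencies must be (width, 4)")
        if not np.allclose(freq.sum(axis=1), 1.0) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("frequencies and background must sum to 1")
        object.__setattr__(self, "frequencies", freq)
        object.__setattr__(self, "background", bg)
        object.__setattr__(self, "log_odds", np.log2(freq / bg[None, :]))

    @property
    def width(self) -> int:
        return self.frequencies.shape[0]

    def score(self, seq: str) -> float:
        if len(seq) != self.width:
            raise ValueError(f"sequence length {len(seq)} != PWM width {self.width}")
        try:
            idx = [_BASE_INDEX[c] for c in seq]
        except KeyError as exc:
            raise ValueError(f"non-ACGT symbol in sequence: {exc}") from exc
        return float(self.log_odds[np.arange(self.width), idx].sum())


def build_pwm(training_seqs: Sequence[str], pseudocount: float = 0.25) -> PWM:
    """Build a PWM from equal-width ACGT sequences.

    Each column gets ``pseudocount`` added per base; the background is the
    pooled base composition of the training set with the same pseudocount.
    """
    if not training_seqs:
        raise ValueError("at least one training sequence is required")
    widths = {len(s) for s in training_seqs}
    if len(widths) != 1:
        raise ValueError(f"training sequences have unequal widths: {sorted(widths)}")
    (width,) = widths
    counts = np.zeros((width, 4))
    for s in training_seqs:
        for j, c in enumerate(s):
            if c not in _BASE_INDEX:
                raise ValueError(f"non-ACGT symbol {c!r} in training sequence")
            counts[j, _BASE_INDEX[c]] += 1
    freq = (counts + pseudocount) / (len(training_seqs) + 4 * pseudocount)
    pooled = counts.sum(axis=0)
    bg = (pooled + pseudocount) / (pooled.sum() + 4 * pseudocount)
    return PWM(frequencies=freq, background=bg)


def pwm_score(pwm: PWM, seq: str) -> float:
    return pwm.score(seq)


def junction_window(seq: str, junction_after: int) -> str:
    """30 nt window around a junction falling after 1-based position ``junction_after``."""
    if junction_after < JUNCTION_FLANK or junction_after > len(seq) - JUNCTION_FLANK:
        raise ValueError(
            f"junction after site {junction_after} leaves less than "
            f"{JUNCTION_FLANK} nt on one side"
        )
    return seq[junction_after - JUNCTION_FLANK : junction_after + JUNCTION_FLANK]


def scan_splice_candidates(
    gene_seq: str, pwm5: PWM, pwm3: PWM, top_k: int = 5
) -> list[tuple[int, int, float]]:
    """Rank candidate (donor, acceptor) junction placements by summed PWM score.

    Every 30 nt window is scored by both matrices; candidate pairs require
    donor < acceptor and are returned as (donor_after, acceptor_after,
    score) sorted by descending score.  Positions are 1-based and mark the
    last site before the junction.
    """
    n = len(gene_seq)
    if n <= JUNCTION_WINDOW:
        raise ValueError(f"gene of {n} nt is too short to scan (need > {JUNCTION_WINDOW})")
    positions = range(JUNCTION_FLANK, n - JUNCTION_FLANK + 1)
    s5 = {p: pwm5.score(junction_window(gene_seq, p)) for p in positions}
    s3 = {p: pwm3.score(junction_window(gene_seq, p)) for p in positions}
    pairs = (
        (d, a, s5[d] + s3[a]) for d in positions for a in positions if d < a
    )
    return nlargest(top_k, pairs, key=lambda t: (t[2], -t[0], -t[1]))
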