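"""Splicing efficiency, translation intensity, and per-kilobase normalisation.

Junction counts feed three summary statistics:

* splicing efficiency  SE = N_EE / N_Total, where the total transcript
  count is bias-corrected as N_Total = N_EE + p*N_EI5 + (1-p)*N_EI3 with
  p = N_EI5 / (N_EI5 + N_EI3).  The correction reflects that the 5' and
  3' exon-intron junctions of the unspliced isoform are unequally
  represented in poly(A)-enriched libraries, so a weighted combination
  of the two (weighted toward whichever junction was actually observed)
  replaces their plain average;
* translation intensity TI = mean(N_EI5, N_EI3, N_Target) — ribosome
  footprint support for the unspliced isoform;
* per-kilobase counts, count / kilobases of processed data, so runs of
  different depth are comparable.

When N_EI5 = N_EI3 = 0 the weight p is undefined and N_Total falls back
to N_EE; when every count is zero SE and TI are reported as undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class JunctionCounts:
    """Reads mapped to the four 40 nt queries (multiplicity-weighted)."""

    n_ee: int
    n_ei5: int
    n_ei3: int
    n_target: int = 0

    def __post_init__(self) -> None:
        for name in ("n_ee", "n_ei5", "n_ei3", "n_target"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class SplicingSummary:
    """Derived splicing statistics; None marks an undefined quantity."""

    p: float | None
    n_total: float
    se: float | None
    ti: float | None
    per_kb: dict[str, float] | None = None

    @property
    def se_rounded(self) -> float | None:
        """SE at display precision (3 decimals)."""
        return None if self.se is None else round(self.se, 3)

    @property
    def ti_rounded(self) -> int | None:
        return None if self.ti is None else round(self.ti)

    def format_se(self) -> str:
        if self.se is None:
            return "-"
        r = round(self.se, 3)
        return f"{int(r)}" if r == int(r) else f"{r:.3f}"

    def format_p(self) -> str:
        if self.p is None:
            return "-"
        r = round(self.p, 3)
        return f"{int(r)}" if r == int(r) else f"{r:.3f}"


def splicing_efficiency(c: JunctionCounts) -> SplicingSummary:
    """Bias-corrected splicing efficiency from junction counts.

    Returns a summary whose ``p``, ``n_total`` and ``se`` fields carry the
    unrounded values; ``se_rounded``/``format_se`` give display precision.
    """
    denom = c.n_ei5 + c.n_ei3
    if denom > 0:
        p: float | None = c.n_ei5 / denom
        n_total = c.n_ee + p * c.n_ei5 + (1 - p) * c.n_ei3
    else:
        p = None
        n_total = float(c.n_ee)
    se = c.n_ee / n_total if n_total > 0 else None
    return SplicingSummary(p=p, n_total=n_total, se=se, ti=translation_intensity(c))


def translation_intensity(c: JunctionCounts) -> float | None:
    """Mean of the three unspliced-query counts (EI5, EI3, Target), unrounded.

    Undefined (None) when all four junction counts are zero, mirroring the
    refusal to summarise runs with no mapped reads at all.
    """
    if c.n_ee == 0 and c.n_ei5 == 0 and c.n_ei3 == 0 and c.n_target == 0:
        return None
    return (c.n_ei5 + c.n_ei3 + c.n_target) / 3.0


def per_kb(count: float, dataset_kilobases: float) -> float:
    """Depth-normalised count per kilobase of retained sequence."""
    if not dataset_kilobases > 0 or math.isnan(dataset_kilobases):
        raise ValueError(f"dataset_kilobases must be positive, got {dataset_kilobases}")
    return count / dataset_kilobases


def per_kb_counts(c: JunctionCounts, dataset_kilobases: float) -> dict[str, float]:
    return {
        "EE": per_kb(c.n_ee, dataset_kilobases),
        "EI5": per_kb(c.n_ei5, dataset_kilobases),
        "EI3": per_kb(c.n_ei3, dataset_kilobases),
        "Target": per_kb(c.n_target, dataset_kilobases),
    }
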