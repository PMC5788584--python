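"""Remmele-Stegner immunoreactivity scoring (IRS) and single-marker
evaluation on a tissue microarray.

The IRS is the product of a percentage-of-positive-cells grade (0-4, in
20-point bins) and a staining-intensity grade (0-3: none, low,
moderate, strong), giving a score from 0 to 12.  A sample is called
positive for a marker at cut-off ``c`` iff its IRS is strictly greater
than ``c``; sensitivity and specificity are computed against the
reference entity (Ewing sarcoma), with Ewing-like sarcomas counted as
non-reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import Performance, TMADataset, ValidationError

#: single-assessment IRS values attainable as a grade product
ATTAINABLE_IRS = frozenset(
    p * i for p in range(5) for i in range(4)
)  # {0, 1, 2, 3, 4, 6, 8, 9, 12}

_PERCENT_EDGES = (20.0, 40.0, 60.0, 80.0)


def percentage_grade(percent_positive: float) -> int:
    """Grade the percentage of marker-positive cells into 5 bins.

    Bin edges at 20/40/60/80, lower-inclusive: 0-19% -> 0, 20-39% -> 1,
    40-59% -> 2, 60-79% -> 3, 80-100% -> 4.
    """
    if not 0 <= percent_positive <= 100:
        raise ValidationError(
            f"percent positive must be in [0, 100], got {percent_positive}"
        )
    return int(np.searchsorted(_PERCENT_EDGES, percent_positive, side="right"))


@dataclass(frozen=True)
class GradePair:
    """A percentage grade (0-4) and an intensity grade (0-3)."""

    percentage_grade: int
    intensity_grade: int

    def __post_init__(self) -> None:
        if self.percentage_grade not in range(5):
            raise ValidationError(f"percentage grade must be 0-4, got {self.percentage_grade}")
        if self.intensity_grade not in range(4):
            raise ValidationError(f"intensity grade must be 0-3, got {self.intensity_grade}")


def irs(grades: GradePair) -> int:
    """The immunoreactivity score: product of the two grades (0-12)."""
    return grades.percentage_grade * grades.intensity_grade


def score_assessment(percent_positive: float, intensity_grade: int) -> int:
    """IRS straight from a raw (percentage, intensity) observation."""
    return irs(GradePair(percentage_grade(percent_positive), intensity_grade))


def aggregate_cores(core_scores: list[int], method: str = "median") -> int:
    """Combine the IRS of up to three TMA cores into one sample score.

    Default is the median (robust to a single failed core), rounded
    half up to an integer; ``max`` and ``mean`` are available.  A
    single score passes through unchanged.
    """
    if not core_scores:
        raise ValidationError("need at least one core score")
    if len(core_scores) > 3:
        raise ValidationError("a sample has at most three cores")
    for s in core_scores:
        if not 0 <= s <= 12:
            raise ValidationError(f"core IRS out of range: {s}")
    if method == "median":
        value = float(np.median(core_scores))
    elif method == "max":
        value = float(max(core_scores))
    elif method == "mean":
        value = float(np.mean(core_scores))
    else:
        raise ValidationError(f"unknown aggregation method {method!r}")
    return int(np.floor(value + 0.5))  # round half up


def _performance_from_calls(positive: np.ndarray, is_reference: np.ndarray) -> Performance:
    tp = int(np.count_nonzero(positive & is_reference))
    fn = int(np.count_nonzero(~positive & is_reference))
    fp = int(np.count_nonzero(positive & ~is_reference))
    tn = int(np.count_nonzero(~positive & ~is_reference))
    return Performance(tp=tp, fn=fn, tn=tn, fp=fp)


def marker_performance(tma: TMADataset, marker: str, cutoff: int) -> Performance:
    """Sensitivity/specificity of a single marker at one cut-off.

    Positive iff IRS > cutoff (strict).  Cut-off -1 means every sample
    is positive, 12 means none.
    """
    if not -1 <= cutoff <= 12:
        raise ValidationError(f"cutoff must be in [-1, 12], got {cutoff}")
    positive = tma.irs(marker) > cutoff
    return _performance_from_calls(positive, tma.is_reference.to_numpy())


def cutoff_sweep(tma: TMADataset, marker: str,
                 cutoffs: range = range(-1, 13)) -> pd.DataFrame:
    """Sensitivity/specificity table of one marker over a cut-off grid."""
    rows = []
    for c in cutoffs:
        perf = marker_performance(tma, marker, c)
        rows.append({"marker": marker, "cutoff": c, **perf.as_dict()})
    return pd.DataFrame(rows)
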