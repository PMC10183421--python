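"""Cohort safe-corridor aggregation and summary statistics.

A per-subject angulated tunnel solution yields a feasible exit interval
[posterior border, anterior border] in signed percent of the lateral
cortical edge.  The cohort *safe corridor* for an angulated orientation is
the intersection of those intervals: its anterior bound is the minimum of
the per-subject anterior borders and its posterior bound the maximum of
the posterior borders, so any point inside it is feasible for every
subject.  The center-center corridor is instead the range (min/max) of the
single per-subject exit locations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import UndefinedStatisticError, FibsafeError

__all__ = [
    "SafeCorridor",
    "Summary",
    "PairedComparison",
    "CorridorReport",
    "cohort_corridor_angulated",
    "cohort_corridor_central",
    "summarize",
    "paired_t_and_pearson",
]


@dataclass
class SafeCorridor:
    orientation: str
    lower: float  # posterior bound, signed %
    upper: float  # anterior bound, signed %
    mode: str  # "intersection" (angulated) or "range" (center-center)
    empty: bool = False
    n_subjects: int = 0
    n_infeasible: int = 0

    def to_dict(self) -> dict:
        return {
            "orientation": self.orientation,
            "lower_pct": self.lower,
            "upper_pct": self.upper,
            "mode": self.mode,
            "empty": self.empty,
            "n_subjects": self.n_subjects,
            "n_infeasible": self.n_infeasible,
        }


@dataclass
class Summary:
    n: int
    mean: float
    sd: float
    min: float
    max: float

    def to_dict(self) -> dict:
        return {"n": self.n, "mean": self.mean, "sd": self.sd, "min": self.min, "max": self.max}


@dataclass
class PairedComparison:
    n: int
    t: float
    t_p: float
    r: float
    r_p: float
    degenerate_t: bool = False  # constant paired differences
    degenerate_r: bool = False  # zero variance in x or y

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "t": self.t,
            "t_p": self.t_p,
            "r": self.r,
            "r_p": self.r_p,
            "degenerate_t": self.degenerate_t,
            "degenerate_r": self.degenerate_r,
        }


@dataclass
class CorridorReport:
    """Cohort-level corridor and central-alignment summary."""

    corridors: dict  # orientation -> SafeCorridor
    central: dict  # orientation -> Summary of central/single exits
    n_subjects: int
    n_infeasible: int

    def to_dict(self) -> dict:
        return {
            "corridors": {k: v.to_dict() for k, v in self.corridors.items()},
            "central": {k: v.to_dict() for k, v in self.central.items()},
            "n_subjects": self.n_subjects,
            "n_infeasible": self.n_infeasible,
        }


def cohort_corridor_angulated(
    intervals: Sequence[tuple[float, float]],
    orientation: str = "",
    mode: str = "intersection",
    n_infeasible: int = 0,
) -> SafeCorridor:
    """Cohort corridor from per-subject (posterior, anterior) border pairs.

    ``mode="intersection"`` (default) intersects all per-subject feasible
    intervals; an empty intersection is returned flagged, not raised.
    ``mode="range"`` pools the union range instead (exposed for
    comparison).
    """
    if len(intervals) == 0:
        raise FibsafeError("corridor requires at least one feasible subject")
    lowers = np.array([iv[0] for iv in intervals], dtype=float)
    uppers = np.array([iv[1] for iv in intervals], dtype=float)
    if np.any(lowers > uppers):
        raise FibsafeError("per-subject interval with posterior > anterior border")
    if mode == "intersection":
        lower = float(lowers.max())
        upper = float(uppers.min())
    elif mode == "range":
        lower = float(lowers.min())
        upper = float(uppers.max())
    else:
        raise ValueError(f"unknown corridor mode {mode!r}")
    return SafeCorridor(
        orientation=orientation,
        lower=lower,
        upper=upper,
        mode=mode,
        empty=lower > upper,
        n_subjects=len(intervals),
        n_infeasible=n_infeasible,
    )


def cohort_corridor_central(
    locations: Sequence[float],
    orientation: str = "center_center",
    n_infeasible: int = 0,
) -> SafeCorridor:
    """Center-center corridor: min/max of the per-subject exit locations."""
    if len(locations) == 0:
        raise FibsafeError("corridor requires at least one location")
    arr = np.asarray(locations, dtype=float)
    return SafeCorridor(
        orientation=orientation,
        lower=float(arr.min()),
        upper=float(arr.max()),
        mode="range",
        empty=False,
        n_subjects=len(arr),
        n_infeasible=n_infeasible,
    )


def summarize(values: Iterable[float]) -> Summary:
    """Sample mean, sd (n-1 denominator) and range."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise UndefinedStatisticError(
            f"summarize needs >= 2 values for the sd, got {arr.size}"
        )
    return Summary(
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
        min=float(arr.min()),
        max=float(arr.max()),
    )


def paired_t_and_pearson(x: Sequence[float], y: Sequence[float]) -> PairedComparison:
    """Two-sided paired t-test on x - y plus Pearson correlation of (x, y).

    Degenerate inputs (constant differences, or zero variance in either
    variable) are flagged and reported with t = 0 / r = nan and p = 1
    rather than raised, matching descriptive-cohort usage.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise UndefinedStatisticError("paired test needs equal-length vectors, n >= 3")
    diff = x - y
    degenerate_t = bool(np.allclose(diff, diff[0]))
    if degenerate_t:
        t_stat, t_p = 0.0, 1.0
    else:
        t_stat, t_p = sps.ttest_rel(x, y)
    degenerate_r = bool(np.allclose(x, x[0]) or np.allclose(y, y[0]))
    if degenerate_r:
        r, r_p = float("nan"), 1.0
    else:
        r, r_p = sps.pearsonr(x, y)
    return PairedComparison(
        n=int(x.size),
        t=float(t_stat),
        t_p=float(t_p),
        r=float(r),
        r_p=float(r_p),
        degenerate_t=degenerate_t,
        degenerate_r=degenerate_r,
    )
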