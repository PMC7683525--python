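"""The Stability Index: a cumulative-distribution distance on time-of-day activity.

For one behavior on one day, the minute-level amounts ``A(x)`` (``x`` =
1..M, M = 1440) are summarized by their normalized cumulative sum

    C(x) = sum_{i<=x} A(i) / sum_{i<=M} A(i),

the fraction of the day's activity done by minute ``x``.  Two days are
compared by the mean absolute difference of their cumulatives,

    D(d1, d2) = (1/M) * sum_x |C_d1(x) - C_d2(x)|,

and the Stability Index of a multi-day period P is

    SI(P) = 1 - median{ D(i, j) : i, j in P, i != j }

over unordered day pairs.  SI lies in (0, 1]; a day whose schedule merely
slides by delta minutes moves D by at most delta/M, which is what makes the
metric robust to small routine shifts where hourly histogram comparison is
not (see :func:`hourly_raw_distance`).

Days with zero total activity have no defined cumulative distribution and
are excluded from the pair set rather than imputed.

``n_minutes`` is a parameter (default 1440) so that exhaustive oracle
checks can run on tiny instances; all production use is at 1440.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .behavior_data import DayActivityVector

__all__ = [
    "NormalizedCumulative",
    "StabilityResult",
    "normalized_cumsum",
    "absolute_cumsum",
    "day_pair_distance",
    "stability_index",
    "absolute_stability_index",
    "hourly_raw_distance",
]


@dataclass
class NormalizedCumulative:
    """Per-day normalized cumulative distribution; undefined for an empty day."""

    values: np.ndarray | None
    defined: bool
    n_minutes: int

    def __post_init__(self) -> None:
        if self.defined:
            assert self.values is not None and len(self.values) == self.n_minutes


@dataclass
class StabilityResult:
    """Stability Index of one behavior over a set of days.

    ``si`` is ``None`` when fewer than two days had any activity.  For the
    absolute (un-normalized) variant ``si`` may fall outside [0, 1];
    ``median_distance`` carries the raw median pair distance either way.
    """

    behavior: str | None
    si: float | None
    n_days_used: int
    n_pairs: int
    median_distance: float | None = None


def _amounts(day: DayActivityVector | np.ndarray | Sequence[float]) -> np.ndarray:
    if isinstance(day, DayActivityVector):
        return day.amounts
    a = np.asarray(day, dtype=float)
    if a.ndim != 1:
        raise ValueError("day amounts must be one-dimensional")
    return a


def normalized_cumsum(
    day: DayActivityVector | np.ndarray | Sequence[float],
) -> NormalizedCumulative:
    """Normalized cumulative sum of a day's minute amounts.

    ``values[x-1]`` is the fraction of the day's total activity accumulated
    by minute ``x``; it is non-decreasing and reaches exactly 1 at the last
    minute.  A day with zero total yields ``defined=False``.
    """
    a = _amounts(day)
    if np.any(~np.isfinite(a)):
        raise ValueError("day amounts contain NaN or infinity")
    if np.any(a < 0):
        raise ValueError("day amounts must be non-negative")
    total = a.sum()
    if total <= 0:
        return NormalizedCumulative(values=None, defined=False, n_minutes=len(a))
    values = np.cumsum(a) / total
    values[-1] = 1.0  # guard the top against accumulated roundoff
    return NormalizedCumulative(values=values, defined=True, n_minutes=len(a))


def absolute_cumsum(day: DayActivityVector | np.ndarray | Sequence[float]) -> np.ndarray:
    """Absolute (un-normalized) cumulative sum C'(x) of a day's amounts."""
    a = _amounts(day)
    if np.any(~np.isfinite(a)):
        raise ValueError("day amounts contain NaN or infinity")
    return np.cumsum(a)


def day_pair_distance(c1: NormalizedCumulative, c2: NormalizedCumulative) -> float:
    """Mean absolute difference between two cumulative distributions.

    Symmetric, bounded by (M-1)/M for normalized inputs, and NaN when either
    day's distribution is undefined (the undefinedness propagates; it is not
    an error).
    """
    if c1.n_minutes != c2.n_minutes:
        raise ValueError(f"mismatched day lengths {c1.n_minutes} vs {c2.n_minutes}")
    if not (c1.defined and c2.defined):
        return math.nan
    return float(np.abs(c1.values - c2.values).mean())


def _si_from_cumulatives(curves: list[np.ndarray], n_minutes: int) -> tuple[float | None, int, int]:
    """(1 - median pair distance, n_days_used, n_pairs) over defined curves."""
    n = len(curves)
    n_pairs = n * (n - 1) // 2
    if n < 2:
        return None, n, n_pairs
    stacked = np.stack(curves)
    iu, ju = np.triu_indices(n, k=1)
    dists = np.abs(stacked[iu] - stacked[ju]).mean(axis=1)
    return float(np.median(dists)), n, n_pairs


def stability_index(
    days: Sequence[DayActivityVector] | Sequence[np.ndarray],
) -> StabilityResult:
    """Stability Index over a period of days of one behavior.

    Zero-activity days are excluded from the pair set; with fewer than two
    usable days the index is undefined (``si=None``).
    """
    behavior = _check_homogeneous(days)
    curves = []
    n_minutes = None
    for d in days:
        c = normalized_cumsum(d)
        n_minutes = c.n_minutes
        if c.defined:
            curves.append(c.values)
    median, n_used, n_pairs = _si_from_cumulatives(curves, n_minutes or 0)
    si = None if median is None else 1.0 - median
    return StabilityResult(
        behavior=behavior, si=si, n_days_used=n_used, n_pairs=n_pairs, median_distance=median
    )


def absolute_stability_index(
    days: Sequence[DayActivityVector] | Sequence[np.ndarray],
) -> StabilityResult:
    """1 - median pair distance on *absolute* cumulative sums.

    A volume-sensitive diagnostic variant: unlike the normalized index it is
    not invariant to rescaling a day's amounts and may fall outside [0, 1].
    Zero-total days are excluded as in the normalized index so the two
    variants are computed over the same pair set.
    """
    behavior = _check_homogeneous(days)
    curves = []
    n_minutes = None
    for d in days:
        a = _amounts(d)
        n_minutes = len(a)
        if a.sum() > 0:
            curves.append(absolute_cumsum(a))
    median, n_used, n_pairs = _si_from_cumulatives(curves, n_minutes or 0)
    si = None if median is None else 1.0 - median
    return StabilityResult(
        behavior=behavior, si=si, n_days_used=n_used, n_pairs=n_pairs, median_distance=median
    )


def _check_homogeneous(days: Sequence) -> str | None:
    behaviors = {d.behavior for d in days if isinstance(d, DayActivityVector)}
    participants = {d.participant_id for d in days if isinstance(d, DayActivityVector)}
    if len(behaviors) > 1 or len(participants) > 1:
        raise ValueError(
            f"stability index requires one participant/behavior, got {participants}/{behaviors}"
        )
    return next(iter(behaviors)) if behaviors else None


def hourly_raw_distance(
    day1: DayActivityVector | np.ndarray | Sequence[float],
    day2: DayActivityVector | np.ndarray | Sequence[float],
) -> float:
    """Total-variation distance between the two days' hourly activity profiles.

    Baseline for contrast with :func:`day_pair_distance`: aggregating into
    hourly bins makes the distance saturate when an event slides across an
    hour boundary by a couple of minutes, exactly the shift-sensitivity the
    cumulative-distribution distance avoids.  NaN if either day is empty.
    """
    a1, a2 = _amounts(day1), _amounts(day2)
    if len(a1) != len(a2):
        raise ValueError("mismatched day lengths")
    if len(a1) % 24 != 0:
        raise ValueError("day length must be divisible by 24 for hourly aggregation")
    t1, t2 = a1.sum(), a2.sum()
    if t1 <= 0 or t2 <= 0:
        return math.nan
    h1 = a1.reshape(24, -1).sum(axis=1) / t1
    h2 = a2.reshape(24, -1).sum(axis=1) / t2
    return float(0.5 * np.abs(h1 - h2).sum())
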