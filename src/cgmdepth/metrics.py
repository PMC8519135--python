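"""Primary glycemic outcome metrics per analysis interval.

Three families, computed over whatever interval the caller passes (a whole
intervention phase or its nocturnal window):

* descriptive: n, mean, median, min, max, range;
* glycemic variation: sample SD, variance, coefficient of variation
  (CV = 100 * SD / mean);
* glycemic control (ADA 2020 consensus ranges, mmol/L):
  time under range level 2 (< 3.0), level 1 ([3.0, 3.9)),
  time in range (narrow [3.9, 7.8], wide [3.9, 10.0]),
  time above range (> 7.8, > 10.0), each as a percentage of samples.

Level-3 hypoglycemia is a clinical event definition (assistance required) and
cannot be computed from CGM values; it is carried only as an annotation.
The "ri95" interval is a normal reference interval, mean +/- 1.96 * SD — a
band expected to contain ~95% of individual readings, not a confidence
interval of the mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from ._utils import round_half_up
from .trace import GlucoseTrace
from .windows import (
    NOCTURNAL_WINDOW,
    ClockWindow,
    InterventionSchedule,
    extract_clock_window,
    nights_of,
    split_by_intervention,
)

__all__ = [
    "DescriptiveStats",
    "ControlStats",
    "descriptive",
    "reference_interval_95",
    "time_in_ranges",
    "interval_report",
]

# ADA 2020 thresholds, mmol/L
LEVEL2_HYPO = 3.0
LEVEL1_HYPO = 3.9
TIR_NARROW_HIGH = 7.8
TIR_WIDE_HIGH = 10.0


@dataclass(frozen=True)
class DescriptiveStats:
    """Descriptive + variation statistics of one glucose interval (mmol/L)."""

    n: int
    mean: float
    median: float
    min: float
    max: float
    range: float
    sd: float  # sample SD (n-1); nan when n == 1
    variance: float
    cv_percent: float


@dataclass(frozen=True)
class ControlStats:
    """Glycemic-control range occupancy, percent of samples."""

    tur_l2: float  # < 3.0 (level 2 hypoglycemia)
    tur_l1: float  # [3.0, 3.9) (level 1 hypoglycemia)
    tir_39_78: float  # [3.9, 7.8]
    tir_39_100: float  # [3.9, 10.0]
    tar_78: float  # > 7.8
    tar_100: float  # > 10.0


def descriptive(values) -> DescriptiveStats:
    """Descriptive statistics; SD/variance/CV are nan for a single sample."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("descriptive statistics need at least one value")
    mean = float(np.mean(arr))
    if arr.size >= 2:
        sd = float(np.std(arr, ddof=1))
        variance = sd**2
        cv = 100.0 * sd / mean
    else:
        sd = variance = cv = float("nan")
    return DescriptiveStats(
        n=int(arr.size),
        mean=mean,
        median=float(np.median(arr)),
        min=float(np.min(arr)),
        max=float(np.max(arr)),
        range=float(np.max(arr) - np.min(arr)),
        sd=sd,
        variance=variance,
        cv_percent=cv,
    )


def reference_interval_95(
    stats: DescriptiveStats, *, ndigits: Optional[int] = 1
) -> Tuple[float, float]:
    """Normal 95% reference interval mean +/- 1.96*SD, floored at 0.

    Undefined (nan, nan) when the SD is undefined (single sample).
    """
    if not np.isfinite(stats.sd):
        return (float("nan"), float("nan"))
    low = max(stats.mean - 1.96 * stats.sd, 0.0)
    high = stats.mean + 1.96 * stats.sd
    if ndigits is not None:
        low, high = round_half_up(low, ndigits), round_half_up(high, ndigits)
    return (low, high)


def time_in_ranges(values) -> ControlStats:
    """Range-occupancy percentages with ADA 2020 boundary conventions.

    Boundaries follow the defining inequalities exactly: 3.9 counts toward
    TIR, 7.8 toward the narrow TIR, 10.0 toward the wide TIR. The four
    mutually exclusive classes (< 3.0, [3.0, 3.9), [3.9, 7.8], > 7.8) sum to
    100% exactly before rounding.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("time-in-range needs at least one value")
    n = arr.size
    pct = lambda mask: 100.0 * np.count_nonzero(mask) / n
    return ControlStats(
        tur_l2=pct(arr < LEVEL2_HYPO),
        tur_l1=pct((arr >= LEVEL2_HYPO) & (arr < LEVEL1_HYPO)),
        tir_39_78=pct((arr >= LEVEL1_HYPO) & (arr <= TIR_NARROW_HIGH)),
        tir_39_100=pct((arr >= LEVEL1_HYPO) & (arr <= TIR_WIDE_HIGH)),
        tar_78=pct(arr > TIR_NARROW_HIGH),
        tar_100=pct(arr > TIR_WIDE_HIGH),
    )


def _row(
    label: str,
    scope: str,
    trace: GlucoseTrace,
    periods: int,
    expected_n: int,
    ndigits: Optional[int],
) -> dict:
    stats = descriptive(trace.values)
    ctrl = time_in_ranges(trace.values)
    lo, hi = reference_interval_95(stats, ndigits=ndigits)
    r = lambda x: round_half_up(x, ndigits) if ndigits is not None else x
    missing = 100.0 * max(expected_n - stats.n, 0) / expected_n if expected_n else 0.0
    return {
        "intervention": label,
        "scope": scope,
        "n": stats.n,
        "periods": periods,
        "median": r(stats.median),
        "min": r(stats.min),
        "max": r(stats.max),
        "range": r(stats.range),
        "mean": r(stats.mean),
        "sd": r(stats.sd),
        "variance": r(stats.variance),
        "cv_percent": r(stats.cv_percent),
        "ri95_low": lo,
        "ri95_high": hi,
        "tur_l2_pct": r(ctrl.tur_l2),
        "tur_l1_pct": r(ctrl.tur_l1),
        "tir_39_78_pct": r(ctrl.tir_39_78),
        "tir_39_100_pct": r(ctrl.tir_39_100),
        "tar_78_pct": r(ctrl.tar_78),
        "tar_100_pct": r(ctrl.tar_100),
        "missing_pct": r(missing),
    }


def interval_report(
    trace: GlucoseTrace,
    schedule: Optional[InterventionSchedule] = None,
    window: ClockWindow = NOCTURNAL_WINDOW,
    *,
    ndigits: Optional[int] = 1,
    level3_note: str = "",
) -> pd.DataFrame:
    """Per-intervention report: one total + one nocturnal row each.

    ``periods`` counts distinct calendar dates for total rows and distinct
    nights for nocturnal rows. ``missing_pct`` compares the observed sample
    count with the count the cadence would put in the row's span; percentage
    metrics themselves use observed samples only. Level-3 hypoglycemia is a
    clinical event definition that CGM values cannot yield; ``level3_note``
    is carried through as an annotation column, never computed. Without a
    schedule the whole trace is one phase labeled ``"all"``. Values are
    rounded to report precision (``ndigits=None`` for full precision).
    Empty groups are skipped.
    """
    if schedule is None:
        groups = {"all": trace}
        order = ["all"]
    else:
        groups = split_by_intervention(trace, schedule)
        order = [lbl for lbl in groups.keys()]
    rows = []
    for label in order:
        group = groups[label]
        if len(group) == 0:
            continue
        n_days = len(pd.unique(group.times.normalize()))
        span_min = (group.end - group.start).total_seconds() / 60.0
        expected_total = int(round(span_min / group.cadence_min)) + 1
        rows.append(_row(label, "total", group, n_days, expected_total, ndigits))
        nights = nights_of(group, window)
        if nights:
            nocturnal = extract_clock_window(group, window)
            expected_night = sum(nt.expected_n for nt in nights)
            rows.append(_row(label, str(window), nocturnal, len(nights), expected_night, ndigits))
    frame = pd.DataFrame(rows)
    if len(frame):
        frame["level3_hypoglycemia"] = level3_note
    return frame
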