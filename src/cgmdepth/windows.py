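"""Intervention segmentation and clock-window (nocturnal) extraction.

Diet and physical activity confound daytime glucose, so analyses that compare
interventions are run both on whole segments and on the 01:00-05:00 clock
window, when neither is active. Conventions are half-open throughout:
clock windows ``[start, end)`` (48 samples/night at 5-minute cadence for a
4-hour window) and intervention segments ``[start, end)``, so a sample on a
boundary belongs to the later segment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, time
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .trace import GlucoseTrace

__all__ = [
    "ClockWindow",
    "NOCTURNAL_WINDOW",
    "Intervention",
    "InterventionSchedule",
    "Night",
    "extract_clock_window",
    "split_by_intervention",
    "nights_of",
    "fill_single_gaps",
    "UNASSIGNED_LABEL",
]

log = logging.getLogger(__name__)

UNASSIGNED_LABEL = "unassigned"

#: Fraction of expected samples a night needs to enter spectral/CUSUM analyses.
DEFAULT_COMPLETENESS = 0.8


@dataclass(frozen=True)
class ClockWindow:
    """Half-open time-of-day window ``[start, end)``; may wrap midnight."""

    start: time
    end: time

    def __post_init__(self) -> None:
        if self.start == self.end:
            raise ValueError("clock window must be non-empty")

    @classmethod
    def parse(cls, text: str) -> "ClockWindow":
        """Parse ``"01:00-05:00"``."""
        try:
            a, b = text.split("-")
            return cls(time.fromisoformat(a.strip()), time.fromisoformat(b.strip()))
        except ValueError as exc:
            raise ValueError(f"cannot parse clock window {text!r} (expected 'HH:MM-HH:MM')") from exc

    @property
    def wraps_midnight(self) -> bool:
        return self.end <= self.start

    def duration_minutes(self) -> float:
        a = self.start.hour * 60 + self.start.minute + self.start.second / 60
        b = self.end.hour * 60 + self.end.minute + self.end.second / 60
        return (b - a) % (24 * 60)

    def contains(self, tod: time) -> bool:
        if self.wraps_midnight:
            return tod >= self.start or tod < self.end
        return self.start <= tod < self.end

    def mask(self, times: pd.DatetimeIndex) -> np.ndarray:
        tod = times.hour * 3600 + times.minute * 60 + times.second
        a = self.start.hour * 3600 + self.start.minute * 60 + self.start.second
        b = self.end.hour * 3600 + self.end.minute * 60 + self.end.second
        if self.wraps_midnight:
            return (tod >= a) | (tod < b)
        return (tod >= a) & (tod < b)

    def __str__(self) -> str:
        return f"{self.start:%H:%M}-{self.end:%H:%M}"


#: The default nocturnal analysis window.
NOCTURNAL_WINDOW = ClockWindow(time(1, 0), time(5, 0))


@dataclass(frozen=True)
class Intervention:
    """A labeled diet/medication phase, half-open ``[start, end)``."""

    label: str
    start: pd.Timestamp
    end: pd.Timestamp
    dose_text: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", pd.Timestamp(self.start))
        object.__setattr__(self, "end", pd.Timestamp(self.end))
        if not self.start < self.end:
            raise ValueError(f"intervention {self.label!r}: start must precede end")


@dataclass
class InterventionSchedule:
    """Ordered intervention phases for one patient."""

    interventions: List[Intervention]
    patient_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.interventions = sorted(self.interventions, key=lambda iv: iv.start)

    def overlaps(self) -> List[tuple]:
        """Pairs of consecutive interventions that overlap in time."""
        out = []
        for a, b in zip(self.interventions, self.interventions[1:]):
            if b.start < a.end:
                out.append((a.label, b.label))
        return out

    @property
    def labels(self) -> List[str]:
        return [iv.label for iv in self.interventions]

    @classmethod
    def from_csv(cls, path: Union[str, Path], *, patient_id: Optional[str] = None) -> "InterventionSchedule":
        frame = pd.read_csv(path)
        return cls._from_frame(frame, patient_id)

    @classmethod
    def from_yaml(cls, path: Union[str, Path], *, patient_id: Optional[str] = None) -> "InterventionSchedule":
        data = yaml.safe_load(Path(path).read_text())
        rows = data["interventions"] if isinstance(data, dict) else data
        frame = pd.DataFrame(rows)
        return cls._from_frame(frame, patient_id or (data.get("patient_id") if isinstance(data, dict) else None))

    @classmethod
    def _from_frame(cls, frame: pd.DataFrame, patient_id: Optional[str]) -> "InterventionSchedule":
        required = {"label", "start", "end"}
        if not required.issubset(frame.columns):
            raise ValueError(f"schedule needs columns {sorted(required)}, found {list(frame.columns)}")
        ivs = [
            Intervention(
                str(r["label"]),
                pd.Timestamp(r["start"]),
                pd.Timestamp(r["end"]),
                str(r.get("dose_text", "") or ""),
            )
            for _, r in frame.iterrows()
        ]
        return cls(ivs, patient_id=patient_id)


def extract_clock_window(trace: GlucoseTrace, window: ClockWindow = NOCTURNAL_WINDOW) -> GlucoseTrace:
    """Keep samples whose time of day falls in ``[start, end)`` on any date."""
    if len(trace) == 0:
        return trace
    return trace.select(window.mask(trace.times))


def split_by_intervention(
    trace: GlucoseTrace, schedule: InterventionSchedule
) -> Dict[str, GlucoseTrace]:
    """Partition a trace by intervention phase.

    Every sample goes to the unique intervention whose ``[start, end)``
    contains it; samples outside all phases are returned under the reserved
    ``"unassigned"`` label (only when any exist). Overlapping phases are an
    error because assignment would be ambiguous.
    """
    overlaps = schedule.overlaps()
    if overlaps:
        raise ValueError(f"overlapping interventions: {overlaps}")
    out: Dict[str, GlucoseTrace] = {}
    assigned = np.zeros(len(trace), dtype=bool)
    for iv in schedule.interventions:
        mask = np.asarray((trace.times >= iv.start) & (trace.times < iv.end))
        out[iv.label] = trace.select(mask)
        assigned |= mask
    if not assigned.all():
        out[UNASSIGNED_LABEL] = trace.select(~assigned)
    return out


def fill_single_gaps(trace: GlucoseTrace) -> GlucoseTrace:
    """Linearly interpolate isolated missing samples onto the cadence grid.

    Only holes of exactly one missing sample (neighbor spacing of twice the
    cadence) are filled, with the mean of the flanking values; longer gaps
    are left alone. Off by default everywhere — the analyses subset rather
    than resample — but available where a single dropout would otherwise
    break a night's uniform grid.
    """
    if len(trace) < 2:
        return trace
    dt_min = np.diff(trace.times.asi8) / 60e9
    holes = np.flatnonzero(np.isclose(dt_min, 2.0 * trace.cadence_min))
    if holes.size == 0:
        return trace
    times = list(trace.times)
    values = list(trace.values)
    clipped = list(trace.clipped)
    for i in reversed(holes):
        mid_t = trace.times[i] + pd.Timedelta(minutes=trace.cadence_min)
        times.insert(i + 1, mid_t)
        values.insert(i + 1, 0.5 * (trace.values[i] + trace.values[i + 1]))
        clipped.insert(i + 1, False)
    return GlucoseTrace(
        pd.DatetimeIndex(times), values, clipped,
        cadence_min=trace.cadence_min, patient_id=trace.patient_id,
    )


@dataclass(frozen=True)
class Night:
    """One calendar night's clock-window sub-trace with completeness info."""

    date: pd.Timestamp  # calendar date the window starts on
    trace: GlucoseTrace
    expected_n: int

    @property
    def n(self) -> int:
        return len(self.trace)

    @property
    def completeness(self) -> float:
        return self.n / self.expected_n if self.expected_n else 0.0

    @property
    def complete(self) -> bool:
        """All expected samples present."""
        return self.n == self.expected_n

    def eligible(self, threshold: float = DEFAULT_COMPLETENESS) -> bool:
        """Enough samples to include in spectral/CUSUM analyses."""
        return self.completeness >= threshold


def nights_of(
    trace: GlucoseTrace,
    window: ClockWindow = NOCTURNAL_WINDOW,
) -> List[Night]:
    """Per-date nocturnal windows, one entry per date with >= 1 sample.

    A night is labeled by the calendar date its window starts on; for windows
    wrapping midnight, samples before midnight keep their own date and samples
    after midnight are attributed to the previous date.
    """
    sub = extract_clock_window(trace, window)
    if len(sub) == 0:
        return []
    dates = sub.times.normalize()
    if window.wraps_midnight:
        # samples in [00:00, end) belong to the previous night's date
        in_morning = np.array([t < window.end for t in sub.times.time])
        dates = pd.DatetimeIndex(np.where(in_morning, dates - pd.Timedelta(days=1), dates))
    expected = int(window.duration_minutes() // trace.cadence_min)
    nights = []
    for date in pd.unique(dates):
        mask = np.asarray(dates == date)
        nights.append(Night(pd.Timestamp(date), sub.select(mask), expected))
    nights.sort(key=lambda nt: nt.date)
    return nights
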