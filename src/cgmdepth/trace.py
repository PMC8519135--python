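"""Core container for continuous glucose monitoring (CGM) traces.

A CGM sensor reports an interstitial glucose estimate on a nominal 5-minute
grid (288 samples per day). Values are held internally in mmol/L. The sensor
is validated only above 2.2 mmol/L; below-range readings are floored at that
value and flagged ``clipped`` rather than dropped, because omitting them
would bias every descriptive statistic toward euglycemia.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

#: Validated lower limit of the CGM sensor, mmol/L. Readings below this are
#: reported by the device as "Low" and are floored here, not discarded.
CGM_FLOOR_MMOL = 2.2

#: Device ceiling, mmol/L ("High" flag); no analysis in this package uses it
#: as a clamp, it only gives "High" rows a numeric stand-in.
CGM_CEILING_MMOL = 22.2

#: Nominal sampling interval of the sensor, minutes.
DEFAULT_CADENCE_MIN = 5.0


class GlucoseSample(NamedTuple):
    """One timestamped glucose estimate."""

    timestamp: pd.Timestamp
    value: float  # mmol/L
    clipped: bool


@dataclass(frozen=True)
class PatientContext:
    """Per-patient metadata needed for rate arithmetic and labeling."""

    weight_kg: float
    age_y: Optional[float] = None
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.weight_kg) or self.weight_kg <= 0:
            raise ValueError(f"weight_kg must be positive, got {self.weight_kg!r}")


class GlucoseTrace:
    """Ordered, strictly increasing timestamped glucose series in mmol/L.

    Parameters
    ----------
    times
        Sample timestamps (anything ``pd.to_datetime`` accepts). Naive local
        device clock time; clock-based windows (01:00-05:00) rely on this.
    values
        Glucose concentrations, mmol/L. Must be finite and positive.
    clipped
        Boolean flags marking samples that were floored at the sensor's
        validated lower limit. Defaults to all-False.
    cadence_min
        Nominal sampling interval in minutes (default 5).
    patient_id
        Opaque label carried through reports.
    """

    unit = "mmol/L"

    def __init__(
        self,
        times,
        values,
        clipped=None,
        *,
        cadence_min: float = DEFAULT_CADENCE_MIN,
        patient_id: Optional[str] = None,
    ) -> None:
        times = pd.DatetimeIndex(pd.to_datetime(times))
        values = np.asarray(values, dtype=float)
        if clipped is None:
            clipped = np.zeros(len(values), dtype=bool)
        clipped = np.asarray(clipped, dtype=bool)
        if not (len(times) == len(values) == len(clipped)):
            raise ValueError("times, values and clipped must have equal length")
        if len(times) > 1:
            deltas = np.diff(times.asi8)
            if np.any(deltas <= 0):
                raise ValueError("timestamps must be strictly increasing (no duplicates)")
        if len(values) and (not np.all(np.isfinite(values)) or np.any(values <= 0)):
            raise ValueError("glucose values must be finite and positive")
        if not np.isfinite(cadence_min) or cadence_min <= 0:
            raise ValueError(f"cadence_min must be positive, got {cadence_min!r}")
        self._times = times
        self._values = values
        self._clipped = clipped
        self.cadence_min = float(cadence_min)
        self.patient_id = patient_id

    # -- basic accessors -------------------------------------------------
    @property
    def times(self) -> pd.DatetimeIndex:
        return self._times

    @property
    def values(self) -> np.ndarray:
        return self._values

    @property
    def clipped(self) -> np.ndarray:
        return self._clipped

    def __len__(self) -> int:
        return len(self._values)

    @property
    def start(self) -> pd.Timestamp:
        return self._times[0]

    @property
    def end(self) -> pd.Timestamp:
        return self._times[-1]

    @property
    def samples(self) -> list[GlucoseSample]:
        return [
            GlucoseSample(t, float(v), bool(c))
            for t, v, c in zip(self._times, self._values, self._clipped)
        ]

    def minutes_since_start(self) -> np.ndarray:
        """Elapsed minutes of each sample relative to the first."""
        if len(self) == 0:
            return np.array([])
        return (self._times.asi8 - self._times.asi8[0]) / 60e9

    # -- derived constructors --------------------------------------------
    def select(self, mask) -> "GlucoseTrace":
        """Sub-trace at boolean mask / integer positions, metadata preserved."""
        mask = np.asarray(mask)
        return GlucoseTrace(
            self._times[mask],
            self._values[mask],
            self._clipped[mask],
            cadence_min=self.cadence_min,
            patient_id=self.patient_id,
        )

    def with_values(self, values, clipped=None) -> "GlucoseTrace":
        return GlucoseTrace(
            self._times,
            values,
            self._clipped if clipped is None else clipped,
            cadence_min=self.cadence_min,
            patient_id=self.patient_id,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self._times,
                "glucose_mmol_l": self._values,
                "clipped": self._clipped.astype(int),
            }
        )

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        *,
        cadence_min: float = DEFAULT_CADENCE_MIN,
        patient_id: Optional[str] = None,
    ) -> "GlucoseTrace":
        return cls(
            frame["timestamp"],
            frame["glucose_mmol_l"],
            frame["clipped"].astype(bool) if "clipped" in frame else None,
            cadence_min=cadence_min,
            patient_id=patient_id,
        )

    def equals(self, other: "GlucoseTrace", tol: float = 0.01) -> bool:
        return (
            len(self) == len(other)
            and bool((self._times == other._times).all())
            and bool(np.all(np.abs(self._values - other._values) <= tol))
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        span = f"{self.start}..{self.end}" if len(self) else "empty"
        pid = f", patient={self.patient_id!r}" if self.patient_id else ""
        return f"GlucoseTrace(n={len(self)}, {span}, cadence={self.cadence_min:g} min{pid})"


def concat_traces(traces: Sequence[GlucoseTrace]) -> GlucoseTrace:
    """Concatenate chronologically ordered, non-overlapping traces."""
    traces = [t for t in traces if len(t)]
    if not traces:
        raise ValueError("nothing to concatenate")
    times = np.concatenate([t.times.asi8 for t in traces])
    values = np.concatenate([t.values for t in traces])
    clipped = np.concatenate([t.clipped for t in traces])
    return GlucoseTrace(
        pd.DatetimeIndex(times.astype("datetime64[ns]")),
        values,
        clipped,
        cadence_min=traces[0].cadence_min,
        patient_id=traces[0].patient_id,
    )
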