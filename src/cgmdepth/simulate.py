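"""Synthetic CGM traces and starch-load curves with known ground truth.

Real CGM traces from the patient population this package targets are not
publicly available, so every analysis stage is validated against simulated
traces whose spectral content, range occupancy and event times are known by
construction. A trace is

    value(t) = baseline + sum_j A_j * sin(2*pi*f_j*t_h + phi_j)
             + event terms + noise,

floored at the 2.2 mmol/L sensor limit, sampled on a half-open grid
``t = 0, c, 2c, ... < duration`` (exactly 288 samples/day at 5-minute
cadence). Hypoglycemic dips are smooth raised-cosine negative excursions;
meal excursions are asymmetric rise/decay triangles peaking at a quarter of
their duration. Noise is Gaussian per sample, optionally AR(1)-autocorrelated.
All randomness flows from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .trace import CGM_FLOOR_MMOL, DEFAULT_CADENCE_MIN, GlucoseTrace

__all__ = [
    "SinusoidComponent",
    "TraceEvent",
    "SyntheticConfig",
    "LoadCurveSpec",
    "generate_trace",
    "generate_load_curve",
    "inject_gaps",
]

DEFAULT_START = datetime(2021, 3, 1, 0, 0)


@dataclass(frozen=True)
class SinusoidComponent:
    """One sinusoidal term of the nocturnal glucose pattern."""

    frequency_per_h: float  # cycles per hour
    amplitude: float  # mmol/L
    phase: float = 0.0  # radians

    def __post_init__(self) -> None:
        if self.frequency_per_h < 0:
            raise ValueError("frequency must be >= 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass(frozen=True)
class TraceEvent:
    """Additive excursion: ``hypo_dip`` (raised cosine, negative) or
    ``meal_excursion`` (asymmetric triangle, positive)."""

    kind: str
    start_min: float
    duration_min: float
    magnitude: float  # mmol/L, depth of the dip / height of the excursion

    def __post_init__(self) -> None:
        if self.kind not in ("hypo_dip", "meal_excursion"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.duration_min <= 0:
            raise ValueError("duration_min must be positive")
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")

    def contribution(self, t_min: np.ndarray) -> np.ndarray:
        s = (t_min - self.start_min) / self.duration_min
        inside = (s >= 0) & (s < 1)
        out = np.zeros_like(t_min, dtype=float)
        if self.kind == "hypo_dip":
            out[inside] = -self.magnitude * 0.5 * (1 - np.cos(2 * np.pi * s[inside]))
        else:  # meal_excursion: linear rise to peak at 25% duration, linear decay
            peak = 0.25
            rise = inside & (s < peak)
            fall = inside & (s >= peak)
            out[rise] = self.magnitude * s[rise] / peak
            out[fall] = self.magnitude * (1 - s[fall]) / (1 - peak)
        return out


@dataclass(frozen=True)
class SyntheticConfig:
    """Full specification of a simulated CGM trace."""

    baseline: float = 5.0  # mmol/L
    components: Tuple[SinusoidComponent, ...] = ()
    noise_sd: float = 0.0  # mmol/L, per-sample Gaussian
    events: Tuple[TraceEvent, ...] = ()
    duration_h: float = 24.0
    cadence_min: float = DEFAULT_CADENCE_MIN
    start: datetime = DEFAULT_START
    seed: int = 0
    ar_coeff: float = 0.0  # AR(1) coefficient of the noise, 0 = white

    def __post_init__(self) -> None:
        if self.duration_h <= 0:
            raise ValueError("duration_h must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.cadence_min <= 0:
            raise ValueError("cadence_min must be positive")
        if not -1 < self.ar_coeff < 1:
            raise ValueError("ar_coeff must lie in (-1, 1)")

    def replace(self, **kw) -> "SyntheticConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class LoadCurveSpec:
    """Anchor points of a starch-load response curve.

    The curve passes through (0, initial), (t_max_min, max_value) and
    (end_time_min, end_value); ``piecewise_linear`` connects them with
    straight lines so the downstream load summary recovers the spec exactly,
    ``smooth`` uses cosine easing between the same anchors.
    """

    initial: float
    max_value: float
    t_max_min: float
    end_value: float
    end_time_min: float
    shape: str = "piecewise_linear"

    def __post_init__(self) -> None:
        if not 0 < self.t_max_min < self.end_time_min:
            raise ValueError("need 0 < t_max_min < end_time_min")
        if self.max_value < self.initial or self.max_value < self.end_value:
            raise ValueError("max_value must be >= initial and end_value")
        if self.shape not in ("piecewise_linear", "smooth"):
            raise ValueError(f"unknown shape {self.shape!r}")


def generate_trace(config: SyntheticConfig, *, patient_id: Optional[str] = None) -> GlucoseTrace:
    """Simulate a CGM trace per ``config``; same config => identical trace."""
    n = int(round(config.duration_h * 60.0 / config.cadence_min))
    t_min = np.arange(n) * config.cadence_min
    t_h = t_min / 60.0

    signal = np.full(n, config.baseline, dtype=float)
    for comp in config.components:
        signal += comp.amplitude * np.sin(2 * np.pi * comp.frequency_per_h * t_h + comp.phase)
    for event in config.events:
        signal += event.contribution(t_min)

    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        white = rng.normal(0.0, config.noise_sd, n)
        if config.ar_coeff:
            # stationary AR(1) with marginal sd == noise_sd
            rho = config.ar_coeff
            noise = np.empty(n)
            noise[0] = white[0]
            scale = np.sqrt(1 - rho**2)
            for i in range(1, n):
                noise[i] = rho * noise[i - 1] + scale * white[i]
        else:
            noise = white
        signal = signal + noise

    clipped = signal < CGM_FLOOR_MMOL
    values = np.where(clipped, CGM_FLOOR_MMOL, signal)
    times = pd.Timestamp(config.start) + pd.to_timedelta(t_min, unit="m")
    return GlucoseTrace(times, values, clipped, cadence_min=config.cadence_min, patient_id=patient_id)


def generate_load_curve(
    spec: LoadCurveSpec,
    cadence_min: float = DEFAULT_CADENCE_MIN,
    *,
    start: datetime = DEFAULT_START,
    patient_id: Optional[str] = None,
) -> GlucoseTrace:
    """Sample a load-response curve on a cadence grid through the anchors.

    The grid always contains t = 0, t_max and end_time (off-grid anchors are
    inserted) so that the load summary recovers the spec's timing and values
    exactly for the piecewise-linear shape.
    """
    if cadence_min <= 0:
        raise ValueError("cadence_min must be positive")
    grid = list(np.arange(0.0, spec.end_time_min, cadence_min))
    for anchor in (spec.t_max_min, spec.end_time_min):
        if not np.any(np.isclose(grid, anchor)):
            grid.append(float(anchor))
    t_min = np.array(sorted(set(grid)))

    knots_t = np.array([0.0, spec.t_max_min, spec.end_time_min])
    knots_v = np.array([spec.initial, spec.max_value, spec.end_value])
    if spec.shape == "piecewise_linear":
        values = np.interp(t_min, knots_t, knots_v)
    else:  # cosine easing segment by segment
        values = np.empty_like(t_min)
        for i, t in enumerate(t_min):
            j = 0 if t <= spec.t_max_min else 1
            a, b = knots_v[j], knots_v[j + 1]
            s = (t - knots_t[j]) / (knots_t[j + 1] - knots_t[j])
            values[i] = a + (b - a) * (1 - np.cos(np.pi * np.clip(s, 0, 1))) / 2

    clipped = values < CGM_FLOOR_MMOL
    values = np.where(clipped, CGM_FLOOR_MMOL, values)
    times = pd.Timestamp(start) + pd.to_timedelta(t_min, unit="m")
    return GlucoseTrace(times, values, clipped, cadence_min=cadence_min, patient_id=patient_id)


def inject_gaps(
    trace: GlucoseTrace,
    gaps: Optional[Sequence[Tuple[datetime, datetime]]] = None,
    *,
    n_random: int = 0,
    gap_minutes: float = 30.0,
    seed: Optional[int] = None,
) -> GlucoseTrace:
    """Remove samples inside gap intervals (sensor-dropout emulation).

    ``gaps`` is a list of half-open ``(start, end)`` datetime intervals.
    Alternatively ``n_random`` gaps of ``gap_minutes`` each are drawn from
    ``seed`` within the trace span. Remaining samples are unchanged.
    """
    intervals = [(pd.Timestamp(a), pd.Timestamp(b)) for a, b in (gaps or [])]
    if n_random:
        if len(trace) == 0:
            raise ValueError("cannot draw random gaps from an empty trace")
        rng = np.random.default_rng(seed)
        span_min = (trace.end - trace.start).total_seconds() / 60.0
        for _ in range(n_random):
            offset = rng.uniform(0.0, max(span_min - gap_minutes, 0.0))
            a = trace.start + pd.Timedelta(minutes=offset)
            intervals.append((a, a + pd.Timedelta(minutes=gap_minutes)))
    if not intervals:
        return trace
    keep = np.ones(len(trace), dtype=bool)
    for a, b in intervals:
        keep &= ~((trace.times >= a) & (trace.times < b))
    return trace.select(keep)
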