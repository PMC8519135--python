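"""Reading and writing CGM data, unit conversion and carbohydrate-rate arithmetic.

The supported input dialect is the CSV export of the Dexcom CLARITY clinical
portal: one row per event with a timestamp column, an event-type column and a
glucose-value column. Only estimated-glucose rows are glucose data; calibration
and alert rows are skipped. Below-range readings appear as the literal string
``"Low"`` and are mapped to clipped samples at the 2.2 mmol/L sensor floor.

The canonical on-disk format of this package is a three-column CSV
(ISO-8601 timestamp, glucose in mmol/L, clipped 0/1) with a JSON metadata
sidecar.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from ._utils import round_half_up
from .trace import CGM_CEILING_MMOL, CGM_FLOOR_MMOL, DEFAULT_CADENCE_MIN, GlucoseTrace, PatientContext

__all__ = [
    "DexcomDialect",
    "CGMFormatError",
    "EmptyTraceError",
    "read_dexcom_csv",
    "read_trace_csv",
    "write_trace_csv",
    "clip_floor",
    "mgdl_to_mmol",
    "mmol_to_mgdl",
    "carb_rate",
    "carb_rate_to_g_per_h",
    "MGDL_PER_MMOL",
    "PatientContext",
]

log = logging.getLogger(__name__)

#: mg/dL per mmol/L of glucose (molar mass of glucose, 180.16 g/mol).
MGDL_PER_MMOL = 18.016


class CGMFormatError(ValueError):
    """The input file does not have the configured columns/shape."""


class EmptyTraceError(ValueError):
    """Parsing succeeded but no usable glucose rows remained."""


@dataclass(frozen=True)
class DexcomDialect:
    """Column map and conventions of a CLARITY-style CSV export."""

    timestamp_col: str = "Timestamp (YYYY-MM-DDThh:mm:ss)"
    event_col: Optional[str] = "Event Type"
    value_col: str = "Glucose Value (mmol/L)"
    units: str = "mmol"  # "mmol" or "mgdl"
    delimiter: str = ","
    decimal: str = "."
    low_text: str = "Low"
    high_text: str = "High"
    glucose_events: Tuple[str, ...] = ("EGV", "Estimated Glucose Value")

    def __post_init__(self) -> None:
        if self.units not in ("mmol", "mgdl"):
            raise ValueError(f"units must be 'mmol' or 'mgdl', got {self.units!r}")


def mgdl_to_mmol(value):
    """Convert glucose from mg/dL to mmol/L (divide by 18.016)."""
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError("glucose in mg/dL must be non-negative")
    out = arr / MGDL_PER_MMOL
    return float(out) if np.isscalar(value) or arr.ndim == 0 else out


def mmol_to_mgdl(value):
    """Inverse of :func:`mgdl_to_mmol`."""
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError("glucose in mmol/L must be non-negative")
    out = arr * MGDL_PER_MMOL
    return float(out) if np.isscalar(value) or arr.ndim == 0 else out


def carb_rate(rate_g_per_h: float, weight_kg: float, *, ndigits: Optional[int] = 1) -> float:
    """Carbohydrate delivery in mg per kg body weight per minute.

    Continuous feeds and cornstarch regimens are prescribed in g/h; the
    physiologically comparable quantity (e.g. against endogenous glucose
    production) is mg/kg/min: ``1000 * g_per_h / (weight_kg * 60)``.

    By default the result is reported to 1 decimal, the precision clinical
    reports use; pass ``ndigits=None`` for full precision.
    """
    if not np.isfinite(weight_kg) or weight_kg <= 0:
        raise ValueError(f"weight_kg must be positive, got {weight_kg!r}")
    if not np.isfinite(rate_g_per_h) or rate_g_per_h < 0:
        raise ValueError(f"rate_g_per_h must be non-negative, got {rate_g_per_h!r}")
    rate = 1000.0 * rate_g_per_h / (weight_kg * 60.0)
    return rate if ndigits is None else round_half_up(rate, ndigits)


def carb_rate_to_g_per_h(rate_mg_kg_min: float, weight_kg: float) -> float:
    """Inverse of :func:`carb_rate` (full precision)."""
    if not np.isfinite(weight_kg) or weight_kg <= 0:
        raise ValueError(f"weight_kg must be positive, got {weight_kg!r}")
    if not np.isfinite(rate_mg_kg_min) or rate_mg_kg_min < 0:
        raise ValueError("rate must be non-negative")
    return rate_mg_kg_min * weight_kg * 60.0 / 1000.0


def clip_floor(trace: GlucoseTrace, floor: float = CGM_FLOOR_MMOL) -> GlucoseTrace:
    """Floor sub-range values at the sensor's validated lower limit.

    Values below ``floor`` are replaced by ``floor`` and flagged clipped;
    everything else is untouched. Idempotent; length-preserving.
    """
    below = trace.values < floor
    values = np.where(below, floor, trace.values)
    clipped = trace.clipped | below
    return trace.with_values(values, clipped)


def read_dexcom_csv(
    path: Union[str, Path],
    dialect: Optional[DexcomDialect] = None,
    *,
    patient_id: Optional[str] = None,
    cadence_min: float = DEFAULT_CADENCE_MIN,
    errors: str = "log",
) -> GlucoseTrace:
    """Parse a CLARITY-style CSV export into a :class:`GlucoseTrace`.

    Rows whose event type is not an estimated glucose value are skipped.
    ``"Low"`` readings become clipped samples at 2.2 mmol/L; ``"High"``
    readings are kept at the 22.2 mmol/L device ceiling with a warning (no
    validated upper limit is defined). Rows with unparseable timestamps or
    values are collected and logged (``errors="log"``) or raised
    (``errors="raise"``). The output is sorted by time with duplicate
    timestamps dropped (first occurrence kept) and floored at 2.2 mmol/L.
    """
    dialect = dialect or DexcomDialect()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=dialect.delimiter, decimal=dialect.decimal, dtype=str)

    missing = [c for c in (dialect.timestamp_col, dialect.value_col) if c not in raw.columns]
    if missing:
        raise CGMFormatError(f"{path.name}: missing required column(s) {missing}; found {list(raw.columns)}")

    if dialect.event_col is not None and dialect.event_col in raw.columns:
        ev = raw[dialect.event_col].fillna("").str.strip().str.lower()
        wanted = tuple(e.lower() for e in dialect.glucose_events)
        raw = raw[ev.isin(wanted)]

    row_errors: list[tuple[int, str]] = []
    times, values, clipped = [], [], []
    for idx, row in raw.iterrows():
        ts_text = row[dialect.timestamp_col]
        val_text = row[dialect.value_col]
        try:
            ts = pd.to_datetime(ts_text)
        except (ValueError, TypeError):
            row_errors.append((idx, f"unparseable timestamp {ts_text!r}"))
            continue
        if pd.isna(ts):
            row_errors.append((idx, f"unparseable timestamp {ts_text!r}"))
            continue
        text = (val_text or "").strip() if isinstance(val_text, str) else val_text
        if isinstance(text, str) and text.lower() == dialect.low_text.lower():
            value, was_clipped = CGM_FLOOR_MMOL, True
        elif isinstance(text, str) and text.lower() == dialect.high_text.lower():
            log.warning("%s row %s: 'High' reading kept at device ceiling %.1f mmol/L", path.name, idx, CGM_CEILING_MMOL)
            value, was_clipped = CGM_CEILING_MMOL, False
        else:
            try:
                value = float(str(text).replace(dialect.decimal, "."))
            except (ValueError, TypeError):
                row_errors.append((idx, f"unparseable glucose value {val_text!r}"))
                continue
            if dialect.units == "mgdl":
                value = mgdl_to_mmol(value)
            was_clipped = False
        times.append(ts)
        values.append(value)
        clipped.append(was_clipped)

    if row_errors:
        msg = "; ".join(f"row {i}: {why}" for i, why in row_errors)
        if errors == "raise":
            raise CGMFormatError(f"{path.name}: {msg}")
        log.warning("%s: skipped %d row(s): %s", path.name, len(row_errors), msg)

    if not times:
        raise EmptyTraceError(f"{path.name}: no usable glucose rows")

    frame = pd.DataFrame({"timestamp": times, "glucose_mmol_l": values, "clipped": clipped})
    frame = frame.sort_values("timestamp", kind="stable")
    dup = frame["timestamp"].duplicated(keep="first")
    if dup.any():
        log.warning("%s: dropped %d duplicate timestamp(s), first kept", path.name, int(dup.sum()))
        frame = frame[~dup]

    trace = GlucoseTrace(
        frame["timestamp"],
        frame["glucose_mmol_l"],
        frame["clipped"],
        cadence_min=cadence_min,
        patient_id=patient_id,
    )
    return clip_floor(trace)


def write_trace_csv(trace: GlucoseTrace, path: Union[str, Path], *, sidecar: bool = True) -> Path:
    """Write the canonical trace CSV (+ JSON metadata sidecar)."""
    path = Path(path)
    frame = trace.to_frame()
    frame["timestamp"] = frame["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    frame["glucose_mmol_l"] = [f"{v:.4f}" for v in trace.values]
    frame.to_csv(path, index=False)
    if sidecar:
        meta = {
            "patient_id": trace.patient_id,
            "cadence_min": trace.cadence_min,
            "unit": trace.unit,
            "n_samples": len(trace),
            "start": str(trace.start) if len(trace) else None,
            "end": str(trace.end) if len(trace) else None,
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))
    return path


def read_trace_csv(path: Union[str, Path]) -> GlucoseTrace:
    """Read a canonical trace CSV written by :func:`write_trace_csv`."""
    path = Path(path)
    frame = pd.read_csv(path, parse_dates=["timestamp"])
    required = {"timestamp", "glucose_mmol_l"}
    if not required.issubset(frame.columns):
        raise CGMFormatError(f"{path.name}: expected columns {sorted(required)}")
    if len(frame) == 0:
        raise EmptyTraceError(f"{path.name}: empty trace")
    meta_path = Path(str(path) + ".json")
    cadence, patient_id = DEFAULT_CADENCE_MIN, None
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        cadence = meta.get("cadence_min", cadence)
        patient_id = meta.get("patient_id")
    return GlucoseTrace.from_frame(frame, cadence_min=cadence, patient_id=patient_id)
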