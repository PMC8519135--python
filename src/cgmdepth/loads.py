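"""Starch-load response summaries and crossover arm comparison.

A monitored starch load (e.g. uncooked cornstarch vs an extended-release
starch) produces a single glucose curve per patient per arm. Each curve is
reduced to the standard descriptors: initial/maximum/end concentration,
time to maximum, rise and fall slopes in mmol/L/h, and the trapezoidal AUC
in mmol/L*h above a zero baseline. Crossover arms are compared with
per-patient pairing: arm means are taken over all available loads (patients
with an incomplete opposite arm still contribute to their own arm's mean),
while the paired two-tailed t-test uses complete pairs only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Union

import numpy as np
from scipy import stats as sps

from .metrics import DescriptiveStats, descriptive
from .trace import GlucoseTrace

__all__ = ["StarchLoadSummary", "ArmComparison", "load_summary", "auc_trapezoid", "compare_arms"]


@dataclass(frozen=True)
class StarchLoadSummary:
    """Curve descriptors of one starch load (time re-zeroed to load start)."""

    n: int
    initial: float  # mmol/L, first sample
    max_value: float  # mmol/L, global maximum (earliest occurrence on ties)
    t_max_min: float  # minutes from load start to the maximum
    end_time_min: float  # minutes from start to the last sample
    end_value: float  # mmol/L, last sample
    slope_rise: float  # (max - initial) / t_max, mmol/L/h; nan if n == 1
    slope_fall: float  # (end - max) / (end_time - t_max), mmol/L/h; 0 if t_max == end
    fall_undefined: bool  # True when t_max coincides with the end sample
    auc: float  # mmol/L*h, trapezoid above zero; nan if n < 2
    descriptive: DescriptiveStats


def auc_trapezoid(trace: GlucoseTrace) -> float:
    """Trapezoidal area under the glucose curve, mmol/L*h, zero baseline."""
    if len(trace) < 2:
        raise ValueError("AUC needs at least two samples")
    hours = trace.minutes_since_start() / 60.0
    return float(np.trapezoid(trace.values, hours))


def load_summary(trace: GlucoseTrace) -> StarchLoadSummary:
    """Summarize one load curve.

    The maximum's tie-break is the earliest occurrence (affects t_max). When
    the maximum falls on the final sample there is no falling limb; the fall
    slope is reported as 0 with ``fall_undefined=True``. Slopes are undefined
    (nan) for a single-sample trace.
    """
    if len(trace) == 0:
        raise ValueError("load summary needs a nonempty trace")
    t_min = trace.minutes_since_start()
    values = trace.values
    i_max = int(np.argmax(values))  # np.argmax returns the first maximum
    initial = float(values[0])
    max_value = float(values[i_max])
    t_max = float(t_min[i_max])
    end_time = float(t_min[-1])
    end_value = float(values[-1])

    if len(trace) == 1:
        slope_rise = slope_fall = float("nan")
        fall_undefined = True
        auc = float("nan")
    else:
        slope_rise = (max_value - initial) / (t_max / 60.0) if t_max > 0 else 0.0
        if t_max >= end_time:
            slope_fall, fall_undefined = 0.0, True
        else:
            slope_fall = (end_value - max_value) / ((end_time - t_max) / 60.0)
            fall_undefined = False
        auc = auc_trapezoid(trace)

    return StarchLoadSummary(
        n=len(trace),
        initial=initial,
        max_value=max_value,
        t_max_min=t_max,
        end_time_min=end_time,
        end_value=end_value,
        slope_rise=slope_rise,
        slope_fall=slope_fall,
        fall_undefined=fall_undefined,
        auc=auc,
        descriptive=descriptive(values),
    )


@dataclass(frozen=True)
class ArmComparison:
    """Two-arm crossover comparison of one load metric."""

    metric: str
    arm_a: str
    arm_b: str
    mean_a: float  # mean over all available loads in arm A
    mean_b: float
    n_a: int
    n_b: int
    n_pairs: int  # patients with both arms
    t_stat: float  # nan when < 2 complete pairs
    p_value: float  # two-tailed; nan when < 2 complete pairs


def _metric_value(entry, metric: str) -> float:
    if isinstance(entry, (int, float, np.floating)):
        return float(entry)
    if hasattr(entry, metric):
        return float(getattr(entry, metric))
    if hasattr(entry, "descriptive") and hasattr(entry.descriptive, metric):
        return float(getattr(entry.descriptive, metric))
    raise AttributeError(f"summary has no metric {metric!r}")


def compare_arms(
    summaries: Mapping[str, Mapping[str, Union[StarchLoadSummary, float]]],
    metric: str,
    *,
    arms: Optional[tuple] = None,
) -> ArmComparison:
    """Compare one metric between the two arms of a crossover.

    ``summaries`` maps patient -> arm -> :class:`StarchLoadSummary` (or a
    plain number). Missing/NaN entries are treated as unavailable loads. Arm
    means use every available load; the paired t-test uses only patients with
    both arms. Symmetric up to the sign of the difference.
    """
    if arms is None:
        seen: list = []
        for per_patient in summaries.values():
            for arm in per_patient:
                if arm not in seen:
                    seen.append(arm)
        arms = tuple(seen)
    if len(arms) != 2:
        raise ValueError(f"exactly two arms required, got {arms!r}")
    arm_a, arm_b = arms

    vals: Dict[str, Dict[str, float]] = {arm_a: {}, arm_b: {}}
    for patient, per_patient in summaries.items():
        for arm in arms:
            if arm in per_patient and per_patient[arm] is not None:
                v = _metric_value(per_patient[arm], metric)
                if np.isfinite(v):
                    vals[arm][patient] = v

    a_all = np.array(list(vals[arm_a].values()))
    b_all = np.array(list(vals[arm_b].values()))
    paired_patients = sorted(set(vals[arm_a]) & set(vals[arm_b]))
    if len(paired_patients) >= 2:
        a_pair = np.array([vals[arm_a][p] for p in paired_patients])
        b_pair = np.array([vals[arm_b][p] for p in paired_patients])
        t_stat, p_value = sps.ttest_rel(a_pair, b_pair)
        t_stat, p_value = float(t_stat), float(p_value)
    else:
        t_stat = p_value = float("nan")

    return ArmComparison(
        metric=metric,
        arm_a=arm_a,
        arm_b=arm_b,
        mean_a=float(np.mean(a_all)) if a_all.size else float("nan"),
        mean_b=float(np.mean(b_all)) if b_all.size else float("nan"),
        n_a=int(a_all.size),
        n_b=int(b_all.size),
        n_pairs=len(paired_patients),
        t_stat=t_stat,
        p_value=p_value,
    )
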