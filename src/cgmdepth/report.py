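"""Pipeline orchestration: ingest -> windows -> metrics/dynamics/spectral/loads.

``run_pipeline`` turns one trace (plus optional intervention schedule and
starch-load manifest) into a reproducible report bundle: the per-intervention
metrics table, a per-sample dynamics CSV (glucose, derivatives, both CUSUM
series), the nocturnal spectrogram in long form with its per-night stability
summary, per-load summaries with arm comparisons, and a provenance JSON
(package version, config echo, input checksums, seed) so identical inputs
yield byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dynamics import cusum_a, cusum_b, derivatives, fit_hypercube
from .io import read_dexcom_csv, read_trace_csv, write_trace_csv
from .loads import compare_arms, load_summary
from .metrics import interval_report
from .simulate import LoadCurveSpec, SinusoidComponent, SyntheticConfig, generate_trace, generate_load_curve
from .spectral import build_spectrogram, stability_summary
from .trace import GlucoseTrace, concat_traces
from .windows import (
    DEFAULT_COMPLETENESS,
    NOCTURNAL_WINDOW,
    ClockWindow,
    InterventionSchedule,
    extract_clock_window,
    nights_of,
)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "make_fixtures"]

#: Table 4 anchor curves used as canonical fixtures: (initial, max, t_max, end_value, end_time)
_FIXTURE_LOADS = {
    "load_ii1_uccs": LoadCurveSpec(initial=4.0, max_value=8.4, t_max_min=185, end_value=3.0, end_time_min=475),
    "load_ii9_uccs": LoadCurveSpec(initial=5.5, max_value=12.1, t_max_min=40, end_value=2.5, end_time_min=425),
}


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    trace_path: Union[str, Path]
    out_dir: Union[str, Path]
    schedule_path: Optional[Union[str, Path]] = None
    manifest_path: Optional[Union[str, Path]] = None
    input_format: str = "canonical"  # "canonical" or "dexcom"
    night: str = "01:00-05:00"
    detection_threshold: Optional[float] = None  # mmol/L; None = adaptive default
    completeness: float = DEFAULT_COMPLETENESS
    bins: Tuple[int, int] = (8, 8)
    baseline_label: Optional[str] = None  # CUSUM-A reference intervention
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "bins" in data:
            data["bins"] = tuple(data["bins"])
        return cls(**data)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: (str(v) if isinstance(v, Path) else v) for k, v in d.items()}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(frame: pd.DataFrame, path: Path) -> Path:
    frame.to_csv(path, index=False, lineterminator="\n")
    return path


def run_pipeline(config: RunConfig) -> Dict[str, Path]:
    """Run every analysis stage; returns the paths of all written artifacts."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trace_path = Path(config.trace_path)
    window = ClockWindow.parse(config.night)

    try:
        if config.input_format == "dexcom":
            trace = read_dexcom_csv(trace_path)
        else:
            trace = read_trace_csv(trace_path)
    except Exception as exc:
        raise RuntimeError(f"[ingest] {exc}") from exc

    schedule = None
    if config.schedule_path:
        sp = Path(config.schedule_path)
        schedule = (
            InterventionSchedule.from_yaml(sp)
            if sp.suffix in (".yml", ".yaml")
            else InterventionSchedule.from_csv(sp)
        )

    outputs: Dict[str, Path] = {}

    # -- interval metrics -------------------------------------------------
    try:
        report = interval_report(trace, schedule, window)
    except Exception as exc:
        raise RuntimeError(f"[metrics] {exc}") from exc
    outputs["metrics"] = _write_csv(report, out_dir / "metrics.csv")

    # -- dynamics: derivatives + CUSUM A/B over concatenated nights --------
    try:
        deriv = derivatives(trace)
        reference: Union[str, float] = "self"
        if schedule is not None:
            label = config.baseline_label or schedule.labels[0]
            base = [iv for iv in schedule.interventions if iv.label == label]
            if base:
                iv = base[0]
                mask = np.asarray((trace.times >= iv.start) & (trace.times < iv.end))
                if mask.any():
                    reference = float(trace.values[mask].mean())
        ca = cusum_a(trace.values, reference, times=trace.times)
        model = fit_hypercube(trace, bins=config.bins)
        cb = cusum_b(trace, model)
        nights = nights_of(trace, window)
        night_start = np.zeros(len(trace), dtype=bool)
        for nt in nights:
            if len(nt.trace):
                night_start |= np.asarray(trace.times == nt.trace.start)
        dyn = pd.DataFrame(
            {
                "timestamp": trace.times.strftime("%Y-%m-%dT%H:%M:%S"),
                "glucose_mmol_l": trace.values,
                "glucose_prime": deriv.first,
                "glucose_second": deriv.second,
                "gap_mask": deriv.gap_mask.astype(int),
                "cusum_a": ca.values,
                "cusum_b": cb.values,
                "night_start": night_start.astype(int),
            }
        )
    except Exception as exc:
        raise RuntimeError(f"[dynamics] {exc}") from exc
    outputs["dynamics"] = _write_csv(dyn, out_dir / "dynamics.csv")
    model_json = {
        "n_bins": list(config.bins),
        "edges": [e.tolist() for e in model.edges_],
        "cell_mean": np.where(np.isfinite(model.cell_mean_), model.cell_mean_, None).tolist(),
        "n_train": model.n_train_,
    }
    (out_dir / "hypercube_model.json").write_text(json.dumps(model_json, indent=2))
    outputs["hypercube_model"] = out_dir / "hypercube_model.json"

    # -- spectral ----------------------------------------------------------
    try:
        spg = build_spectrogram(
            trace, window,
            threshold=config.detection_threshold,
            min_completeness=config.completeness,
        )
    except Exception as exc:
        raise RuntimeError(f"[spectral] {exc}") from exc
    outputs["spectrogram"] = _write_csv(spg.to_long_frame(), out_dir / "spectrogram.csv")
    outputs["stability"] = _write_csv(stability_summary(spg), out_dir / "stability.csv")

    # -- starch loads (optional manifest) ----------------------------------
    if config.manifest_path:
        try:
            manifest = pd.read_csv(config.manifest_path)
            required = {"patient", "arm", "trace_file"}
            if not required.issubset(manifest.columns):
                raise ValueError(f"manifest needs columns {sorted(required)}")
            base = Path(config.manifest_path).parent
            summaries: Dict[str, Dict[str, object]] = {}
            rows = []
            for _, m in manifest.iterrows():
                lt = read_trace_csv(base / m["trace_file"])
                s = load_summary(lt)
                summaries.setdefault(str(m["patient"]), {})[str(m["arm"])] = s
                rows.append(
                    {
                        "patient": m["patient"], "arm": m["arm"], "n": s.n,
                        "initial": s.initial, "max_value": s.max_value,
                        "t_max_min": s.t_max_min, "end_time_min": s.end_time_min,
                        "end_value": s.end_value, "slope_rise": s.slope_rise,
                        "slope_fall": s.slope_fall, "auc": s.auc,
                    }
                )
            outputs["loads"] = _write_csv(pd.DataFrame(rows), out_dir / "loads.csv")
            comp_rows = []
            for metric in ("max_value", "slope_rise", "slope_fall", "auc", "initial", "t_max_min"):
                c = compare_arms(summaries, metric)
                comp_rows.append(dataclasses.asdict(c))
            outputs["arm_comparison"] = _write_csv(pd.DataFrame(comp_rows), out_dir / "arm_comparison.csv")
        except Exception as exc:
            raise RuntimeError(f"[loads] {exc}") from exc

    # -- provenance ---------------------------------------------------------
    checksums = {trace_path.name: _sha256(trace_path)}
    for p in (config.schedule_path, config.manifest_path):
        if p:
            checksums[Path(p).name] = _sha256(Path(p))
    provenance = {
        "package": "cgmdepth",
        "version": __version__,
        "seed": config.seed,
        "config": config.echo(),
        "input_sha256": checksums,
        "outputs": sorted(p.name for p in outputs.values()),
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    outputs["provenance"] = out_dir / "provenance.json"
    return outputs


def make_fixtures(seed: int, out: Union[str, Path]) -> Dict[str, Path]:
    """Write the canonical synthetic fixtures used throughout the docs/tests.

    * ``trace_24h.csv`` — one day, 288 samples, mild nocturnal sinusoid + noise;
    * ``trace_4day.csv`` — four full days (192 nocturnal samples at 01:00-05:00);
    * ``load_ii1_uccs.csv`` / ``load_ii9_uccs.csv`` — piecewise-linear curves
      through two published starch-load anchor sets;
    * ``sinusoid_nights.csv`` — seven noise-free nights with a fixed
      1 cycle/h, 1.0 mmol/L nocturnal component.
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    written: Dict[str, Path] = {}

    day = SyntheticConfig(
        baseline=5.5,
        components=(SinusoidComponent(frequency_per_h=1.0, amplitude=0.8),),
        noise_sd=0.2,
        duration_h=24.0,
        seed=seed,
    )
    written["trace_24h"] = write_trace_csv(generate_trace(day, patient_id="synthetic-day"), out / "trace_24h.csv")

    four = day.replace(duration_h=96.0, seed=seed + 1)
    written["trace_4day"] = write_trace_csv(generate_trace(four, patient_id="synthetic-4day"), out / "trace_4day.csv")

    for name, spec in _FIXTURE_LOADS.items():
        written[name] = write_trace_csv(
            generate_load_curve(spec, patient_id=f"synthetic-{name}"), out / f"{name}.csv"
        )

    nights = SyntheticConfig(
        baseline=5.0,
        components=(SinusoidComponent(frequency_per_h=1.0, amplitude=1.0),),
        noise_sd=0.0,
        duration_h=7 * 24.0,
        seed=seed + 2,
    )
    written["sinusoid_nights"] = write_trace_csv(
        generate_trace(nights, patient_id="synthetic-nights"), out / "sinusoid_nights.csv"
    )
    return written
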