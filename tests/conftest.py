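from datetime import datetime

import numpy as np
import pandas as pd
import pytest

from cgmdepth import GlucoseTrace, SinusoidComponent, SyntheticConfig, generate_trace

START = datetime(2021, 3, 1, 0, 0)


def make_trace(values, start=START, cadence_min=5.0, **kw):
    """Trace on a regular grid from a plain list of glucose values."""
    times = pd.Timestamp(start) + pd.to_timedelta(np.arange(len(values)) * cadence_min, unit="m")
    return GlucoseTrace(times, values, cadence_min=cadence_min, **kw)


@pytest.fixture
def four_day_trace():
    """Four complete noise-free days with one nocturnal sinusoid."""
    cfg = SyntheticConfig(
        baseline=5.5,
        components=(SinusoidComponent(frequency_per_h=1.0, amplitude=0.8),),
        duration_h=96.0,
        start=START,
    )
    return generate_trace(cfg)


@pytest.fixture
def dexcom_csv_factory(tmp_path):
    """Write a CLARITY-style CSV from (timestamp, event, value) rows."""

    def write(rows, name="export.csv", header=None):
        header = header or [
            "Timestamp (YYYY-MM-DDThh:mm:ss)",
            "Event Type",
            "Glucose Value (mmol/L)",
        ]
        lines = [",".join(header)]
        lines += [",".join(str(c) for c in row) for row in rows]
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return write
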