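"""Bundled reference data for validation.

The CGM traces behind the published hepatic-GSD starch-load crossover were
never deposited, but the per-load summary descriptors were published in full
and are reproduced here: 11 patients each scheduled for an uncooked-cornstarch
("UCCS") and a "Glycosade" (extended-release starch) load in randomized
order. Two Glycosade loads (patients II-2 and II-3) are incomplete because
CGM recording started after the glucose peak; only end time and end value
are available for them, and they are excluded from paired analyses.

Columns of :func:`starch_loads`: patient, arm, n (samples), median, min,
max_value, range, sd, variance, cv_percent (all mmol/L-based), initial (mmol/L),
t_max_min and end_time_min (minutes from load start), end_value (mmol/L),
slope_rise and slope_fall (mmol/L/h), auc (mmol/L*h).

:data:`FEEDING_REGIMENS` holds the published nocturnal carbohydrate regimens
of the dietary-intervention case (body weight 37.4 kg) with their reported
delivery rates in mg/kg/min, used to validate the rate arithmetic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["starch_loads", "FEEDING_REGIMENS", "CASE_WEIGHT_KG", "UCCS", "GLYCOSADE"]

UCCS = "UCCS"
GLYCOSADE = "Glycosade"

#: Body weight (kg) of the nocturnal dietary-intervention case.
CASE_WEIGHT_KG = 37.4

#: regimen -> (carbohydrate g/h, reported mg/kg/min)
FEEDING_REGIMENS = {
    "nutridrink_cgdf": (10.4, 4.6),
    "maltocal6_cgdf": (8.6, 3.9),  # reported value; 8.6 g/h computes 3.8
    "uccs_45g": (9.9, 4.4),
    "uccs_40g_followup": (8.8, 3.9),
}

_COLUMNS = [
    "patient", "arm", "n", "median", "min", "max_value", "range", "sd", "variance",
    "cv_percent", "initial", "t_max_min", "end_time_min", "end_value",
    "slope_rise", "slope_fall", "auc",
]

_NAN = float("nan")

_ROWS = [
    # patient, arm, n, median, min, max, range, sd, var, cv, initial, t_max, end_t, end_v, rise, fall, auc
    ("II-1", UCCS, 96, 5.0, 3.0, 8.4, 5.4, 1.5, 2.3, 29.4, 4.0, 185, 475, 3.0, 1.4, -1.1, 41),
    ("II-1", GLYCOSADE, 96, 5.1, 3.1, 7.3, 4.2, 1.1, 1.3, 21.2, 4.1, 215, 475, 3.1, 0.9, -1.0, 41),
    ("II-2", UCCS, 93, 4.9, 3.6, 8.7, 5.2, 1.4, 1.8, 26.4, 4.7, 40, 460, 3.6, 6.0, -0.7, 41),
    ("II-2", GLYCOSADE, 73, _NAN, _NAN, _NAN, _NAN, _NAN, _NAN, _NAN, _NAN, _NAN, 550, 4.3, _NAN, _NAN, _NAN),
    ("II-3", UCCS, 108, 4.9, 3.2, 7.9, 4.7, 1.1, 1.1, 22.0, 4.9, 70, 535, 3.2, 2.5, -0.6, 45),
    ("II-3", GLYCOSADE, 61, _NAN, _NAN, _NAN, _NAN, _NAN, _NAN, _NAN, _NAN, _NAN, 475, 4.7, _NAN, _NAN, _NAN),
    ("II-4", UCCS, 98, 5.6, 4.1, 9.3, 5.3, 1.0, 1.1, 17.5, 5.1, 100, 485, 5.2, 2.6, -0.6, 47),
    ("II-4", GLYCOSADE, 108, 4.7, 3.3, 7.9, 4.6, 0.9, 0.9, 18.4, 4.9, 75, 535, 4.9, 2.5, -0.4, 44),
    ("II-5", UCCS, 146, 4.3, 3.2, 8.1, 4.9, 1.0, 0.9, 21.7, 5.0, 55, 725, 4.8, 3.4, -0.3, 55),
    ("II-5", GLYCOSADE, 146, 3.7, 3.2, 7.1, 3.9, 0.9, 0.8, 22.5, 4.8, 40, 725, 4.8, 3.4, -0.2, 49),
    ("II-6", UCCS, 146, 4.7, 3.3, 8.6, 5.3, 1.0, 1.0, 20.4, 3.3, 40, 725, 4.3, 7.9, -0.4, 59),
    ("II-6", GLYCOSADE, 144, 5.2, 3.7, 7.5, 3.8, 0.7, 0.5, 13.2, 3.7, 40, 715, 4.9, 5.7, -0.2, 63),
    ("II-7", UCCS, 143, 4.4, 2.5, 7.4, 4.9, 1.1, 1.2, 24.4, 4.9, 35, 710, 2.5, 4.4, -0.4, 54),
    ("II-7", GLYCOSADE, 108, 5.2, 3.6, 6.8, 3.2, 0.9, 0.8, 18.4, 6.6, 90, 535, 3.7, 0.1, -0.4, 44),
    ("II-8", UCCS, 120, 5.4, 3.4, 6.2, 2.8, 0.6, 0.4, 11.5, 3.4, 100, 595, 3.7, 1.7, -0.3, 52),
    ("II-8", GLYCOSADE, 122, 5.8, 4.7, 7.4, 2.7, 0.7, 0.5, 12.1, 5.8, 115, 605, 5.0, 0.8, -0.3, 59),
    ("II-9", UCCS, 86, 3.9, 2.0, 12.1, 10.1, 2.5, 6.2, 56.8, 5.5, 40, 425, 2.5, 9.9, -1.5, 31),
    ("II-9", GLYCOSADE, 98, 4.7, 3.9, 8.7, 4.8, 1.3, 1.8, 25.0, 4.1, 45, 485, 4.2, 6.1, -0.6, 42),
    ("II-10", UCCS, 122, 5.0, 4.1, 10.2, 6.1, 1.4, 2.0, 25.5, 5.2, 45, 605, 4.9, 6.6, -0.6, 55),
    ("II-10", GLYCOSADE, 122, 3.9, 3.2, 8.8, 5.7, 1.2, 1.5, 27.3, 4.4, 60, 605, 3.8, 4.4, -0.6, 44),
    ("II-11", UCCS, 120, 5.5, 4.3, 9.9, 5.6, 1.2, 1.4, 20.3, 4.9, 50, 595, 4.3, 5.9, -0.6, 59),
    ("II-11", GLYCOSADE, 145, 5.9, 4.2, 9.7, 5.5, 1.4, 2.1, 21.5, 7.8, 40, 725, 4.9, 2.8, -0.4, 78),
]


def starch_loads(*, complete_only: bool = False) -> pd.DataFrame:
    """Published per-load starch-load descriptors (one row per load).

    ``complete_only=True`` drops the two incomplete Glycosade loads.
    """
    frame = pd.DataFrame(_ROWS, columns=_COLUMNS)
    if complete_only:
        frame = frame[np.isfinite(frame["slope_rise"])].reset_index(drop=True)
    return frame
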