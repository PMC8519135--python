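"""Small shared helpers: report rounding and input validation."""

from __future__ import annotations

import decimal
from typing import Iterable

import numpy as np


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round to ``ndigits`` decimals with ties going away from zero.

    Report tables round 5s upward (4.65 -> 4.7); Python's builtin ``round``
    uses banker's rounding, which would print 4.6.
    """
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return x
    q = decimal.Decimal(10) ** -ndigits
    d = decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)


def round_series_half_up(values: Iterable[float], ndigits: int = 1) -> np.ndarray:
    return np.array([round_half_up(float(v), ndigits) for v in values])


def check_positive(name: str, value: float) -> float:
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be positive and finite, got {value!r}")
    return float(value)


def check_nonnegative(name: str, value: float) -> float:
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be non-negative and finite, got {value!r}")
    return float(value)
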