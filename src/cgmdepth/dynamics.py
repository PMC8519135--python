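"""Glucose dynamics: derivatives and cumulative-sum (CUSUM) change detection.

Two descriptive CUSUM formulations visualize sustained drifts that single
readings hide:

* Method A accumulates deviations from a reference mean,
  ``CUSUM_t = sum_{i<=t} (glucose_i - reference)``. With the series' own mean
  as reference the terminal value is exactly zero (the classical zero-sum
  CUSUM); with a baseline-period mean, later behavior drifts against earlier.
* Method B accumulates residuals against a per-patient predictor of absolute
  glucose from the first and second derivatives,
  ``CUSUM_t = sum_{i<=t} (predicted_i - glucose_i)``. A sustained positive
  trend means observed glucose runs below what the patient's own dynamics
  predict.

The predictor ("hypercube" regression) bins the (glucose', glucose'') plane
into an equal-width grid and predicts the mean observed glucose of the cell;
queries landing in empty cells fall back to the nearest populated cell by
bin-index distance. It is deliberately per-patient: patients serve as their
own control.

Derivatives use second-order finite differences (central in the interior,
one-sided at boundaries) on the actual timestamp spacing, in mmol/L per
minute; sample pairs spanning a recording gap larger than twice the cadence
are masked.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .trace import GlucoseTrace

__all__ = [
    "DerivativeSeries",
    "CusumSeries",
    "HypercubeRegressor",
    "derivatives",
    "cusum_a",
    "fit_hypercube",
    "cusum_b",
]


@dataclass(frozen=True)
class DerivativeSeries:
    """First/second derivative of a trace; masked entries span gaps."""

    times: pd.DatetimeIndex
    first: np.ndarray  # mmol/L per minute
    second: np.ndarray  # mmol/L per minute^2
    gap_mask: np.ndarray  # True where differentiation crossed a gap


@dataclass(frozen=True)
class CusumSeries:
    """Cumulative-sum series (mmol/L accumulated over samples)."""

    method: str  # "A" or "B"
    times: Optional[pd.DatetimeIndex]
    values: np.ndarray
    reference: Union[float, str, None]  # method A: the reference mean used
    gap_mask: Optional[np.ndarray] = None  # method B: masked (zeroed) increments


def derivatives(trace: GlucoseTrace) -> DerivativeSeries:
    """First and second time derivatives of a glucose trace.

    Second-order accurate everywhere (``np.gradient`` with ``edge_order=2``
    applied twice), so exact for quadratic profiles. Requires >= 3 samples
    for the second derivative; with exactly 2 the second derivative is nan.
    """
    n = len(trace)
    if n < 2:
        raise ValueError("derivatives need at least two samples")
    t_min = trace.minutes_since_start()
    if n >= 3:
        first = np.gradient(trace.values, t_min, edge_order=2)
        second = np.gradient(first, t_min, edge_order=2)
    else:
        first = np.gradient(trace.values, t_min)
        second = np.full(n, np.nan)

    dt = np.diff(t_min)
    gap = dt > 2.0 * trace.cadence_min
    gap_mask = np.zeros(n, dtype=bool)
    gap_mask[:-1] |= gap  # sample before the gap
    gap_mask[1:] |= gap  # sample after the gap
    return DerivativeSeries(trace.times, first, second, gap_mask)


def cusum_a(
    values,
    reference: Union[float, str] = "self",
    *,
    times: Optional[pd.DatetimeIndex] = None,
) -> CusumSeries:
    """Method-A CUSUM: running sum of deviations from a reference mean.

    ``reference="self"`` uses the series' own mean (terminal value exactly 0);
    a float uses a fixed reference, typically the baseline-intervention mean.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("CUSUM needs at least one value")
    ref = float(np.mean(arr)) if (isinstance(reference, str) and reference == "self") else float(reference)
    series = np.cumsum(arr - ref)
    return CusumSeries(method="A", times=times, values=series, reference=ref)


class HypercubeRegressor(BaseEstimator, RegressorMixin):
    """Binned predictor of absolute glucose from (glucose', glucose'').

    The observed derivative plane is divided into an ``n_bins[0] x n_bins[1]``
    grid (equal-width by default, per-dimension quantile edges optionally);
    each populated cell predicts the mean observed glucose of its training
    samples. Queries in empty cells use the nearest populated cell by
    Manhattan bin-index distance, ties broken toward the lexicographically
    lower cell index.

    Parameters
    ----------
    n_bins : tuple of int, default (8, 8)
        Grid resolution over (first derivative, second derivative).
    strategy : {"uniform", "quantile"}, default "uniform"
        Edge placement.

    Attributes
    ----------
    edges_ : list of ndarray
        Bin edges per dimension, length ``n_bins[d] + 1``.
    cell_mean_ : ndarray of shape n_bins
        Mean training glucose per cell (nan where empty).
    cell_count_ : ndarray of shape n_bins
        Training samples per cell.
    n_train_ : int
        Number of training samples.
    """

    def __init__(self, n_bins: Tuple[int, int] = (8, 8), strategy: str = "uniform"):
        self.n_bins = n_bins
        self.strategy = strategy

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_samples, 2): first and second derivative")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        if X.shape[0] == 0:
            raise ValueError("cannot fit on an empty training set")
        if self.strategy not in ("uniform", "quantile"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        nb = tuple(int(b) for b in self.n_bins)
        if len(nb) != 2 or any(b < 1 for b in nb):
            raise ValueError("n_bins must be two positive integers")

        edges = []
        for d in range(2):
            col = X[:, d]
            lo, hi = float(np.min(col)), float(np.max(col))
            if self.strategy == "quantile" and lo < hi:
                e = np.unique(np.quantile(col, np.linspace(0, 1, nb[d] + 1)))
                if len(e) < 2:
                    e = np.array([lo, hi])
            else:
                if lo == hi:  # degenerate dimension: one cell
                    lo, hi = lo - 0.5, hi + 0.5
                e = np.linspace(lo, hi, nb[d] + 1)
            edges.append(e)
        self.edges_ = edges

        idx = self._bin_indices(X)
        shape = tuple(len(e) - 1 for e in edges)
        sums = np.zeros(shape)
        counts = np.zeros(shape, dtype=int)
        np.add.at(sums, (idx[:, 0], idx[:, 1]), y)
        np.add.at(counts, (idx[:, 0], idx[:, 1]), 1)
        with np.errstate(invalid="ignore"):
            self.cell_mean_ = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        self.cell_count_ = counts
        self.n_train_ = int(X.shape[0])
        self._nonempty_ = np.argwhere(counts > 0)
        return self

    def _bin_indices(self, X: np.ndarray) -> np.ndarray:
        idx = np.empty((X.shape[0], 2), dtype=int)
        for d in range(2):
            e = self.edges_[d]
            idx[:, d] = np.clip(np.searchsorted(e, X[:, d], side="right") - 1, 0, len(e) - 2)
        return idx

    def predict(self, X):
        check_is_fitted(self, "cell_mean_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_samples, 2)")
        idx = self._bin_indices(X)
        out = self.cell_mean_[idx[:, 0], idx[:, 1]]
        empty = ~np.isfinite(out)
        if np.any(empty):
            nonempty = self._nonempty_  # (m, 2)
            for i in np.flatnonzero(empty):
                d = np.abs(nonempty - idx[i]).sum(axis=1)
                best = d.min()
                candidates = nonempty[d == best]
                # ties: lexicographically lower bin index
                cell = min(map(tuple, candidates))
                out[i] = self.cell_mean_[cell]
        return out


def fit_hypercube(
    trace: GlucoseTrace,
    bins: Tuple[int, int] = (8, 8),
    *,
    strategy: str = "uniform",
) -> HypercubeRegressor:
    """Fit a per-patient hypercube model on a trace's unmasked samples."""
    deriv = derivatives(trace)
    keep = ~deriv.gap_mask & np.isfinite(deriv.first) & np.isfinite(deriv.second)
    if not np.any(keep):
        raise ValueError("no unmasked samples to fit on")
    X = np.column_stack([deriv.first[keep], deriv.second[keep]])
    return HypercubeRegressor(n_bins=bins, strategy=strategy).fit(X, trace.values[keep])


def cusum_b(trace: GlucoseTrace, model: HypercubeRegressor) -> CusumSeries:
    """Method-B CUSUM: running sum of (predicted - observed) glucose.

    Derivative-masked samples (gap-adjacent) contribute a zero increment and
    are flagged in ``gap_mask``.
    """
    check_is_fitted(model, "cell_mean_")
    deriv = derivatives(trace)
    usable = ~deriv.gap_mask & np.isfinite(deriv.first) & np.isfinite(deriv.second)
    residuals = np.zeros(len(trace))
    if np.any(usable):
        X = np.column_stack([deriv.first[usable], deriv.second[usable]])
        residuals[usable] = model.predict(X) - trace.values[usable]
    return CusumSeries(
        method="B",
        times=trace.times,
        values=np.cumsum(residuals),
        reference=None,
        gap_mask=~usable,
    )
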