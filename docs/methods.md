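# Methods

## Data model and conventions

A `GlucoseTrace` is a strictly time-ordered series of interstitial glucose
estimates in mmol/L at a nominal 5-minute cadence, with per-sample `clipped`
flags. Timestamps are naive local device clock time — the nocturnal window
is defined on the clock, so no timezone conversion is applied. The sensor is
validated above 2.2 mmol/L (40 mg/dL); "Low" device readings and any value
below the floor are set to 2.2 and flagged, never dropped, because omitting
them would bias every statistic of hypoglycemia-prone traces upward.
`clip_floor` is idempotent and length-preserving. "High" readings have no
validated ceiling; they are kept at the 22.2 mmol/L device ceiling with a
warning so they remain visible rather than silently discarded.

Unit conversion uses 18.016 mg/dL per mmol/L (the molar mass of glucose);
mg/dL is accepted only at the I/O boundary and mmol/L is canonical
internally. Duplicate timestamps in an export keep the first occurrence and
log the rest. Report tables round concentrations, slopes and percentages to
one decimal with half-up ties (matching clinical report conventions); all
in-memory objects keep full precision and rounding happens only at the
report/CSV surface.

Carbohydrate delivery prescribed in g/h is converted to mg/kg/min as
1000·(g/h)/(60·kg), the scale on which it can be compared with endogenous
glucose production estimates.

**Half-open intervals everywhere.** Clock windows are `[start, end)` — the
default nocturnal window [01:00, 05:00) contains exactly 48 samples/night at
5-minute cadence — and intervention phases are `[start, end)`, so a sample
on a boundary belongs to the later phase and every sample is assigned
exactly once. A night is labeled by the calendar date its window starts on.

**Missingness.** Nights with fewer than 80% of expected samples are excluded
from spectral analysis by default (configurable); partially complete nights
above the threshold are analyzed as-is and flagged. The nocturnal analyses
subset the trace rather than resampling it; no interpolation is performed by
default anywhere in the pipeline.

## Glycemic metrics

SD is the sample (n−1) standard deviation; CV = 100·SD/mean (mean, not
median, per the defining formula). The "ri95" band is a normal reference
interval mean ± 1.96·SD floored at 0 — a band expected to cover ~95% of
individual readings under normality. It is deliberately *not* called a
confidence interval: it scales with SD, not SD/√n.

Range occupancy uses the ADA 2020 boundary conventions exactly as defined
by the inequalities: level-2 hypoglycemia < 3.0, level-1 [3.0, 3.9), TIR
[3.9, 7.8] (narrow) and [3.9, 10.0] (wide), TAR > 7.8 and > 10.0. A value
of exactly 3.9 counts toward TIR, 7.8 toward the narrow TIR, 10.0 toward
the wide TIR. The four exclusive classes {<3.0, [3.0,3.9), [3.9,7.8], >7.8}
partition every input, so their percentages sum to 100 up to floating-point
error. Level-3 hypoglycemia is a clinical event definition (assistance
required) and is never computed from CGM values.

## Starch loads

The load clock is re-zeroed to the load start. The maximum's tie-break is
the earliest occurrence, which determines the time-to-max. Rise slope is
(max − initial)/(t_max/60), fall slope (end − max)/((end_time − t_max)/60),
both mmol/L/h. If the maximum falls on the last sample there is no falling
limb; the fall slope is reported as 0 with an explicit `fall_undefined`
flag. AUC is the trapezoid of concentration against hours above a zero
baseline (total AUC, not incremental above the initial value), consistent
in magnitude with duration × mean concentration.

Crossover comparison: arm means are computed over *all* available loads —
a patient whose opposite arm is incomplete still contributes to their own
arm's mean — while the paired two-tailed t-test (df = pairs − 1) uses
complete pairs only. This combination reproduces both the published group
means and the published paired p-value of the bundled reference dataset.
No multiple-testing correction is applied; the reference analysis reported
raw p-values across its 13 metrics, and the comparison is descriptive.

## Dynamics

Derivatives are second-order finite differences on the actual timestamp
spacing (`np.gradient` with `edge_order=2`, applied twice), exact for
quadratic profiles including the boundary points, in mmol/L per minute.
Sample pairs spanning a gap longer than twice the cadence break
differentiation; both flanking samples are masked.

CUSUM method A is Σ(Gᵢ − reference). The reference is configurable: the
series' own mean gives the classical zero-sum CUSUM (terminal value exactly
0), while a fixed baseline-period mean (default in the pipeline: the first
intervention's mean when a schedule is present) lets later phases drift
against earlier behavior, which is what makes the curve clinically readable
across interventions.

CUSUM method B is Σ(Ĝᵢ − Gᵢ) with Ĝ from the per-patient hypercube model:
an equal-width 8×8 binning of the observed (glucose′, glucose″) plane
(quantile edges optional) predicting each cell's mean observed glucose.
This is the plainest reading of a regression that "correlates absolute
glucose to first and second order derivatives"; smoother alternatives
(multilinear interpolation, local regression) would change little for the
descriptive use the series has here. Predictions for empty cells fall back
to the nearest populated cell by Manhattan bin-index distance, ties toward
the lower index. Because cell means are least-squares optimal per cell, the
training trace's residuals sum to zero — method B on its own training data
terminates at 0, and a systematic offset of c mmol/L accumulates at −c per
sample. Models are strictly per-patient; no pooling. Masked (gap-adjacent)
samples contribute zero increments and are flagged.

`HypercubeRegressor` follows the scikit-learn estimator protocol
(`fit(X, y)`/`predict`, `get_params`, fitted attributes with trailing
underscores) and composes with sklearn tooling; `fit_hypercube(trace)` is
the trace-level convenience wrapper.

## Spectral analysis

Per night: mean removal, real FFT, amplitude 2·|Xₖ|/n at bin k for
1 ≤ k ≤ n/2, frequency k/T cycles per hour (T = window length in hours; a
48-sample window yields 24 bins at 0.25 c/h spacing). Frequencies are also
reported as cycles/night (= c/h × T). The Nyquist bin uses the same 2·|X|/n
factor as every other bin — one formula throughout — and the package's
Parseval check accounts for that convention. No taper and no zero-padding
by default (the raw transform is the defining formula); a padding option
exists for display smoothness only.

Component detection: bins that are local maxima of the amplitude vector
with amplitude ≥ max(0.2 mmol/L, 20% of the night's peak). The local-maximum
requirement prevents leakage lobes of non-bin-aligned frequencies from
being counted as separate components; the threshold values are configurable
choices (no canonical rule exists) — 0.2 mmol/L is well above the noise
floor an 0.2-mmol/L-SD sensor puts in a single bin (≈ 0.04 mmol/L), and
the relative criterion keeps secondary structure comparable across nights
of different overall amplitude. Raising the threshold never increases the
component count. The dominant component is the maximal amplitude, ties
broken toward the lower frequency. The per-night summary reports the three
outcome parameters without a composite score, since none is defined.

## Synthetic generator

The generator emulates what the analyses consume: a baseline level,
sinusoidal nocturnal components (the spectral ground truth), additive
meal/hypoglycemia excursions, per-sample Gaussian sensor noise (AR(1)
autocorrelation optional, off by default — the real sensor's noise model is
unknown), and floor clipping at 2.2 mmol/L. The sampling grid is half-open
(t = 0, c, 2c, … < duration), giving exactly 288 samples/day at 5 minutes;
the default trace starts at midnight so clock-window tests are
deterministic. Event shapes are chosen for smoothness, not physiology:
hypoglycemic dips are raised cosines, meal excursions asymmetric triangles
peaking at 25% of their duration. One integer seed drives all randomness;
identical configs are bit-identical.

Load curves are sampled through their anchor points (0, initial),
(t_max, max), (end_time, end) with the anchors inserted into the grid if
off-grid, so `load_summary` inverts `generate_load_curve` exactly for the
piecewise-linear shape.

What passing tests on synthetic data do *not* show: real CGM noise is
autocorrelated and occasionally artifactual (compression lows, calibration
steps), real nocturnal patterns are not stationary sinusoids, and real
dropout is burstier than the uniform gap model. The generator validates the
*arithmetic* of the pipeline, not the physiology; conclusions about real
patients require real traces.

## Bundled reference descriptors

The per-load summary table of a published 11-patient starch-load crossover
(two arms, randomized order; two incomplete loads excluded from pairing) is
bundled in `cgmdepth.datasets`, since the underlying traces were never
deposited. The acceptance script reconstructs each complete load as a
piecewise-linear curve from its printed anchors, re-summarizes it through
the pipeline, and reproduces the published group means and paired t-test.
Printed values carry 0.05-mmol/L input rounding, so recomputed slopes are
compared within the propagated printed precision (±0.05 on each
concentration and on the slope), not by exact re-rounding.

## Problem sizes and tolerances

Default test/acceptance problem sizes: 48-sample nights, 1–28-day traces,
1000 random traces for partition closure, 100 seeded nights for noisy
amplitude recovery (recovery within 1% noise-free, 10% at noise SD
0.2 mmol/L), 100 random load specs for the round-trip identity, and
range-occupancy recovery within 1 percentage point against a hand-counted
phase-grid oracle. Derivative exactness is asserted at 1e-9 on quadratic
profiles; CUSUM-A terminal values at machine precision relative to the
series magnitude.

## Known limitations

* The hypercube estimator is a step-function regression; its predictions
  are discontinuous at bin edges and extrapolate by nearest-cell fallback.
* Spectral analysis assumes a uniform grid; irregular nights are excluded
  rather than transformed (no Lomb–Scargle).
* The interval report treats interventions as non-overlapping by
  definition; overlapping schedules are rejected, not resolved.
* Percentage metrics are computed over available samples only; heavy
  dropout biases them toward whatever state the sensor survived in.
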