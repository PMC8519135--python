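# cgmdepth

In-depth analysis of continuous glucose monitoring (CGM) data for patients
with hepatic glycogen storage disease (GSD).

Hepatic GSDs cause fasting intolerance and recurrent hypoglycemia; dietary
treatment (continuous gastric drip feeding, uncooked cornstarch regimens)
and medication (e.g. the SGLT2 inhibitor empagliflozin in GSD Ib) are
titrated against glucose homeostasis. A CGM sensor samples interstitial
glucose every 5 minutes (288 readings/day) and is validated down to
2.2 mmol/L; below-range readings are floored at that value rather than
dropped, so descriptive statistics are not biased toward euglycemia. Because
each patient serves as their own control, the package analyzes one patient's
trace per intervention phase, with a separate pass over the 01:00–05:00
clock window where diet and physical activity do not confound glucose.

## What it computes

**Per-interval glycemic metrics** — descriptive (n, mean, median, min, max,
range), variation (sample SD, variance, CV = 100·SD/mean, and the normal
reference band mean ± 1.96·SD), and ADA-2020 glycemic control as percentage
of samples: time under range TUR (level 2: < 3.0 mmol/L; level 1:
[3.0, 3.9)), time in range TIR ([3.9, 7.8] and [3.9, 10.0]) and time above
range TAR (> 7.8, > 10.0).

**Starch-load summaries** — a monitored starch load (uncooked cornstarch vs
an extended-release starch) is reduced to initial/max/end glucose, time to
maximum, rise slope (max − initial)/t_max and fall slope in mmol/L/h, and
the trapezoidal AUC in mmol/L·h. Crossover arms are compared with arm means
over all available loads and a two-tailed paired *t*-test over complete
pairs.

**Dynamics** — first/second derivatives glucose′ = dG/dt,
glucose″ = d²G/dt² (mmol/L per minute, central differences on the actual
timestamps) and two cumulative-sum series:
CUSUM_t = Σᵢ (Gᵢ − reference mean) (method A) and
CUSUM_t = Σᵢ (Ĝᵢ − Gᵢ) (method B), where Ĝ is a per-patient "hypercube"
predictor: the (glucose′, glucose″) plane is binned into an 8×8 grid and
each cell predicts the mean observed glucose of its training samples
(`HypercubeRegressor`, a scikit-learn estimator).

**Nocturnal Fourier spectrograms** — each night's 01:00–05:00 window
(n = 48) is mean-removed and transformed; the amplitude at bin k is
2·|Xₖ|/n mmol/L at frequency k/4 cycles/hour. Stacked across nights this
gives a spectrogram with three per-night outcome parameters: dominant
frequency, number of detected frequency components, and dominant amplitude
(low / few / small = stable glucose management).

**Synthetic traces** — a generator (baseline + sinusoids + meal/hypo events
+ Gaussian or AR(1) noise, floored at 2.2 mmol/L) provides ground truth for
every stage, since real traces from this population are not public.

## Worked example

```python
from cgmdepth import (SyntheticConfig, SinusoidComponent, generate_trace,
                      interval_report, build_spectrogram, stability_summary)

cfg = SyntheticConfig(
    baseline=5.5,
    components=(SinusoidComponent(frequency_per_h=1.0, amplitude=0.8),),
    noise_sd=0.2, duration_h=96.0, seed=42,
)
trace = generate_trace(cfg)                    # 4 days, 1152 samples
print(interval_report(trace)[["scope", "n", "periods", "median", "sd",
                              "cv_percent", "tir_39_78_pct"]])
print(stability_summary(build_spectrogram(trace)))
```

prints

```
      scope    n  periods  median  sd  cv_percent  tir_39_78_pct
      total 1152        4     5.5 0.6        10.8          100.0
01:00-05:00  192        4     5.5 0.6        11.0          100.0
     night  dominant_frequency_cph  dominant_cycles_per_night  n_frequencies  dominant_amplitude
2021-03-01                     1.0                        4.0              1            0.795091
2021-03-02                     1.0                        4.0              1            0.752778
2021-03-03                     1.0                        4.0              1            0.811914
2021-03-04                     1.0                        4.0              1            0.877559
```

All 1152 samples sit in the physiological band (TIR 100%), the nocturnal
window contains the expected 4 × 48 = 192 samples, and the spectral stage
recovers the injected nocturnal pattern every night: one component at
1 cycle/hour (4 cycles/night) with amplitude ≈ 0.8 mmol/L — the configured
ground truth, biased only by the sensor noise. Carbohydrate-rate
arithmetic: `carb_rate(10.4, 37.4)` → `4.6` mg/kg/min.

A CLI mirrors the library (`cgmdepth ingest|simulate|windows|metrics|loads|
dynamics|spectral|report|fixtures`); `cgmdepth report --trace trace.csv
--schedule sched.yaml --out run/` writes the full report bundle with a
provenance JSON.

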