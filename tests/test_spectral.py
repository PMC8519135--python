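import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cgmdepth import (
    SinusoidComponent,
    SyntheticConfig,
    amplitude_spectrum,
    build_spectrogram,
    detect_components,
    generate_trace,
    stability_summary,
)
from cgmdepth.spectral import Spectrogram
from cgmdepth.windows import NOCTURNAL_WINDOW

from conftest import make_trace


def sinusoid_window(amplitudes_freqs, n=48, cadence_min=5.0, baseline=5.0, noise=0.0, seed=0):
    t_h = np.arange(n) * cadence_min / 60.0
    x = np.full(n, baseline)
    for amp, freq in amplitudes_freqs:
        x = x + amp * np.sin(2 * np.pi * freq * t_h)
    if noise:
        x = x + np.random.default_rng(seed).normal(0, noise, n)
    return x


class TestAmplitudeSpectrum:
    def test_constant_window_all_zero(self):
        spec = amplitude_spectrum([5.0] * 48)
        np.testing.assert_allclose(spec.amplitudes, 0.0, atol=1e-12)

    def test_bin_aligned_sinusoid_recovered_exactly(self):
        spec = amplitude_spectrum(sinusoid_window([(1.0, 1.0)]))
        k = np.argmax(spec.amplitudes)
        assert spec.frequencies_per_h[k] == pytest.approx(1.0)  # bin 4 of a 4-h window
        assert spec.amplitudes[k] == pytest.approx(1.0, rel=1e-9)
        rest = np.delete(spec.amplitudes, k)
        np.testing.assert_allclose(rest, 0.0, atol=1e-9)

    def test_two_components_linear(self):
        spec = amplitude_spectrum(sinusoid_window([(0.8, 0.5), (0.3, 2.0)]))
        lookup = dict(zip(np.round(spec.frequencies_per_h, 6), spec.amplitudes))
        assert lookup[0.5] == pytest.approx(0.8, rel=1e-9)
        assert lookup[2.0] == pytest.approx(0.3, rel=1e-9)
        assert sum(a > 1e-9 for a in spec.amplitudes) == 2

    def test_cycles_per_night_axis(self):
        # 3 cycles per 4-h night = 0.75 cycles/hour
        spec = amplitude_spectrum(sinusoid_window([(1.0, 0.75)]))
        spec = detect_components(spec)
        assert spec.dominant.frequency_per_h == pytest.approx(0.75)
        assert spec.dominant.cycles_per_night == pytest.approx(3.0)

    def test_parseval_energy_identity(self):
        rng = np.random.default_rng(42)
        for n in (48, 47):  # even (Nyquist bin) and odd
            x = rng.uniform(3, 9, n)
            spec = amplitude_spectrum(x)
            xc = x - x.mean()
            energy = np.mean(xc**2)
            amp = spec.amplitudes
            if n % 2 == 0:
                spectral = np.sum(amp[:-1] ** 2) / 2 + amp[-1] ** 2 / 4
            else:
                spectral = np.sum(amp**2) / 2
            assert spectral == pytest.approx(energy, rel=1e-9)

    def test_hann_taper_preserves_aligned_amplitude(self):
        spec = amplitude_spectrum(sinusoid_window([(1.0, 1.0)]), taper="hann")
        k = int(np.argmin(np.abs(spec.frequencies_per_h - 1.0)))
        assert spec.amplitudes[k] == pytest.approx(1.0, rel=0.01)
        with pytest.raises(ValueError):
            amplitude_spectrum(sinusoid_window([(1.0, 1.0)]), taper="hamming")

    def test_zero_padding_densifies_frequency_axis(self):
        raw = amplitude_spectrum(sinusoid_window([(1.0, 1.0)]))
        padded = amplitude_spectrum(sinusoid_window([(1.0, 1.0)]), pad_to=96)
        assert len(padded.amplitudes) == 2 * len(raw.amplitudes)
        k = int(np.argmin(np.abs(padded.frequencies_per_h - 1.0)))
        assert padded.amplitudes[k] == pytest.approx(1.0, rel=1e-9)

    def test_too_short_window_rejected(self):
        with pytest.raises(ValueError):
            amplitude_spectrum([5.0] * 4)

    def test_noisy_amplitude_recovery_within_10pct(self):
        estimates = []
        for seed in range(100):
            x = sinusoid_window([(1.0, 1.0)], noise=0.2, seed=seed)
            spec = amplitude_spectrum(x)
            k = int(np.argmin(np.abs(spec.frequencies_per_h - 1.0)))
            estimates.append(spec.amplitudes[k])
        assert np.mean(estimates) == pytest.approx(1.0, rel=0.10)


class TestDetectComponents:
    def test_single_component(self):
        spec = detect_components(amplitude_spectrum(sinusoid_window([(1.0, 1.0)])))
        assert spec.n_frequencies == 1
        assert spec.dominant.frequency_per_h == pytest.approx(1.0)

    def test_all_zero_spectrum_no_components(self):
        spec = detect_components(amplitude_spectrum([5.0] * 48))
        assert spec.n_frequencies == 0 and spec.dominant is None

    def test_equal_amplitudes_dominant_is_lower_frequency(self):
        spec = detect_components(amplitude_spectrum(sinusoid_window([(0.8, 0.5), (0.8, 2.0)])))
        assert spec.n_frequencies == 2
        assert spec.dominant.frequency_per_h == pytest.approx(0.5)

    @given(st.floats(0.01, 2.0), st.floats(0.01, 2.0))
    @settings(derandomize=True, deadline=None, max_examples=50)
    def test_threshold_monotonicity(self, t1, t2):
        lo, hi = sorted([t1, t2])
        spec = amplitude_spectrum(sinusoid_window([(0.9, 0.5), (0.5, 1.5), (0.25, 3.0)]))
        assert detect_components(spec, hi).n_frequencies <= detect_components(spec, lo).n_frequencies

    def test_leakage_lobes_not_counted(self):
        # non-bin-aligned frequency leaks, but only the local maximum counts
        spec = detect_components(amplitude_spectrum(sinusoid_window([(1.0, 1.1)])), threshold=0.05)
        assert spec.n_frequencies <= 2  # main lobe (+ possibly one shoulder), not every leaked bin
        assert spec.dominant.frequency_per_h == pytest.approx(1.0, abs=0.25)


class TestSpectrogram:
    def test_seven_night_fixed_sinusoid(self):
        trace = generate_trace(
            SyntheticConfig(
                baseline=5.0,
                components=(SinusoidComponent(1.0, 1.0),),
                duration_h=7 * 24.0,
            )
        )
        spg = build_spectrogram(trace, NOCTURNAL_WINDOW)
        assert len(spg) == 7
        assert all(nt.n_frequencies == 1 for nt in spg.nights)
        matrix = spg.to_matrix()
        assert matrix.shape == (7, 24)  # 48-sample window -> 24 bins

    def test_quiet_night_has_no_components(self):
        quiet = generate_trace(
            SyntheticConfig(baseline=5.0, noise_sd=0.02, duration_h=24.0, seed=1)
        )
        spg = build_spectrogram(quiet, NOCTURNAL_WINDOW)
        assert len(spg) == 1
        assert spg.nights[0].n_frequencies == 0

    def test_empty_trace_empty_spectrogram(self):
        spg = build_spectrogram(make_trace([]), NOCTURNAL_WINDOW)
        assert len(spg) == 0
        assert spg.to_matrix().empty and spg.to_long_frame().empty

    def test_incomplete_nights_excluded(self):
        from cgmdepth import inject_gaps

        trace = generate_trace(SyntheticConfig(
            baseline=5.0, components=(SinusoidComponent(1.0, 1.0),), duration_h=48.0,
        ))
        night2 = trace.start + pd.Timedelta(days=1, hours=1)
        gapped = inject_gaps(trace, [(night2, night2 + pd.Timedelta(hours=2))])  # 50% of night 2
        spg = build_spectrogram(gapped, NOCTURNAL_WINDOW, min_completeness=0.8)
        assert len(spg) == 1


class TestStabilitySummary:
    def test_stable_nights_constant_rows(self):
        trace = generate_trace(SyntheticConfig(
            baseline=5.0, components=(SinusoidComponent(1.0, 1.0),), duration_h=3 * 24.0,
        ))
        table = stability_summary(build_spectrogram(trace, NOCTURNAL_WINDOW))
        assert len(table) == 3
        assert table["n_frequencies"].nunique() == 1
        assert table["dominant_frequency_cph"].nunique() == 1

    def test_extra_component_raises_count_one_night(self):
        base = SyntheticConfig(
            baseline=5.0, components=(SinusoidComponent(1.0, 1.0),), duration_h=24.0,
        )
        one = generate_trace(base)
        two = generate_trace(base.replace(
            components=(SinusoidComponent(1.0, 1.0), SinusoidComponent(2.0, 0.8)),
            start=pd.Timestamp(base.start) + pd.Timedelta(days=1),
        ))
        from cgmdepth.trace import concat_traces

        spg = build_spectrogram(concat_traces([one, two]), NOCTURNAL_WINDOW)
        table = stability_summary(spg)
        assert table["n_frequencies"].tolist() == [1, 2]

    def test_amplitude_doubling_doubles_dominant(self):
        base = SyntheticConfig(
            baseline=5.0, components=(SinusoidComponent(1.0, 0.7),), duration_h=24.0,
        )
        a = stability_summary(build_spectrogram(generate_trace(base), NOCTURNAL_WINDOW))
        b = stability_summary(build_spectrogram(
            generate_trace(base.replace(components=(SinusoidComponent(1.0, 1.4),))),
            NOCTURNAL_WINDOW,
        ))
        assert b["dominant_amplitude"].iloc[0] == pytest.approx(
            2 * a["dominant_amplitude"].iloc[0], rel=1e-9
        )
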