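"""Per-night Fourier analysis of the nocturnal glucose window.

Each night's 01:00-05:00 window (48 samples at 5-minute cadence) is
mean-removed and discrete-Fourier-transformed; the amplitude at bin k
(1 <= k <= n/2) is ``2 * |X_k| / n`` mmol/L at frequency ``k / T`` cycles
per hour (T = window duration in hours), so a bin-aligned sinusoid of
amplitude A is recovered exactly as A. Stacking nights yields a spectrogram;
its three per-night outcome parameters are the dominant frequency, the number
of detected frequency components and the dominant amplitude — a stable night
has few, low, small components.

Component detection is thresholded (default: the larger of 0.2 mmol/L and
20% of the night's peak amplitude) and restricted to local maxima of the
amplitude vector so that leakage lobes of non-bin-aligned frequencies are
not counted as separate components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .trace import DEFAULT_CADENCE_MIN, GlucoseTrace
from .windows import DEFAULT_COMPLETENESS, NOCTURNAL_WINDOW, ClockWindow, nights_of

__all__ = [
    "FrequencyComponent",
    "NightSpectrum",
    "Spectrogram",
    "amplitude_spectrum",
    "detect_components",
    "build_spectrogram",
    "stability_summary",
]

log = logging.getLogger(__name__)

MIN_WINDOW_SAMPLES = 8


@dataclass(frozen=True)
class FrequencyComponent:
    """One detected sinusoidal component of a night's glucose pattern."""

    frequency_per_h: float  # cycles per hour
    cycles_per_night: float  # frequency * window hours
    amplitude: float  # mmol/L


@dataclass(frozen=True)
class NightSpectrum:
    """Amplitude spectrum of one night's window."""

    date: Optional[pd.Timestamp]
    n: int  # window sample count
    duration_h: float
    frequencies_per_h: np.ndarray  # bins 1..n//2, cycles per hour
    amplitudes: np.ndarray  # mmol/L per bin
    components: tuple = ()  # filled by detect_components

    @property
    def n_frequencies(self) -> int:
        return len(self.components)

    @property
    def dominant(self) -> Optional[FrequencyComponent]:
        """Maximal-amplitude component; ties go to the lower frequency."""
        if not self.components:
            return None
        return max(self.components, key=lambda c: (c.amplitude, -c.frequency_per_h))


def amplitude_spectrum(
    values,
    cadence_min: float = DEFAULT_CADENCE_MIN,
    *,
    date: Optional[pd.Timestamp] = None,
    taper: Optional[str] = None,
    pad_to: Optional[int] = None,
) -> NightSpectrum:
    """One-sided DFT amplitude spectrum of a uniform nocturnal window.

    The mean is removed first (bin 0 carries no pattern information), so a
    constant window has an all-zero spectrum. Amplitudes are ``2|X_k|/n``
    for every bin including Nyquist, matching the single amplitude formula
    used throughout.

    ``taper="hann"`` applies a Hann window (amplitudes rescaled by the
    window's coherent gain so bin-aligned sinusoids keep their height);
    ``pad_to`` zero-pads the transform to a denser frequency axis. Both are
    off by default — the raw transform is the defining analysis; padding is
    an interpolation of the spectrum for display smoothness only.
    """
    arr = np.asarray(values, dtype=float)
    n = arr.size
    if n < MIN_WINDOW_SAMPLES:
        raise ValueError(f"window too short for spectral analysis (n={n} < {MIN_WINDOW_SAMPLES})")
    duration_h = n * cadence_min / 60.0
    x = arr - arr.mean()
    gain = 1.0
    if taper == "hann":
        w = np.hanning(n)
        x = x * w
        gain = float(w.mean())
    elif taper is not None:
        raise ValueError(f"unknown taper {taper!r}")
    m = n if pad_to is None else int(pad_to)
    if m < n:
        raise ValueError("pad_to must be >= window length")
    spec = np.fft.rfft(x, m)
    k = np.arange(1, m // 2 + 1)
    amplitudes = 2.0 * np.abs(spec[k]) / (n * gain)
    freqs = k / (m * cadence_min / 60.0)
    return NightSpectrum(
        date=date, n=n, duration_h=duration_h, frequencies_per_h=freqs, amplitudes=amplitudes
    )


def _local_maxima(amp: np.ndarray) -> np.ndarray:
    """Boolean mask of local maxima (plateau-tolerant, boundary-aware)."""
    if amp.size == 1:
        return np.array([True])
    left = np.r_[True, amp[1:] >= amp[:-1]]
    right = np.r_[amp[:-1] >= amp[1:], True]
    return left & right


def detect_components(
    spectrum: NightSpectrum,
    threshold: Optional[float] = None,
    *,
    relative: float = 0.2,
    absolute: float = 0.2,
) -> NightSpectrum:
    """Fill in detected components: local-maximum bins above threshold.

    ``threshold`` overrides the default ``max(absolute, relative * peak)``
    (mmol/L). Raising the threshold never increases the component count.
    """
    amp = spectrum.amplitudes
    if amp.size == 0 or float(np.max(amp)) == 0.0:
        return replace(spectrum, components=())
    if threshold is None:
        threshold = max(absolute, relative * float(np.max(amp)))
    keep = (amp >= threshold) & _local_maxima(amp)
    comps = tuple(
        FrequencyComponent(
            frequency_per_h=float(f),
            cycles_per_night=float(f * spectrum.duration_h),
            amplitude=float(a),
        )
        for f, a in zip(spectrum.frequencies_per_h[keep], amp[keep])
    )
    return replace(spectrum, components=comps)


@dataclass(frozen=True)
class Spectrogram:
    """Night-by-night stack of amplitude spectra over one clock window."""

    nights: tuple  # NightSpectrum, strictly increasing dates
    window: ClockWindow

    def __len__(self) -> int:
        return len(self.nights)

    def to_matrix(self) -> pd.DataFrame:
        """night x frequency-bin amplitude matrix (for waterfall plotting)."""
        if not self.nights:
            return pd.DataFrame()
        rows = {nt.date: nt.amplitudes for nt in self.nights}
        cols = self.nights[0].frequencies_per_h
        return pd.DataFrame.from_dict(rows, orient="index", columns=np.round(cols, 6))

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format (night, frequency_cph, amplitude) table."""
        records = [
            {"night": nt.date, "frequency_cph": float(f), "amplitude": float(a)}
            for nt in self.nights
            for f, a in zip(nt.frequencies_per_h, nt.amplitudes)
        ]
        return pd.DataFrame(records, columns=["night", "frequency_cph", "amplitude"])


def build_spectrogram(
    trace: GlucoseTrace,
    window: ClockWindow = NOCTURNAL_WINDOW,
    *,
    threshold: Optional[float] = None,
    min_completeness: float = DEFAULT_COMPLETENESS,
) -> Spectrogram:
    """Per-night spectra of a multi-day trace.

    Nights below the completeness threshold (or too short for a transform)
    are excluded with a logged reason.
    """
    spectra: List[NightSpectrum] = []
    for night in nights_of(trace, window):
        if not night.eligible(min_completeness):
            log.info(
                "night %s excluded: %d/%d samples (%.0f%% < %.0f%%)",
                night.date.date(), night.n, night.expected_n,
                100 * night.completeness, 100 * min_completeness,
            )
            continue
        if night.n < MIN_WINDOW_SAMPLES:
            log.info("night %s excluded: too short (n=%d)", night.date.date(), night.n)
            continue
        spec = amplitude_spectrum(night.trace.values, trace.cadence_min, date=night.date)
        spectra.append(detect_components(spec, threshold))
    if not spectra:
        log.warning("no eligible nights; spectrogram is empty")
    return Spectrogram(nights=tuple(spectra), window=window)


def stability_summary(spectrogram: Spectrogram) -> pd.DataFrame:
    """The three per-night outcome parameters as a table.

    Columns: night, dominant frequency (cycles/h and cycles/night), number
    of detected frequencies, dominant amplitude. No composite score is
    defined — the three parameters are read jointly (low/few/small = stable).
    """
    rows = []
    for nt in spectrogram.nights:
        dom = nt.dominant
        rows.append(
            {
                "night": nt.date,
                "dominant_frequency_cph": dom.frequency_per_h if dom else float("nan"),
                "dominant_cycles_per_night": dom.cycles_per_night if dom else float("nan"),
                "n_frequencies": nt.n_frequencies,
                "dominant_amplitude": dom.amplitude if dom else float("nan"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "night",
            "dominant_frequency_cph",
            "dominant_cycles_per_night",
            "n_frequencies",
            "dominant_amplitude",
        ],
    )


def plot_spectrogram(spectrogram: Spectrogram, path=None, *, cmap: str = "jet"):
    """Waterfall plot (night vs frequency, color = amplitude); optional save."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    matrix = spectrogram.to_matrix()
    fig, ax = plt.subplots(figsize=(8, 4))
    if not matrix.empty:
        mesh = ax.pcolormesh(
            matrix.columns.astype(float),
            np.arange(len(matrix)),
            matrix.values,
            cmap=cmap,
            shading="nearest",
        )
        fig.colorbar(mesh, ax=ax, label="amplitude (mmol/L)")
        ax.set_yticks(np.arange(len(matrix)))
        ax.set_yticklabels([str(pd.Timestamp(d).date()) for d in matrix.index])
    ax.set_xlabel("frequency (cycles/hour)")
    ax.set_ylabel("night")
    ax.set_title(f"Nocturnal spectrogram {spectrogram.window}")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
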