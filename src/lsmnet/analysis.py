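"""Signal quantification: coefficient of variation, zero-lag cross-correlation
and continuous-wavelet-transform (CWT) frequency-power summaries.

The frequency analysis mirrors the approach of windowed wavelet power: an
analytic Morlet CWT (omega0 = 6, 12 voices per octave, 1-500 Hz by default)
is computed over the whole trace, and for each frequency the maximum power
within each 1-s presentation window is reported.  Samples whose cone of
influence extends past the trace boundary are excluded from the per-window
maxima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt

from .signals import ContinuousSignal

__all__ = [
    "FrequencyPowerSummary",
    "coefficient_of_variation",
    "zero_lag_xcorr",
    "frequency_power",
    "mean_summary",
    "compare_conditions",
]

# analytic Morlet with omega0 = 6: gaussian envelope exp(-t^2/2) (B = 2),
# center frequency 6/(2*pi) cycles per unit time
MORLET_OMEGA0 = 6.0
DEFAULT_WAVELET = f"cmor2.0-{MORLET_OMEGA0 / (2 * np.pi):.6f}"


def _values(signal) -> np.ndarray:
    if isinstance(signal, ContinuousSignal):
        return signal.values
    return np.asarray(signal, dtype=float)


def coefficient_of_variation(signal) -> float:
    """CV = sigma(A) / mean(A) over the full signal; requires a positive mean."""
    x = _values(signal)
    m = x.mean()
    if m <= 0:
        raise ValueError("CV undefined: signal mean must be positive")
    return float(x.std() / m)


def zero_lag_xcorr(x, y) -> float:
    """Normalized zero-lag correlation sum(x*y)/sqrt(sum(x^2)*sum(y^2)).

    Identical signals give 1, orthogonal signals 0 (coefficient normalization
    of the zero-lag cross-correlation, no mean subtraction).
    """
    xv, yv = _values(x), _values(y)
    if xv.size != yv.size:
        raise ValueError("signals must have equal length")
    nx = np.dot(xv, xv)
    ny = np.dot(yv, yv)
    if nx == 0 or ny == 0:
        raise ValueError("zero-lag correlation undefined for an all-zero signal")
    return float(np.dot(xv, yv) / np.sqrt(nx * ny))


@dataclass
class FrequencyPowerSummary:
    """Per-frequency maximum CWT power within each presentation window.

    ``max_power`` has shape (n_frequencies, n_windows); entries are NaN where
    an entire window fell inside the cone of influence.  ``aggregate`` is the
    NaN-aware mean across windows.
    """

    frequencies: np.ndarray
    max_power: np.ndarray
    window_ms: float
    wavelet: str = DEFAULT_WAVELET
    metadata: dict = field(default_factory=dict)

    @property
    def aggregate(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.max_power, axis=1)

    def band_power(self, band: tuple[float, float]) -> float:
        """Mean aggregate power over frequencies inside ``band`` (Hz)."""
        lo, hi = band
        mask = (self.frequencies >= lo) & (self.frequencies <= hi)
        if not mask.any():
            raise ValueError(f"no frequencies inside band {band}")
        return float(np.nanmean(self.aggregate[mask]))

    def to_frame(self) -> pd.DataFrame:
        n_f, n_w = self.max_power.shape
        return pd.DataFrame(
            {
                "frequency_hz": np.repeat(self.frequencies, n_w),
                "window_index": np.tile(np.arange(n_w), n_f),
                "max_power": self.max_power.ravel(),
            }
        )


def _frequency_grid(freq_range: tuple[float, float], voices_per_octave: int) -> np.ndarray:
    f_min, f_max = freq_range
    if not (0 < f_min < f_max):
        raise ValueError("freq_range must satisfy 0 < f_min < f_max")
    n_oct = np.log2(f_max / f_min)
    k = np.arange(int(np.floor(n_oct * voices_per_octave)) + 1)
    return f_min * 2.0 ** (k / voices_per_octave)


def frequency_power(
    trace,
    dt: float | None = None,
    window_ms: float = 1000.0,
    freq_range: tuple[float, float] = (1.0, 500.0),
    voices_per_octave: int = 12,
    wavelet: str = DEFAULT_WAVELET,
) -> FrequencyPowerSummary:
    """Windowed maximum CWT power of a trace.

    The analytic-wavelet CWT magnitude is computed over the whole trace; per
    frequency, the maximum squared magnitude within each window of
    ``window_ms`` is reported.  The duration must be an integer multiple of
    the window length.
    """
    if isinstance(trace, ContinuousSignal):
        x, dt = trace.values, trace.dt
    else:
        x = np.asarray(trace, dtype=float)
        if dt is None:
            raise ValueError("dt required when trace is a bare array")
    n = x.size
    w_samp = int(round(window_ms / dt))
    if w_samp > n:
        raise ValueError("window longer than signal")
    if n % w_samp:
        raise ValueError("signal duration must be an integer multiple of window_ms")
    n_win = n // w_samp

    freqs = _frequency_grid(freq_range, voices_per_octave)
    dt_s = dt / 1000.0
    fc = pywt.central_frequency(wavelet)
    scales = fc / (freqs * dt_s)
    coefs, _ = pywt.cwt(x, scales, wavelet, sampling_period=dt_s, method="fft")
    power = np.abs(coefs) ** 2  # (n_freq, n)

    # mask boundary samples inside the cone of influence (e-folding time
    # sqrt(2)*scale samples for the Morlet wavelet)
    n_coi = np.ceil(np.sqrt(2.0) * scales).astype(int)
    for i, nc in enumerate(n_coi):
        nc = min(nc, n)
        if nc > 0:
            power[i, :nc] = np.nan
            power[i, n - nc :] = np.nan

    mp = np.full((freqs.size, n_win), np.nan)
    chunks = power.reshape(freqs.size, n_win, w_samp)
    valid = ~np.all(np.isnan(chunks), axis=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # fully-masked windows
        mp[valid] = np.nanmax(chunks, axis=2)[valid]
    return FrequencyPowerSummary(
        frequencies=freqs,
        max_power=mp,
        window_ms=window_ms,
        wavelet=wavelet,
        metadata={"dt": dt, "voices_per_octave": voices_per_octave},
    )


def mean_summary(summaries: list[FrequencyPowerSummary]) -> FrequencyPowerSummary:
    """Average per-window maxima across summaries (e.g. across neurons)."""
    ref = summaries[0]
    for s in summaries[1:]:
        if not np.allclose(s.frequencies, ref.frequencies):
            raise ValueError("frequency grids differ")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        stacked = np.nanmean([s.max_power for s in summaries], axis=0)
    return FrequencyPowerSummary(
        frequencies=ref.frequencies,
        max_power=stacked,
        window_ms=ref.window_ms,
        wavelet=ref.wavelet,
        metadata={"n_averaged": len(summaries), **ref.metadata},
    )


def compare_conditions(
    summary_a: FrequencyPowerSummary,
    summary_b: FrequencyPowerSummary,
    band: tuple[float, float],
) -> tuple[np.ndarray, float]:
    """Elementwise aggregate power ratio a/b plus the band-integrated ratio."""
    if summary_a.frequencies.size != summary_b.frequencies.size or not np.allclose(
        summary_a.frequencies, summary_b.frequencies
    ):
        raise ValueError("frequency grids do not match")
    ratio = summary_a.aggregate / summary_b.aggregate
    band_ratio = summary_a.band_power(band) / summary_b.band_power(band)
    return ratio, band_ratio
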