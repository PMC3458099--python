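"""Conventional event-related EEG measures: ERP, band-limited ERD/ERS, Welch PSD.

All filtering is zero-phase: windowed-sinc (Hamming) FIR kernels applied
forward-backward with ``scipy.signal.filtfilt``, so band-limited features are
not delayed.  Filter order defaults to three times the longest period in the
band, capped so the forward-backward padding fits in the epoch.

ERD/ERS follows the Pfurtscheller amplitude convention: the trial-mean Hilbert
envelope of the band-passed signal expressed as a percentage change from its
mean over a pre-stimulus baseline window; positive = synchronization
(amplitude increase), negative = desynchronization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .epochs import EpochSet
from .exceptions import ConfigurationError, DataError

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "PSDEstimate",
    "erp",
    "band_envelopes",
    "erd_ers",
    "welch_psd",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [f_lo, f_hi) in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self):
        if not (0 <= self.f_lo < self.f_hi):
            raise ConfigurationError(f"invalid band {self.name}: {self.f_lo}-{self.f_hi} Hz")


DEFAULT_BANDS = {
    b.name: b
    for b in (
        BandDefinition("delta", 0.1, 3.9),
        BandDefinition("theta", 4.0, 7.9),
        BandDefinition("alpha", 8.0, 12.9),
        BandDefinition("beta1", 13.0, 19.9),
        BandDefinition("beta2", 20.0, 29.9),
        BandDefinition("gamma", 30.0, 48.0),
    )
}


@dataclass
class PSDEstimate:
    """Welch power spectral density per channel on a uniform frequency grid."""

    frequencies: np.ndarray
    power: np.ndarray  # (n_channels, n_freqs)
    segment_length: int
    window: str
    overlap: int

    @property
    def bin_spacing(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


def _fir_taps(rate: float, f_char: float, n_samples: int) -> int:
    """FIR order: 3x the longest period in the band, capped for filtfilt padding."""
    taps = int(round(3.0 * rate / f_char))
    cap = (n_samples - 1) // 3  # filtfilt needs padlen = 3*taps < n_samples
    taps = max(5, min(taps, cap))
    if taps % 2 == 0:
        taps -= 1
    return taps


def lowpass_fir(x: np.ndarray, rate: float, cutoff: float, axis: int = -1) -> np.ndarray:
    """Zero-phase windowed-sinc low-pass."""
    if cutoff >= rate / 2:
        raise ConfigurationError("cutoff must be below Nyquist")
    taps = _fir_taps(rate, cutoff, x.shape[axis])
    b = signal.firwin(taps, cutoff, fs=rate)
    return signal.filtfilt(b, [1.0], x, axis=axis)


def bandpass_fir(x: np.ndarray, rate: float, band: BandDefinition, axis: int = -1) -> np.ndarray:
    """Zero-phase windowed-sinc band-pass for ``band``."""
    if band.f_hi >= rate / 2:
        raise ConfigurationError(f"band {band.name} reaches the Nyquist frequency")
    taps = _fir_taps(rate, band.f_lo, x.shape[axis])
    b = signal.firwin(taps, [band.f_lo, band.f_hi], pass_zero=False, fs=rate)
    return signal.filtfilt(b, [1.0], x, axis=axis)


def erp(
    e: EpochSet,
    baseline: tuple[float, float] = (-0.2, 0.0),
    lowpass: float | None = 20.0,
) -> np.ndarray:
    """Event-related potential: baseline-corrected trial mean, low-pass smoothed.

    Per trial, the mean over the baseline window is subtracted; trials are
    averaged per channel and the average is smoothed with a zero-phase FIR
    low-pass (default 20 Hz).  Returns (n_channels, n_samples).
    """
    if e.n_trials < 1:
        raise DataError("need at least one trial")
    sl = e.sampling.window_slice(*baseline)
    corrected = e.data - e.data[:, :, sl].mean(axis=2, keepdims=True)
    avg = corrected.mean(axis=0)
    if lowpass is not None:
        avg = lowpass_fir(avg, e.sampling.rate, lowpass, axis=-1)
    return avg


def band_envelopes(e: EpochSet, band: BandDefinition) -> np.ndarray:
    """Per-trial Hilbert amplitude envelope of the band-passed data.

    Returns (n_trials, n_channels, n_samples).
    """
    filtered = bandpass_fir(e.data, e.sampling.rate, band, axis=-1)
    return np.abs(signal.hilbert(filtered, axis=-1))


def erd_ers(
    e: EpochSet,
    band: BandDefinition,
    baseline: tuple[float, float] = (-0.5, 0.0),
) -> np.ndarray:
    """ERD/ERS percentage series per channel for one frequency band.

    100 * (trial-mean envelope / its baseline mean - 1); 0 means no change,
    positive synchronization, negative desynchronization.
    """
    env = band_envelopes(e, band).mean(axis=0)  # (n_channels, n_samples)
    sl = e.sampling.window_slice(*baseline)
    ref = env[:, sl].mean(axis=1, keepdims=True)
    if np.any(ref <= 0):
        raise DataError("zero baseline amplitude: ERD/ERS normalization undefined")
    return 100.0 * (env / ref - 1.0)


def welch_psd(
    e: EpochSet,
    window: tuple[float, float],
    segment_length: int = 512,
) -> PSDEstimate:
    """Welch PSD (Hanning window, 50% overlap) over a time window, per channel.

    Periodograms are averaged over segments, trials and conditions; frequency
    resolution is rate / segment_length.
    """
    sl = e.sampling.window_slice(*window)
    n_avail = sl.stop - sl.start
    if n_avail < segment_length:
        raise DataError(
            f"window holds {n_avail} samples; need at least {segment_length}"
        )
    overlap = segment_length // 2
    freqs, pxx = signal.welch(
        e.data[:, :, sl],
        fs=e.sampling.rate,
        window="hann",
        nperseg=segment_length,
        noverlap=overlap,
        axis=-1,
    )
    return PSDEstimate(
        frequencies=freqs,
        power=pxx.mean(axis=0),
        segment_length=segment_length,
        window="hann",
        overlap=overlap,
    )
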