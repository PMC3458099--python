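"""Empirical mode decomposition by sifting.

EMD splits a signal into intrinsic mode functions (IMFs): zero-mean
oscillations whose counts of extrema and zero crossings differ by at most one,
ordered from highest to lowest frequency.  One sifting pass subtracts the mean
of the cubic-spline envelopes through the local maxima and minima; passes
repeat until a Cauchy-type criterion

    SD = sum((h_prev - h)^2) / sum(h_prev^2) < sd_threshold

is met (default 0.2, hard cap ``max_siftings`` = 50), then the IMF is removed
and sifting continues on the remainder.  Envelope splines are natural cubics
through the extrema with two extrema mirrored at each end to limit end swings.
Extremum detection uses strict inequality with plateaus resolved to their
midpoint.  By construction the IMFs plus residual reconstruct the input
exactly (telescoping subtraction).

On white noise EMD behaves as a dyadic filter bank: successive IMF mean
frequencies drop by a factor of about two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .epochs import EpochSet, SamplingSpec
from .exceptions import DataError, MonotonicSignalError

__all__ = [
    "IMFSet",
    "find_extrema",
    "envelope_mean",
    "sift",
    "imf_mean_frequency",
    "decompose_epochs",
]


@dataclass
class IMFSet:
    """Ordered IMFs (row 0 = highest frequency) plus the residual of one trial."""

    imfs: np.ndarray  # (n_imfs, n_samples)
    residual: np.ndarray  # (n_samples,)

    @property
    def n_imfs(self) -> int:
        return self.imfs.shape[0]

    def reconstruct(self) -> np.ndarray:
        return self.imfs.sum(axis=0) + self.residual

    def mean_frequencies(self, sampling: SamplingSpec, window=None) -> np.ndarray:
        """Amplitude-weighted mean instantaneous frequency of each IMF (Hz)."""
        return np.array(
            [imf_mean_frequency(imf, sampling, window=window) for imf in self.imfs]
        )


def find_extrema(x: np.ndarray):
    """Indices of local maxima and minima (strict; plateau midpoints)."""
    x = np.asarray(x, dtype=float)
    dx = np.diff(x)
    nz = np.flatnonzero(dx != 0)
    if nz.size < 2:
        return np.array([], dtype=int), np.array([], dtype=int)
    s = np.sign(dx[nz])
    turns = np.flatnonzero(s[:-1] != s[1:])
    if turns.size == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    # a plateau extremum spans samples nz[t]+1 .. nz[t+1]; take its midpoint
    lo = nz[turns] + 1
    hi = nz[turns + 1]
    idx = (lo + hi) // 2
    kind = s[turns]  # +1: rising then falling -> maximum
    return idx[kind > 0], idx[kind < 0]


def _mirrored_spline(idx: np.ndarray, val: np.ndarray, n: int) -> np.ndarray:
    """Natural cubic through (idx, val), with two points mirrored about each end."""
    k = min(2, idx.size)
    left_i = -idx[:k][::-1]  # reflect about sample 0
    left_v = val[:k][::-1]
    right_i = 2 * (n - 1) - idx[-k:][::-1]  # reflect about the last sample
    right_v = val[-k:][::-1]
    xi = np.concatenate([left_i, idx, right_i])
    vi = np.concatenate([left_v, val, right_v])
    # mirroring can duplicate knots when an extremum sits on the boundary
    xi, keep = np.unique(xi, return_index=True)
    vi = vi[keep]
    if xi.size < 2:
        raise MonotonicSignalError("not enough spline knots")
    spline = CubicSpline(xi, vi, bc_type="natural")
    return spline(np.arange(n))


def envelope_mean(x: np.ndarray) -> np.ndarray:
    """Pointwise mean of the upper (maxima) and lower (minima) cubic envelopes.

    Raises :class:`MonotonicSignalError` when the signal has fewer than two
    maxima or two minima, which signals the caller to stop sifting.
    """
    x = np.asarray(x, dtype=float)
    maxima, minima = find_extrema(x)
    if maxima.size < 2 or minima.size < 2:
        raise MonotonicSignalError(
            f"too few extrema ({maxima.size} maxima, {minima.size} minima)"
        )
    upper = _mirrored_spline(maxima, x[maxima], x.size)
    lower = _mirrored_spline(minima, x[minima], x.size)
    return 0.5 * (upper + lower)


def _is_imf(h: np.ndarray) -> bool:
    """Defining property: extrema and zero-crossing counts differ by <= 1."""
    maxima, minima = find_extrema(h)
    n_ext = maxima.size + minima.size
    n_zc = int(np.sum(np.diff(np.signbit(h)) != 0))
    return abs(n_ext - n_zc) <= 1


def sift(
    x: np.ndarray,
    max_imfs: int = 6,
    sd_threshold: float = 0.2,
    max_siftings: int = 50,
) -> IMFSet:
    """Decompose ``x`` into up to ``max_imfs`` IMFs plus a residual.

    A mode is accepted once the Cauchy criterion is met *and* it satisfies the
    IMF defining property (or the sifting cap is reached).  Stops early when
    the remainder becomes monotonic (too few extrema); any remainder after
    ``max_imfs`` IMFs is folded into the residual, so
    ``sum(imfs) + residual == x`` holds exactly for every input.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 16:
        raise DataError("sift expects a 1-D series of at least 16 samples")
    if not np.isfinite(x).all():
        raise DataError("sift input contains non-finite values")

    imfs = []
    remainder = x.copy()
    for _ in range(max_imfs):
        h = remainder.copy()
        extracted = False
        for _ in range(max_siftings):
            try:
                m = envelope_mean(h)
            except MonotonicSignalError:
                break
            h -= m
            extracted = True
            denom = np.sum((h + m) ** 2)
            if denom == 0 or (np.sum(m**2) / denom < sd_threshold and _is_imf(h)):
                break
        if not extracted:
            break
        imfs.append(h)
        remainder = remainder - h
    if not imfs:
        raise MonotonicSignalError("input has too few extrema to extract any IMF")
    return IMFSet(imfs=np.vstack(imfs), residual=remainder)


def imf_mean_frequency(
    imf: np.ndarray, sampling: SamplingSpec, window=None
) -> float:
    """Amplitude-weighted mean Hilbert instantaneous frequency over ``window``.

    ``window`` is a (t_lo, t_hi) pair in seconds (default: the interior of the
    epoch, excluding the 100 ms edge-distorted margins).
    """
    from .analytic import analytic  # deferred: avoid import cycle

    series = analytic(imf, sampling.rate)
    if window is None:
        sl = slice(series.edge_samples, imf.size - series.edge_samples)
    else:
        sl = sampling.window_slice(*window)
    amp = series.amplitude[sl]
    freq = series.frequency[sl]
    total = amp.sum()
    if total <= 0:
        raise DataError("zero-amplitude IMF: mean frequency undefined")
    return float(np.sum(amp * freq) / total)


def decompose_epochs(
    e: EpochSet,
    channel: int = 0,
    max_imfs: int = 6,
    sd_threshold: float = 0.2,
    max_siftings: int = 50,
) -> np.ndarray:
    """Sift every trial of one channel; returns (n_trials, max_imfs, n_samples).

    Raises :class:`DataError` if any trial yields fewer than ``max_imfs`` IMFs,
    since per-ordinal aggregation requires equal counts.
    """
    out = np.empty((e.n_trials, max_imfs, e.n_samples))
    for k in range(e.n_trials):
        s = sift(
            e.data[k, channel],
            max_imfs=max_imfs,
            sd_threshold=sd_threshold,
            max_siftings=max_siftings,
        )
        if s.n_imfs < max_imfs:
            raise DataError(
                f"trial {k} produced only {s.n_imfs} IMFs (need {max_imfs})"
            )
        out[k] = s.imfs
    return out
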