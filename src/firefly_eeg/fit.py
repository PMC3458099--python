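"""Comparing simulated and reference data; estimating the model's timing parameters.

Provides time-lagged Pearson correlation between response time courses, the
square-root law fit t = k*sqrt(T) + c linking synchronization latency to
oscillation period, a grid search over the per-channel target phase, and
estimation of t_synch/t_desynch from the phase-locking-value time course of
each IMF (t_synch = PLV argmax; phase-locked interval = contiguous samples
with PLV within 5% of the maximum).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .analytic import IMFResponseSummary
from .epochs import SamplingSpec
from .exceptions import DataError
from .simulate import FireflyConfig, SpectrumWeights, complex_mean_response

__all__ = [
    "FitResult",
    "lagged_correlation",
    "fit_sqrt_law",
    "search_target_phase",
    "estimate_tsynch_from_plv",
]


@dataclass
class FitResult:
    """Outcome of a model/reference comparison or timing-law fit."""

    r: float | None = None
    lag: float | None = None
    phi_target: float | None = None
    k: float | None = None
    c: float | None = None
    r_squared: float | None = None
    rmse: float | None = None


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DataError("constant series: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def lagged_correlation(
    a: np.ndarray,
    b: np.ndarray,
    sampling: SamplingSpec,
    max_lag: float = 0.2,
    window: tuple[float, float] = (0.0, 1.0),
) -> tuple[float, float]:
    """Maximum Pearson r between a and b over integer-sample lags of b.

    A positive lag means b is delayed relative to a (b[t] matches a[t - lag]).
    Correlation is computed on ``window``; ties in r break toward zero lag.
    Returns (r_max, lag_at_max_seconds).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DataError("series must share the time grid")
    sl = sampling.window_slice(*window)
    max_shift = int(round(max_lag * sampling.rate))
    if sl.start - max_shift < 0 or sl.stop + max_shift > a.size:
        raise DataError("window +/- max_lag exceeds the epoch")
    shifts = np.arange(-max_shift, max_shift + 1)
    # visit lags by increasing |lag| so strict improvement == tie toward zero
    order = np.argsort(np.abs(shifts), kind="stable")
    best_r, best_lag = -np.inf, 0.0
    aw = a[sl]
    for sh in shifts[order]:
        bw = b[sl.start + sh : sl.stop + sh]
        r = _pearson(aw, bw)
        if r > best_r + 1e-15:
            best_r, best_lag = r, sh / sampling.rate
    return best_r, best_lag


def fit_sqrt_law(periods, times) -> FitResult:
    """Least-squares fit of t = k*sqrt(T) + c with goodness R^2 and RMSE."""
    T = np.asarray(periods, dtype=float)
    t = np.asarray(times, dtype=float)
    if T.size != t.size or T.size < 3:
        raise DataError("need at least 3 (period, time) pairs")
    if np.any(T <= 0):
        raise DataError("periods must be positive")
    x = np.sqrt(T)
    if np.ptp(x) == 0:
        raise DataError("degenerate design: all periods equal")
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, t, rcond=None)
    k, c = float(coef[0]), float(coef[1])
    pred = A @ coef
    ss_res = float(np.sum((t - pred) ** 2))
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    # flat response: R^2 is ill-defined, report 0 (no variance explained)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 1e-12 * max(1.0, float(np.sum(t**2))) else 0.0
    return FitResult(k=k, c=c, r_squared=r2, rmse=float(np.sqrt(ss_res / t.size)))


def search_target_phase(
    reference_erp: np.ndarray,
    cfg: FireflyConfig,
    w: SpectrumWeights,
    sampling: SamplingSpec,
    grid_step_deg: float = 1.0,
    window: tuple[float, float] = (0.0, 1.0),
) -> tuple[float, np.ndarray, np.ndarray]:
    """Grid-search the target phase maximizing ERP correlation with a reference.

    Simulated ERPs share one fixed seed (cfg.rng_seed) across the whole
    -180..+180 degree grid; because the target phase enters every oscillation
    as an additive constant, the trial-mean ERP at phase phi is exactly
    Re{e^{i phi} C(t)} with C the across-trial mean phasor, so one synthesis
    serves the entire grid.  Ties break toward the smallest |phi|.

    Returns (phi_target_radians, grid_radians, correlations).
    """
    reference_erp = np.asarray(reference_erp, dtype=float)
    if reference_erp.size != sampling.n_samples:
        raise DataError("reference ERP must be on the epoch grid")
    C = complex_mean_response(cfg, w, sampling)
    sl = sampling.window_slice(*window)
    ref = reference_erp[sl]
    if np.ptp(ref) == 0:
        raise DataError("constant reference: correlation undefined")
    n = int(round(360.0 / grid_step_deg))
    grid_deg = -180.0 + grid_step_deg * np.arange(n + 1)
    grid = np.deg2rad(grid_deg)
    rs = np.array([_pearson(np.real(np.exp(1j * g) * C[sl]), ref) for g in grid])
    best = np.flatnonzero(rs >= rs.max() - 1e-12)
    phi = grid[best[np.argmin(np.abs(grid[best]))]]
    return float(phi), grid, rs


def estimate_tsynch_from_plv(
    summary: IMFResponseSummary,
    sampling: SamplingSpec,
    t_start: float = 0.0,
    plateau_fraction: float = 0.95,
    smoothing_s: float = 0.03,
) -> list[dict]:
    """Estimate per-IMF (period, t_synch, t_desynch) from the PLV time course.

    The PLV series is smoothed (Gaussian, ``smoothing_s`` seconds) so small
    noise cannot relocate the peak, then t_synch is the time of the
    post-``t_start`` maximum (first sample at the maximum).  The phase-locked
    interval is the contiguous run around the peak with
    PLV >= plateau_fraction * max; its bounds are returned as
    ``t_plateau_start`` and ``t_desynch``.  The PLV-peak time overestimates
    the onset of phase locking (the peak sits inside the locked interval), so
    square-root-law fits of synchronization latency should use the plateau
    start.  The period is 1 / baseline mean frequency.  A maximum at the
    usable epoch edge triggers a boundary warning.
    """
    from scipy.ndimage import gaussian_filter1d

    times = summary.times
    edge = summary.edge_samples
    lo = max(sampling.index_of(t_start), edge)
    hi = times.size - edge
    if hi - lo < 2:
        raise DataError("post-stimulus window is empty")
    out = []
    for i in range(summary.n_imfs):
        smoothed = summary.plv[i]
        if smoothing_s > 0:
            smoothed = gaussian_filter1d(
                smoothed, sigma=smoothing_s * sampling.rate, mode="nearest"
            )
        series = smoothed[lo:hi]
        j = int(np.argmax(series))
        peak = series[j]
        if j in (0, series.size - 1):
            warnings.warn(
                f"IMF {i + 1}: PLV maximum at the epoch boundary", stacklevel=2
            )
        level = plateau_fraction * peak
        end = j
        while end + 1 < series.size and series[end + 1] >= level:
            end += 1
        start = j
        while start - 1 >= 0 and series[start - 1] >= level:
            start -= 1
        out.append(
            {
                "imf": i + 1,
                "period": 1.0 / summary.baseline_freq_mean[i],
                "t_synch": float(times[lo + j]),
                "t_plateau_start": float(times[lo + start]),
                "t_desynch": float(times[lo + end]),
                "plv_max": float(peak),
            }
        )
    return out
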