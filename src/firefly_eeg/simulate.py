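"""Firefly model simulator: event-related EEG from frequency-dependent phase alignment.

The model represents the EEG as a sum of constant-amplitude sinusoids, one per
frequency on a dense grid.  A stimulus at time 0 causes each oscillation to
*slow down* from ``t_start`` until it reaches the phase of a per-channel target
oscillation at a frequency-dependent time ``t_synch``, stay phase-locked until
``t_desynch``, then speed up and return to its baseline phase by ``t_end``.
Synchronization and desynchronization latencies grow with the square root of
the oscillation period T:

    t_synch   = t_start + k_synch * sqrt(T)
    t_desynch = t_start + k_desynch * sqrt(T) + c_desynch
    t_end     = t_desynch + t_end_offset

Because every oscillation keeps constant amplitude, total power is identical
pre- and post-stimulus; the trial-average ERP, band-limited ERD/ERS and PSD
changes all emerge purely from the phase schedule.

Phase schedule of one oscillation (frequency f0, period T): let dphi be the
trial's random offset from the target oscillation at t_start, mapped to
dphi' in [0, 2pi) so that alignment is achieved by pure slowing.  With
u1(t), u2(t) the linear ramp progress of the synchronization and
desynchronization stages (0 before, 1 after),

    phi(t) = 2*pi*f0*(t - t_start) + phi_target + dphi' * (1 - u1(t) + u2(t))

which is continuous, equals the target phase on [t_synch, t_desynch) and
returns to the baseline phase (mod 2pi) at t_end.  Instantaneous frequency is
f0 except for a constant dip of dphi'/(2pi*(t_synch - t_start)) during
synchronization and a rise of dphi'/(2pi*(t_end - t_desynch)) during
desynchronization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .epochs import EpochSet, SamplingSpec
from .exceptions import ConfigurationError, DataError

logger = logging.getLogger(__name__)

__all__ = [
    "FireflyConfig",
    "SpectrumWeights",
    "PhaseTrajectory",
    "synch_time",
    "desynch_time",
    "make_trajectory",
    "phase_at",
    "inst_frequency_model",
    "synthetic_spectrum",
    "simulate_firefly",
    "simulate_evoked",
]

TWO_PI = 2.0 * math.pi


@dataclass
class FireflyConfig:
    """Parameters of the Firefly generative model.

    Times are seconds, frequencies Hz, phases radians.  ``k_synch`` and
    ``k_desynch`` (units s^1/2) are the square-root-law coefficients; they are
    calibration parameters of this package, chosen so that t_synch lands near
    the phase-locking-value peak latencies seen in IMF analyses of
    event-related EEG.  ``responding_fraction`` is the probability that an
    oscillator (one frequency, one trial) undergoes phase modulation;
    non-responding oscillators keep their baseline trajectory.  Responding is
    all-or-none per oscillator, so every sinusoid has constant amplitude and
    total power is conserved exactly.
    """

    f_min: float = 0.1
    f_max: float = 250.0
    f_step: float = 0.1
    t_start: float = 0.08
    k_synch: float = 0.5
    k_desynch: float = 0.9
    c_desynch: float = 0.05
    t_end_offset: float = 1.5
    phi_target: tuple[float, ...] = (0.0,)
    responding_fraction: float = 0.5
    n_trials: int = 100
    rng_seed: int = 0

    def __post_init__(self):
        if np.isscalar(self.phi_target):
            self.phi_target = (float(self.phi_target),)
        else:
            self.phi_target = tuple(float(p) for p in self.phi_target)
        if not (0 < self.f_min < self.f_max):
            raise ConfigurationError("need 0 < f_min < f_max")
        if not self.f_step > 0:
            raise ConfigurationError("f_step must be positive")
        if self.t_start < 0:
            raise ConfigurationError("t_start must be >= 0")
        if not (0.0 <= self.responding_fraction <= 1.0):
            raise ConfigurationError("responding_fraction must lie in [0, 1]")
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        if self.k_synch <= 0 or self.k_desynch <= 0:
            raise ConfigurationError("k_synch and k_desynch must be positive")
        # ordering t_start < t_synch < t_desynch < t_end on the whole grid:
        # t_synch - t_start = k_synch*sqrt(T) > 0 always; the desynch margin
        # (k_desynch - k_synch)*sqrt(T) + c_desynch must stay positive.
        for T in (1.0 / self.f_max, 1.0 / self.f_min):
            if desynch_time(T, self) <= synch_time(T, self):
                raise ConfigurationError(
                    "stage ordering violated: t_desynch <= t_synch at period "
                    f"{T} s; adjust k_synch/k_desynch/c_desynch"
                )
        if self.t_end_offset <= 0:
            raise ConfigurationError("t_end_offset must be positive")

    @property
    def n_channels(self) -> int:
        return len(self.phi_target)

    def frequency_grid(self, rate: float | None = None) -> np.ndarray:
        """Frequency grid f_min, f_min+f_step, ... <= f_max.

        If ``rate`` is given, frequencies at or above the Nyquist rate/2 are
        dropped with a warning (they cannot be represented on the grid).
        """
        n = int(math.floor((self.f_max - self.f_min) / self.f_step + 1e-9)) + 1
        freqs = self.f_min + self.f_step * np.arange(n)
        if rate is not None:
            nyq = rate / 2.0
            if freqs[-1] >= nyq:
                logger.warning(
                    "dropping %d grid frequencies at or above Nyquist (%g Hz)",
                    int(np.sum(freqs >= nyq)),
                    nyq,
                )
                freqs = freqs[freqs < nyq]
            if freqs.size == 0:
                raise ConfigurationError("frequency grid is empty after Nyquist exclusion")
        return freqs


@dataclass
class SpectrumWeights:
    """Amplitude weight a_f (microvolt scale, >= 0) at each grid frequency."""

    frequencies: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.frequencies.shape != self.weights.shape or self.frequencies.ndim != 1:
            raise ConfigurationError("frequencies and weights must be 1-D and equal length")
        if np.any(self.weights < 0):
            raise ConfigurationError("weights must be non-negative")
        if not np.any(self.weights > 0):
            raise ConfigurationError("at least one weight must be positive")

    def on_grid(self, freqs: np.ndarray) -> np.ndarray:
        """Return the weights restricted to ``freqs`` (a prefix-compatible subgrid)."""
        if freqs.size > self.frequencies.size or not np.allclose(
            self.frequencies[: freqs.size], freqs, atol=1e-9
        ):
            raise ConfigurationError("spectrum weights are not defined on the model grid")
        return self.weights[: freqs.size]


def synch_time(period: float, cfg: FireflyConfig):
    """Synchronization latency (offset from t_start): k_synch * sqrt(period)."""
    period = np.asarray(period, dtype=float)
    if np.any(period < 0):
        raise DataError("period must be >= 0")
    return cfg.k_synch * np.sqrt(period)


def desynch_time(period: float, cfg: FireflyConfig):
    """Desynchronization latency (offset from t_start): k_desynch*sqrt(T) + c_desynch."""
    period = np.asarray(period, dtype=float)
    if np.any(period < 0):
        raise DataError("period must be >= 0")
    return cfg.k_desynch * np.sqrt(period) + cfg.c_desynch


@dataclass(frozen=True)
class PhaseTrajectory:
    """Piecewise phase schedule of one oscillation relative to its target.

    ``delta_phi`` is the offset from the target oscillation at t_start, drawn
    in (-pi, pi]; internally it is mapped to ``delta_phi_prime`` in [0, 2pi)
    so that the synchronization ramp is non-positive (pure slowing).
    """

    f0: float
    delta_phi: float
    t_start: float
    t_synch: float
    t_desynch: float
    t_end: float
    phi_target: float = 0.0

    def __post_init__(self):
        if not (self.t_start < self.t_synch < self.t_desynch < self.t_end):
            raise ConfigurationError(
                "stage boundaries must satisfy t_start < t_synch < t_desynch < t_end"
            )

    @property
    def delta_phi_prime(self) -> float:
        """delta_phi mapped into [0, 2pi): the phase the ramp must remove."""
        return float(np.mod(self.delta_phi, TWO_PI))

    def phase(self, t):
        """Unwrapped phase phi(t); vectorized over t."""
        t = np.asarray(t, dtype=float)
        dpp = self.delta_phi_prime
        u1 = np.clip((t - self.t_start) / (self.t_synch - self.t_start), 0.0, 1.0)
        u2 = np.clip((t - self.t_desynch) / (self.t_end - self.t_desynch), 0.0, 1.0)
        return TWO_PI * self.f0 * (t - self.t_start) + self.phi_target + dpp * (
            1.0 - u1 + u2
        )

    def target_phase(self, t):
        t = np.asarray(t, dtype=float)
        return TWO_PI * self.f0 * (t - self.t_start) + self.phi_target

    def frequency(self, t):
        """Instantaneous model frequency (1/2pi) dphi/dt; one-sided at boundaries."""
        t = np.asarray(t, dtype=float)
        dpp = self.delta_phi_prime
        f = np.full_like(t, self.f0, dtype=float)
        synching = (t >= self.t_start) & (t < self.t_synch)
        desynching = (t >= self.t_desynch) & (t < self.t_end)
        f = f - synching * (dpp / (TWO_PI * (self.t_synch - self.t_start)))
        f = f + desynching * (dpp / (TWO_PI * (self.t_end - self.t_desynch)))
        return f if f.ndim else float(f)


def make_trajectory(
    f0: float, delta_phi: float, cfg: FireflyConfig, phi_target: float | None = None
) -> PhaseTrajectory:
    """Build the trajectory of one oscillation under ``cfg``'s timing laws."""
    T = 1.0 / f0
    t_synch = cfg.t_start + float(synch_time(T, cfg))
    t_desynch = cfg.t_start + float(desynch_time(T, cfg))
    return PhaseTrajectory(
        f0=f0,
        delta_phi=delta_phi,
        t_start=cfg.t_start,
        t_synch=t_synch,
        t_desynch=t_desynch,
        t_end=t_desynch + cfg.t_end_offset,
        phi_target=cfg.phi_target[0] if phi_target is None else phi_target,
    )


def phase_at(traj: PhaseTrajectory, t):
    """Phase (radians) of ``traj`` at time(s) t."""
    return traj.phase(t)


def inst_frequency_model(traj: PhaseTrajectory, t):
    """Closed-form instantaneous frequency (Hz) of ``traj`` at time(s) t."""
    return traj.frequency(t)


def synthetic_spectrum(
    alpha_peak_hz: float = 10.0,
    alpha_gain: float = 3.0,
    grid: np.ndarray | None = None,
    alpha_width_hz: float = 1.5,
    exponent: float = 0.5,
    cfg: FireflyConfig | None = None,
) -> SpectrumWeights:
    """Power-law amplitude weights with a Gaussian alpha bump, unit total power.

    a_f = f^(-exponent) + (alpha_gain - 1) * alpha_peak^(-exponent)
          * exp(-(f - alpha_peak)^2 / 2w^2),
    then scaled so that sum(a_f^2) = 1.  The default exponent 0.5 makes the
    *power* spectrum proportional to 1/f, the canonical shape of resting EEG
    away from the alpha peak; exponent = 1 gives amplitude proportional to
    1/f instead.  alpha_gain = 1 disables the bump; otherwise it is the
    amplitude ratio of the bump peak to the underlying power-law level there.
    """
    if grid is None:
        grid = (cfg or FireflyConfig()).frequency_grid()
    grid = np.asarray(grid, dtype=float)
    if alpha_gain < 1:
        raise ConfigurationError("alpha_gain must be >= 1")
    if not (grid[0] <= alpha_peak_hz <= grid[-1]):
        raise ConfigurationError("alpha_peak_hz must lie inside the frequency grid")
    a = grid ** (-exponent)
    a = a + (alpha_gain - 1.0) * alpha_peak_hz ** (-exponent) * np.exp(
        -0.5 * ((grid - alpha_peak_hz) / alpha_width_hz) ** 2
    )
    a = a / np.sqrt(np.sum(a**2))
    return SpectrumWeights(frequencies=grid, weights=a)


def _stage_arrays(freqs: np.ndarray, cfg: FireflyConfig):
    """Per-frequency absolute stage boundaries."""
    T = 1.0 / freqs
    t_synch = cfg.t_start + cfg.k_synch * np.sqrt(T)
    t_desynch = cfg.t_start + cfg.k_desynch * np.sqrt(T) + cfg.c_desynch
    t_end = t_desynch + cfg.t_end_offset
    return t_synch, t_desynch, t_end


def _draw_offsets(rng: np.random.Generator, n_trials: int, n_freq: int) -> np.ndarray:
    """Per-trial per-frequency phase offsets, uniform on (-pi, pi]."""
    return np.pi - rng.uniform(0.0, TWO_PI, size=(n_trials, n_freq))


def _draw_responding(
    rng: np.random.Generator, n_trials: int, n_freq: int, fraction: float
) -> np.ndarray:
    """Per-trial Bernoulli(fraction) mask of oscillators that phase-modulate."""
    if fraction >= 1.0:
        return np.ones((n_trials, n_freq))
    if fraction <= 0.0:
        return np.zeros((n_trials, n_freq))
    return (rng.uniform(size=(n_trials, n_freq)) < fraction).astype(float)


def _synthesize(
    cfg: FireflyConfig,
    w: SpectrumWeights,
    sampling: SamplingSpec,
    modulated: bool,
    rng_seed: int | None = None,
) -> np.ndarray:
    """Core synthesis: (n_trials, n_channels, n_samples) array of V(t).

    ``modulated=False`` disables the phase ramps (stationary random-phase
    background, as used by the evoked model); responding_fraction is then
    irrelevant since both trajectories coincide.
    """
    freqs = cfg.frequency_grid(sampling.rate)
    a = w.on_grid(freqs)
    t = sampling.times()
    rng = np.random.default_rng(cfg.rng_seed if rng_seed is None else rng_seed)
    dphi = _draw_offsets(rng, cfg.n_trials, freqs.size)  # shared across channels
    t_synch, t_desynch, t_end = _stage_arrays(freqs, cfg)

    # modulation only alters samples at t >= t_start
    i0 = sampling.index_of(cfg.t_start) if modulated else sampling.n_samples
    i0 = min(max(i0, 0), sampling.n_samples)
    ts = t[i0:]
    u1 = np.clip(
        (ts[None, :] - t_synch[:, None]) / (t_synch - cfg.t_start)[:, None] + 1.0,
        0.0,
        1.0,
    )
    u2 = np.clip(
        (ts[None, :] - t_desynch[:, None]) / (t_end - t_desynch)[:, None], 0.0, 1.0
    )
    ramp_shape = u2 - u1  # in [-1, 0]: -1 while phase-locked, 0 at baseline/t_end

    base_angle = TWO_PI * freqs[:, None] * (t[None, :] - cfg.t_start)
    r = cfg.responding_fraction if modulated else 0.0
    out = np.empty((cfg.n_trials, cfg.n_channels, sampling.n_samples))

    # responding oscillators: each frequency either follows the full phase
    # schedule or stays at baseline, drawn per trial; a split of one
    # oscillator's amplitude would let its two parts decohere and lose power
    # post-stimulus, violating the constant-amplitude assumption
    responding = _draw_responding(rng, cfg.n_trials, freqs.size, r)

    # preallocated work buffers: psi holds phases, trig their cosines; the
    # *_m pair covers the modulated t >= t_start slice
    psi = np.empty_like(base_angle)
    trig = np.empty_like(base_angle)
    n_mod = sampling.n_samples - i0
    psi_m = np.empty((freqs.size, n_mod)) if r > 0 else None
    trig_m = np.empty((freqs.size, n_mod)) if r > 0 else None

    for k in range(cfg.n_trials):
        dpp = np.mod(dphi[k], TWO_PI)
        a_mod = a * responding[k]
        a_stat = a - a_mod
        np.add(base_angle, dpp[:, None], out=psi)
        if r > 0:
            np.multiply(ramp_shape, dpp[:, None], out=psi_m)
            psi_m += psi[:, i0:]
        prev = 0.0
        for c, phi_c in enumerate(cfg.phi_target):
            if phi_c != prev:
                psi += phi_c - prev
                if r > 0:
                    psi_m += phi_c - prev
                prev = phi_c
            np.cos(psi, out=trig)
            if r > 0:
                vb = a_stat @ trig
                np.cos(psi_m, out=trig_m)
                out[k, c] = a @ trig  # baseline samples use every oscillator
                out[k, c, i0:] = vb[i0:] + a_mod @ trig_m
            else:
                out[k, c] = a @ trig
    return out


def _channel_labels(cfg: FireflyConfig, labels) -> list[str]:
    if labels is not None:
        if len(labels) != cfg.n_channels:
            raise ConfigurationError("channel_labels length must match phi_target")
        return list(labels)
    return [f"SIM{i + 1}" for i in range(cfg.n_channels)]


def simulate_firefly(
    cfg: FireflyConfig,
    w: SpectrumWeights,
    sampling: SamplingSpec,
    channel_labels=None,
    condition: str = "sim",
) -> EpochSet:
    """Simulate ``cfg.n_trials`` trials under the Firefly model.

    Each trial is V(t) = sum_f a_f cos(phi_f(t)) over the frequency grid with
    an independent uniform phase offset per frequency per trial (shared across
    channels); each oscillator phase-modulates with probability
    responding_fraction, otherwise it keeps its baseline trajectory.
    Bit-identical output for a fixed cfg.rng_seed.
    """
    data = _synthesize(cfg, w, sampling, modulated=True)
    return EpochSet(
        data=data,
        channel_labels=_channel_labels(cfg, channel_labels),
        condition_labels=[condition] * cfg.n_trials,
        sampling=sampling,
    )


def simulate_evoked(
    cfg: FireflyConfig,
    w: SpectrumWeights,
    erp_template: np.ndarray,
    sampling: SamplingSpec,
    channel_labels=None,
    condition: str = "evoked",
) -> EpochSet:
    """Simulate the competing evoked model: stationary background + fixed template.

    The background is generated exactly like :func:`simulate_firefly` but with
    all phase ramps disabled; the (channels x samples) template is added
    unscaled to every trial.
    """
    erp_template = np.atleast_2d(np.asarray(erp_template, dtype=float))
    if erp_template.shape != (cfg.n_channels, sampling.n_samples):
        raise DataError(
            f"template shape {erp_template.shape} does not match "
            f"(channels, samples) = ({cfg.n_channels}, {sampling.n_samples})"
        )
    data = _synthesize(cfg, w, sampling, modulated=False)
    data += erp_template[None, :, :]
    return EpochSet(
        data=data,
        channel_labels=_channel_labels(cfg, channel_labels),
        condition_labels=[condition] * cfg.n_trials,
        sampling=sampling,
    )


def complex_mean_response(
    cfg: FireflyConfig, w: SpectrumWeights, sampling: SamplingSpec
) -> np.ndarray:
    """Across-trial mean complex phasor C(t) with phi_target factored out.

    The trial-average ERP at any target phase phi is exactly
    Re{ e^{i*phi} * C(t) } because phi enters every cosine additively.  Used by
    the target-phase grid search so the whole grid shares one simulation seed.
    """
    freqs = cfg.frequency_grid(sampling.rate)
    a = w.on_grid(freqs)
    t = sampling.times()
    rng = np.random.default_rng(cfg.rng_seed)
    dphi = _draw_offsets(rng, cfg.n_trials, freqs.size)
    t_synch, t_desynch, t_end = _stage_arrays(freqs, cfg)

    i0 = min(max(sampling.index_of(cfg.t_start), 0), sampling.n_samples)
    ts = t[i0:]
    u1 = np.clip(
        (ts[None, :] - t_synch[:, None]) / (t_synch - cfg.t_start)[:, None] + 1.0,
        0.0,
        1.0,
    )
    u2 = np.clip(
        (ts[None, :] - t_desynch[:, None]) / (t_end - t_desynch)[:, None], 0.0, 1.0
    )
    ramp_shape = u2 - u1
    base_angle = TWO_PI * freqs[:, None] * (t[None, :] - cfg.t_start)
    r = cfg.responding_fraction
    responding = _draw_responding(rng, cfg.n_trials, freqs.size, r)

    psi = np.empty_like(base_angle)
    trig = np.empty_like(base_angle)
    n_mod = sampling.n_samples - i0
    psi_m = np.empty((freqs.size, n_mod)) if r > 0 else None
    trig_m = np.empty((freqs.size, n_mod)) if r > 0 else None

    acc = np.zeros(sampling.n_samples, dtype=complex)
    for k in range(cfg.n_trials):
        dpp = np.mod(dphi[k], TWO_PI)
        a_mod = a * responding[k]
        a_stat = a - a_mod
        np.add(base_angle, dpp[:, None], out=psi)
        z = np.empty(sampling.n_samples, dtype=complex)
        np.cos(psi, out=trig)
        z.real = a @ trig
        np.sin(psi, out=trig)
        z.imag = a @ trig
        if r > 0:
            zs = np.empty(sampling.n_samples, dtype=complex)
            np.cos(psi, out=trig)
            zs.real = a_stat @ trig
            np.sin(psi, out=trig)
            zs.imag = a_stat @ trig
            np.multiply(ramp_shape, dpp[:, None], out=psi_m)
            psi_m += psi[:, i0:]
            np.cos(psi_m, out=trig_m)
            zm_r = a_mod @ trig_m
            np.sin(psi_m, out=trig_m)
            zm_i = a_mod @ trig_m
            z[i0:] = zs[i0:] + zm_r + 1j * zm_i
        acc += z
    return acc / cfg.n_trials
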