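"""Firefly generative model: timing laws, phase trajectories, trial synthesis."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from firefly_eeg import (
    FireflyConfig,
    SamplingSpec,
    desynch_time,
    inst_frequency_model,
    make_trajectory,
    phase_at,
    simulate_evoked,
    simulate_firefly,
    synch_time,
    synthetic_spectrum,
    SpectrumWeights,
)
from firefly_eeg.exceptions import ConfigurationError, DataError
from firefly_eeg.simulate import TWO_PI, _draw_offsets

CFG = FireflyConfig()


class TestTimingLaws:
    def test_zero_period(self):
        assert synch_time(0.0, CFG) == 0.0

    def test_half_coefficient(self):
        cfg = dataclasses.replace(CFG, k_synch=0.5)
        assert synch_time(0.04, cfg) == pytest.approx(0.1)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(min_value=1e-4, max_value=100.0))
    def test_quadrupling_period_doubles_latency(self, period):
        assert synch_time(4 * period, CFG) == pytest.approx(2 * synch_time(period, CFG))

    def test_desynch_exceeds_synch_on_grid(self):
        for f in (CFG.f_min, 1.0, 10.0, CFG.f_max):
            T = 1.0 / f
            assert desynch_time(T, CFG) > synch_time(T, CFG) > 0

    def test_bad_ordering_rejected(self):
        with pytest.raises(ConfigurationError):
            FireflyConfig(k_synch=1.0, k_desynch=0.5, c_desynch=0.0)


class TestPhaseTrajectory:
    def test_zero_offset_is_unmodulated(self):
        traj = make_trajectory(10.0, 0.0, CFG)
        t = np.linspace(-1, 2, 1501)
        expected = TWO_PI * 10.0 * (t - CFG.t_start) + CFG.phi_target[0]
        assert np.allclose(phase_at(traj, t), expected, atol=1e-12)
        assert np.allclose(inst_frequency_model(traj, t), 10.0)

    @pytest.mark.parametrize("dphi", [-2.5, -0.1, 0.7, 3.0])
    def test_locked_to_target_phase(self, dphi):
        traj = make_trajectory(7.0, dphi, CFG)
        for t in (traj.t_synch, 0.5 * (traj.t_synch + traj.t_desynch)):
            diff = phase_at(traj, t) - traj.target_phase(t)
            assert np.cos(diff) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("dphi", [-3.0, 1.3])
    def test_returns_to_baseline_phase(self, dphi):
        traj = make_trajectory(5.0, dphi, CFG)
        t = traj.t_end + 0.4
        baseline = TWO_PI * 5.0 * (t - CFG.t_start) + CFG.phi_target[0] + dphi
        assert np.cos(phase_at(traj, t) - baseline) == pytest.approx(1.0, abs=1e-9)

    def test_sample_to_sample_continuity_bound(self):
        # max phase step at 500 Hz stays below the analytic slope bound:
        # 2*pi*f0*dt plus the steepest ramp increment
        dt = 1.0 / 500.0
        t = np.arange(-2.0, 2.0, dt)
        for f0 in (0.5, 10.0, 120.0):
            traj = make_trajectory(f0, 2.9, CFG)
            ramp = TWO_PI / (traj.t_synch - traj.t_start)  # dphi' <= 2*pi
            bound = TWO_PI * f0 * dt + ramp * dt + 1e-9
            steps = np.abs(np.diff(phase_at(traj, t)))
            assert steps.max() <= bound

    def test_synch_stage_frequency_closed_form(self):
        # f0=10 Hz, dphi'=pi, ramp 0.2 s -> 10 - pi/(2*pi*0.2) = 7.5 Hz
        traj = make_trajectory(
            10.0, np.pi, dataclasses.replace(CFG, k_synch=0.2 / np.sqrt(0.1))
        )
        assert traj.t_synch - traj.t_start == pytest.approx(0.2)
        mid = 0.5 * (traj.t_start + traj.t_synch)
        assert inst_frequency_model(traj, mid) == pytest.approx(7.5)

    def test_frequency_deviation_integrates_to_zero(self):
        traj = make_trajectory(4.0, 2.2, CFG)
        t = np.linspace(traj.t_start, traj.t_end, 200001)
        dev = inst_frequency_model(traj, t) - traj.f0
        # zero up to trapezoid discretization error at the stage boundaries
        assert np.trapezoid(dev, t) == pytest.approx(0.0, abs=1e-4)

    @pytest.mark.parametrize("dphi", [-3.1, -1.0, 0.5, 3.1])
    def test_slowing_only_during_synchronization(self, dphi):
        traj = make_trajectory(12.0, dphi, CFG)
        t = np.linspace(traj.t_start, traj.t_synch - 1e-6, 100)
        assert np.all(inst_frequency_model(traj, t) <= traj.f0 + 1e-12)

    def test_numerical_derivative_matches_model(self):
        traj = make_trajectory(9.0, 2.0, CFG)
        dt = 1e-4
        t = np.arange(-0.5, 2.5, dt)
        fd = np.diff(phase_at(traj, t)) / dt / TWO_PI
        tm = t[:-1] + dt / 2
        # exclude samples straddling a stage boundary
        keep = np.ones(tm.size, bool)
        for b in (traj.t_start, traj.t_synch, traj.t_desynch, traj.t_end):
            keep &= np.abs(tm - b) > 2 * dt
        assert np.abs(fd[keep] - inst_frequency_model(traj, tm[keep])).max() < 0.01


class TestSpectrum:
    def test_exponent_one_gives_reciprocal_weights(self, small_cfg):
        grid = small_cfg.frequency_grid()
        w = synthetic_spectrum(alpha_gain=1.0, grid=grid, exponent=1.0)
        ratio = w.weights * grid
        assert np.allclose(ratio, ratio[0])

    def test_default_is_one_over_f_power(self, small_cfg):
        grid = small_cfg.frequency_grid()
        w = synthetic_spectrum(alpha_gain=1.0, grid=grid)
        ratio = w.weights**2 * grid  # power * f constant
        assert np.allclose(ratio, ratio[0])

    def test_alpha_peak_is_argmax(self, small_cfg):
        grid = small_cfg.frequency_grid()
        w = synthetic_spectrum(alpha_peak_hz=10.0, alpha_gain=2.0, grid=grid)
        band = (grid >= 6) & (grid <= 14)
        assert grid[band][np.argmax(w.weights[band])] == pytest.approx(10.0)

    def test_unit_power_normalization(self, small_cfg):
        w = synthetic_spectrum(grid=small_cfg.frequency_grid())
        assert np.sum(w.weights**2) == pytest.approx(1.0)

    def test_nyquist_exclusion(self):
        cfg = FireflyConfig(f_min=1.0, f_max=250.0, f_step=1.0)
        freqs = cfg.frequency_grid(rate=500.0)
        assert freqs.max() < 250.0
        with pytest.raises(ConfigurationError):
            FireflyConfig(f_min=40.0, f_max=45.0, f_step=1.0).frequency_grid(rate=60.0)


class TestSimulateFirefly:
    def test_matches_trajectory_closed_form(self, short_sampling):
        # dual route: vectorized synthesis vs the scalar trajectory formula
        cfg = FireflyConfig(
            f_min=5.0, f_max=15.0, f_step=5.0, n_trials=3, rng_seed=4,
            responding_fraction=1.0, phi_target=(0.3,),
        )
        freqs = cfg.frequency_grid(short_sampling.rate)
        w = SpectrumWeights(freqs, np.array([0.5, 1.0, 0.25]))
        e = simulate_firefly(cfg, w, short_sampling)
        dphi = _draw_offsets(np.random.default_rng(cfg.rng_seed), 3, freqs.size)
        t = short_sampling.times()
        for k in range(3):
            expected = np.zeros_like(t)
            for j, f0 in enumerate(freqs):
                traj = make_trajectory(f0, dphi[k, j], cfg, phi_target=0.3)
                expected += w.weights[j] * np.cos(traj.phase(t))
            assert np.allclose(e.data[k, 0], expected, atol=1e-9)

    def test_single_tone_trials_are_pure_sinusoids(self, short_sampling):
        cfg = FireflyConfig(
            f_min=10.0, f_max=10.5, f_step=1.0, n_trials=4, rng_seed=0,
            responding_fraction=1.0,
        )
        w = SpectrumWeights(np.array([10.0]), np.array([1.0]))
        e = simulate_firefly(cfg, w, short_sampling)
        t = short_sampling.times()
        pre = t < cfg.t_start
        dphi = _draw_offsets(np.random.default_rng(0), 4, 1)
        for k in range(4):
            expected = np.cos(TWO_PI * 10.0 * (t[pre] - cfg.t_start) + dphi[k, 0])
            assert np.allclose(e.data[k, 0, pre], expected, atol=1e-9)

    def test_seeded_determinism(self, small_cfg, small_weights, short_sampling):
        a = simulate_firefly(small_cfg, small_weights, short_sampling)
        b = simulate_firefly(small_cfg, small_weights, short_sampling)
        assert np.array_equal(a.data, b.data)
        c = simulate_firefly(
            dataclasses.replace(small_cfg, rng_seed=99), small_weights, short_sampling
        )
        assert not np.array_equal(a.data, c.data)

    def test_no_phase_alignment_cancels_erp(self, short_sampling, small_weights):
        # responding_fraction 0: the trial average shrinks like 1/sqrt(n)
        rms = {}
        for n in (25, 100):
            cfg = FireflyConfig(
                f_min=2.0, f_max=30.0, f_step=0.5, n_trials=n, rng_seed=5,
                responding_fraction=0.0,
            )
            e = simulate_firefly(cfg, small_weights, short_sampling)
            rms[n] = e.data.mean(axis=0)[0].std()
            single = e.data[0, 0].std()
            assert rms[n] < 3 * single / np.sqrt(n)
        assert rms[100] < rms[25]

    def test_antiphase_target_inverts_signal(self, short_sampling, small_weights):
        cfg = dataclasses.replace(small_cfg_two_channels(), rng_seed=8)
        e = simulate_firefly(cfg, small_weights, short_sampling)
        assert np.allclose(e.data[:, 0, :], -e.data[:, 1, :], atol=1e-9)


def small_cfg_two_channels():
    return FireflyConfig(
        f_min=2.0, f_max=30.0, f_step=0.5, n_trials=5, phi_target=(0.0, np.pi)
    )


class TestSimulateEvoked:
    def test_zero_template_average_shrinks(self, short_sampling, small_weights, small_cfg):
        tpl = np.zeros((1, short_sampling.n_samples))
        e = simulate_evoked(small_cfg, small_weights, tpl, short_sampling)
        avg = e.data.mean(axis=0)[0]
        assert avg.std() < 0.5 * e.data[0, 0].std()

    def test_template_recovered_by_averaging(self, short_sampling, small_weights):
        t = short_sampling.times()
        tpl = (0.3 * np.exp(-((t - 0.3) ** 2) / 0.01) * np.cos(TWO_PI * 8 * t))[None]
        err = {}
        for n in (100, 400):
            cfg = FireflyConfig(
                f_min=2.0, f_max=30.0, f_step=0.5, n_trials=n, rng_seed=6
            )
            e = simulate_evoked(cfg, small_weights, tpl, short_sampling)
            err[n] = np.sqrt(np.mean((e.data.mean(axis=0)[0] - tpl[0]) ** 2))
        assert err[400] < err[100]  # law of large numbers
        assert err[400] == pytest.approx(err[100] / 2, rel=0.5)

    def test_template_length_mismatch(self, short_sampling, small_weights, small_cfg):
        with pytest.raises(DataError):
            simulate_evoked(
                small_cfg, small_weights, np.zeros((1, 10)), short_sampling
            )


def test_single_oscillator_power_conserved_exactly(sampling500):
    # every oscillator keeps constant amplitude, so for a single frequency the
    # pre- and post-stimulus mean square match in every trial (FM only);
    # the statistical whole-spectrum test runs on the full-scale simulation
    cfg = FireflyConfig(
        f_min=10.0, f_max=10.5, f_step=1.0, n_trials=10, rng_seed=3,
        responding_fraction=1.0,
    )
    w = SpectrumWeights(np.array([10.0]), np.array([1.0]))
    e = simulate_firefly(cfg, w, sampling500)
    t = sampling500.times()
    pre = (e.data[:, 0, t < 0] ** 2).mean(axis=1)
    post = (e.data[:, 0, t >= 0] ** 2).mean(axis=1)
    assert np.allclose(pre, 0.5, atol=0.01)
    assert np.allclose(post, 0.5, atol=0.01)
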