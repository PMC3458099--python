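"""Hilbert analytics: envelope, instantaneous frequency, PLV, IMF summaries."""

import numpy as np
import pytest

from firefly_eeg import (
    FireflyConfig,
    SamplingSpec,
    analytic,
    inst_frequency,
    make_trajectory,
    plv,
    response_correlations,
    summarize_imfs,
)
from firefly_eeg.exceptions import DataError

SAMP = SamplingSpec(rate=500.0, epoch_start=-2.0, epoch_end=2.0)
T = SAMP.times()


class TestAnalytic:
    def test_tone_amplitude_and_frequency(self):
        s = analytic(3.0 * np.cos(2 * np.pi * 11 * T), SAMP.rate)
        sl = s.interior
        assert np.abs(s.amplitude[sl] - 3.0).max() < 0.03  # within 1%
        assert np.abs(s.frequency[sl] - 11.0).max() < 0.11

    def test_slow_modulator_tracked(self):
        a_t = 1.0 + 0.3 * np.cos(2 * np.pi * 0.5 * T)
        s = analytic(a_t * np.cos(2 * np.pi * 15 * T), SAMP.rate)
        sl = s.interior
        assert np.abs(s.amplitude[sl] / a_t[sl] - 1.0).max() < 0.02

    def test_chirp_midpoint_frequency(self):
        # linear chirp 5 -> 15 Hz over [0, 1] s: instantaneous frequency at
        # t = 0.5 s is 10 Hz by the closed-form phase 2*pi*(5t + 5t^2)
        tt = np.linspace(0, 1, 501)
        x = np.cos(2 * np.pi * (5 * tt + 5 * tt**2))
        s = analytic(x, 500.0)
        mid = 250
        assert s.frequency[mid] == pytest.approx(10.0, abs=0.3)

    def test_constant_input_rejected(self):
        with pytest.raises(DataError):
            analytic(np.ones(500), 500.0)

    def test_unbiased_across_tone_frequencies(self):
        for f in (1.0, 10.0, 40.0, 100.0):
            s = analytic(np.cos(2 * np.pi * f * T), SAMP.rate)
            est = s.frequency[s.interior].mean()
            assert abs(est - f) / f < 0.005


class TestInstFrequency:
    def test_linear_phase_exact(self):
        phase = 2 * np.pi * 8.0 * T
        f = inst_frequency(phase, SAMP.rate)
        interior = slice(100, -100)
        assert np.abs(f[interior] / 8.0 - 1.0).max() < 1e-6

    def test_noise_suppression_vs_two_point_difference(self):
        rng = np.random.default_rng(0)
        phase = 2 * np.pi * 8.0 * T + rng.normal(0, 0.01, T.size)
        interior = slice(100, -100)
        smooth = inst_frequency(phase, SAMP.rate)[interior]
        naive = (np.diff(phase) * SAMP.rate / (2 * np.pi))[interior]
        err_smooth = np.sqrt(np.mean((smooth - 8.0) ** 2))
        err_naive = np.sqrt(np.mean((naive - 8.0) ** 2))
        assert err_naive > 5 * err_smooth

    def test_recovers_model_frequency_schedule(self):
        # phase from the generative trajectory; estimator must match the
        # closed-form instantaneous frequency away from stage boundaries
        cfg = FireflyConfig()
        traj = make_trajectory(10.0, 2.4, cfg)
        f_est = inst_frequency(traj.phase(T), SAMP.rate)
        f_true = traj.frequency(T)
        keep = np.ones(T.size, bool)
        for b in (traj.t_start, traj.t_synch, traj.t_desynch, traj.t_end):
            keep &= np.abs(T - b) > 0.08  # 4 kernel widths
        keep[:100] = keep[-100:] = False
        assert np.abs(f_est[keep] - f_true[keep]).max() < 0.2

    def test_too_short_series_rejected(self):
        with pytest.raises(DataError):
            inst_frequency(np.zeros(10), 500.0)


class TestPLV:
    def test_identical_phases(self):
        phases = np.tile(2 * np.pi * 5 * T, (7, 1))
        assert np.allclose(plv(phases), 1.0)

    def test_antiphase_pair_cancels(self):
        base = 2 * np.pi * 5 * T
        assert np.allclose(plv(np.vstack([base, base + np.pi])), 0.0, atol=1e-12)

    def test_uniform_phase_expectation(self):
        # E[PLV] for N uniform phases ~ sqrt(pi)/(2 sqrt(N)) = 0.0886 at N=100
        rng = np.random.default_rng(1)
        phases = rng.uniform(-np.pi, np.pi, size=(100, 1000))
        mean_plv = plv(phases).mean()
        assert mean_plv == pytest.approx(np.sqrt(np.pi) / 2 / 10, abs=0.01)

    def test_common_offset_invariance(self):
        rng = np.random.default_rng(2)
        phases = rng.uniform(-np.pi, np.pi, size=(20, 200))
        assert np.allclose(plv(phases), plv(phases + 1.234))

    def test_needs_two_trials(self):
        with pytest.raises(DataError):
            plv(np.zeros((1, 100)))


class TestSummaries:
    def _identical_trial_imfs(self):
        imf1 = np.cos(2 * np.pi * 12 * T) * (1 + 0.2 * np.cos(2 * np.pi * 0.5 * T))
        imf2 = 0.5 * np.cos(2 * np.pi * 3 * T)
        trial = np.stack([imf1, imf2])
        return np.tile(trial, (5, 1, 1))

    def test_identical_trials(self):
        imfs = self._identical_trial_imfs()
        s = summarize_imfs(imfs, SAMP)
        assert np.allclose(s.evoked, imfs[0])
        assert np.allclose(s.plv, 1.0)
        # induced equals the envelope of the evoked series for identical trials
        env = analytic(imfs[0, 0], SAMP.rate).amplitude
        assert np.allclose(s.induced[0], env)
        lo, hi = s.baseline_freq_ci[0]
        assert lo <= s.baseline_freq_mean[0] <= hi

    def test_baseline_band_brackets_true_frequency(self):
        # noisy stationary tones: the baseline CI brackets the true 10 Hz and
        # the trial-mean frequency series fluctuates around it
        rng = np.random.default_rng(3)
        imfs = np.empty((80, 1, T.size))
        for k in range(80):
            imfs[k, 0] = np.cos(
                2 * np.pi * 10 * T + rng.uniform(0, 2 * np.pi)
            ) + 0.05 * rng.standard_normal(T.size)
        s = summarize_imfs(imfs, SAMP)
        lo, hi = s.baseline_freq_ci[0]
        assert lo <= 10.0 <= hi or abs(s.baseline_freq_mean[0] - 10.0) < 0.05
        sl = slice(s.edge_samples, -s.edge_samples)
        assert abs(s.frequency[0, sl].mean() - 10.0) < 0.05

    def test_response_correlations_table(self):
        rng = np.random.default_rng(4)
        imfs = np.empty((6, 2, T.size))
        gate = 1 + 0.5 * np.exp(-((T - 0.3) ** 2) / 0.05)
        for k in range(6):
            imfs[k, 0] = gate * np.cos(2 * np.pi * 12 * T + rng.uniform(0, 1.0))
            imfs[k, 1] = np.cos(2 * np.pi * 3 * T + rng.uniform(0, 2 * np.pi))
        s = summarize_imfs(imfs, SAMP)
        table = response_correlations(s, SAMP)
        assert list(table.index) == [1, 2]
        assert set(table.columns) == {
            "induced_vs_evoked_env",
            "induced_vs_plv",
            "induced_vs_frequency",
            "evoked_env_vs_plv",
            "evoked_env_vs_frequency",
            "plv_vs_frequency",
        }
        assert (table.abs() <= 1.0 + 1e-12).all().all()
        # coherent amplitude gate drives both the induced and evoked envelopes
        assert table.loc[1, "induced_vs_evoked_env"] > 0.8

    def test_mismatched_input_rejected(self):
        with pytest.raises(DataError):
            summarize_imfs(np.zeros((5, 100)), SAMP)
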