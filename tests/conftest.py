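import numpy as np
import pytest

from firefly_eeg import EpochSet, FireflyConfig, SamplingSpec, synthetic_spectrum


@pytest.fixture(scope="session")
def sampling500():
    """The canonical epoch grid: 500 Hz, -2..+2 s around the stimulus."""
    return SamplingSpec(rate=500.0, epoch_start=-2.0, epoch_end=2.0)


@pytest.fixture(scope="session")
def short_sampling():
    """A cheaper grid for unit tests: 500 Hz, -0.5..+1.5 s."""
    return SamplingSpec(rate=500.0, epoch_start=-0.5, epoch_end=1.5)


@pytest.fixture
def small_cfg():
    """Reduced frequency grid so unit tests run in milliseconds."""
    return FireflyConfig(
        f_min=2.0, f_max=30.0, f_step=0.5, n_trials=20, rng_seed=11
    )


@pytest.fixture
def small_weights(small_cfg):
    return synthetic_spectrum(alpha_peak_hz=10.0, grid=small_cfg.frequency_grid())


def make_epochs(data, sampling, conditions=None, channels=None):
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[:, None, :]
    n_tr, n_ch, _ = data.shape
    return EpochSet(
        data=data,
        channel_labels=channels or [f"CH{i}" for i in range(n_ch)],
        condition_labels=conditions or ["a"] * n_tr,
        sampling=sampling,
    )
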