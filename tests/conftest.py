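import numpy as np
import pytest

from nircae.synth import default_dataset


@pytest.fixture(scope="session")
def clean_dataset():
    """80-sample noiseless, artifact-free synthetic dataset (linear span)."""
    return default_dataset(
        seed=3, scatter_sigma=0.0, baseline_intercept_sigma=0.0,
        baseline_slope_sigma=0.0, noise_std=0.0)


@pytest.fixture(scope="session")
def standard_dataset():
    """80-sample dataset at the default study conditions."""
    return default_dataset(seed=1)


@pytest.fixture(scope="session")
def small_dataset():
    """Fast 40-sample, 64-channel dataset for training-loop tests."""
    return default_dataset(seed=5, n_samples=40, n_channels=64)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
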