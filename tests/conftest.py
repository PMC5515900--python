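import numpy as np
import pytest

from rpca_eeg.synthetic import SyntheticConfig, generate_feature_dataset


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A cheap 3-day dataset for structural tests."""
    return SyntheticConfig(n_days=3, trials_per_day=6, n_features=30,
                           background_rank=2, sparse_support=5,
                           windows_per_trial=20, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_feature_dataset(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition dataset (5 days x 12 trials/class x 110 x 73)."""
    from rpca_eeg.synthetic import SyntheticConfig
    return generate_feature_dataset(SyntheticConfig(seed=3))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
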