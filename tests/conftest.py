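import numpy as np
import pytest

from lungpf import (
    FilterConfig,
    LikelihoodConfig,
    SyntheticConfig,
    fit_measurement_model,
    generate_training_pairs,
)


@pytest.fixture(scope="session")
def noise_free_cfg():
    return SyntheticConfig(feature_noise_sd=0.0, state_noise_sd=0.0)


@pytest.fixture(scope="session")
def fitted_model(noise_free_cfg):
    """Order-3 measurement model fit on 500 noise-free synthetic pairs."""
    pairs = generate_training_pairs(500, noise_free_cfg, np.random.default_rng(2))
    return fit_measurement_model(pairs, order=3)


@pytest.fixture(scope="session")
def lik_cfg():
    return LikelihoodConfig()


@pytest.fixture()
def filter_cfg():
    return FilterConfig(seed=123)
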