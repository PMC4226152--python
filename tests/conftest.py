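import numpy as np
import pytest

from stoppedsums.data import FixtureConfig, generate_fixture
from stoppedsums.distributions import (
    MagnitudeModelSpec,
    negbin_from_prob_scale,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture(scope="session")
def baseline_negbin():
    """The study's baseline count distribution: mean 10, variance 20."""
    return negbin_from_prob_scale(0.5, 10.0)


@pytest.fixture(scope="session")
def baseline_gamma():
    """The study's gamma magnitude baseline: mean 1000 ms, SD 500 ms."""
    return MagnitudeModelSpec(family="gamma", shape=4.0, scale=250.0)


@pytest.fixture(scope="session")
def baseline_lognormal():
    """The study's log-normal magnitude baseline: mean ~1000 ms, SD ~500 ms."""
    return MagnitudeModelSpec(family="lognormal", mu_log=6.81, sigma_log=0.447)


@pytest.fixture(scope="session")
def two_group_dataset():
    """Small two-level fixture with real frequency and magnitude effects."""
    cfg = FixtureConfig(
        J=120,
        alpha={"const": np.log(8.0), "condition": 0.15},
        beta={"const": 6.8, "condition": 0.10},
        mag_family="lognormal",
        mag_params={"sigma_log": 0.447},
        sigma_upsilon=0.15,
        seed=7,
    )
    return generate_fixture(cfg)
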