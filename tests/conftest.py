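import numpy as np
import pytest

from mobipred.harness import PopulationConfig, build_population


@pytest.fixture(scope="session")
def default_population():
    """The default synthetic study population: 50 users, 28 days, 5-8 anchors."""
    return build_population(PopulationConfig(seed=0))


@pytest.fixture(scope="session")
def noiseless_population():
    """Small noiseless 5-anchor population with complete records (ground truth
    exactly recoverable by the pipeline)."""
    cfg = PopulationConfig(
        n_users=8,
        n_anchors_min=5,
        n_anchors_max=5,
        gnss_noise_sigma=0.0,
        missing_fraction_target=0.0,
        seed=11,
    )
    return build_population(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
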