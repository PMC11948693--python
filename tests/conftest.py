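import numpy as np
import pytest

from molaudit.synthetic_fixtures import (
    generate_chemistry_free_library,
    generate_synthetic_library,
    make_fingerprint_featurizer,
)


@pytest.fixture(scope="session")
def small_library():
    """120 synthetic molecules with a planted sulfonamide rule, no noise."""
    return generate_synthetic_library(120, positive_rate=0.3, noise=0.0, seed=11)


@pytest.fixture(scope="session")
def noisy_library():
    """500 synthetic molecules with 5% label noise (the leaky-model testbed)."""
    return generate_synthetic_library(500, positive_rate=0.25, noise=0.05, seed=42)


@pytest.fixture(scope="session")
def chemfree_library():
    return generate_chemistry_free_library(300, dim=96, positive_rate=0.3, noise=0.05, seed=7)


@pytest.fixture(scope="session")
def ecfp4_featurizer():
    return make_fingerprint_featurizer("ECFP4")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
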