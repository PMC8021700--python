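import numpy as np
import pytest

from deepsc import synthetic as sy


@pytest.fixture(scope="session")
def small_atlas():
    """Continuous 8x8-grid atlas, 20 patterned genes, used across modules."""
    return sy.make_atlas(sy.SyntheticConfig(P=64, G_spatial=20, seed=1))


@pytest.fixture(scope="session")
def tiny_atlas():
    """A 16-position atlas for fast training tests."""
    return sy.make_atlas(sy.SyntheticConfig(P=16, G_spatial=12, seed=2))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
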