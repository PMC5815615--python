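import numpy as np
import pytest

from dendroscape.synth import make_trentino_like


@pytest.fixture(scope="session")
def trentino():
    """Default synthetic alpine dataset (151 sites), shared across tests."""
    return make_trentino_like(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_sites(rng):
    """20 scattered sites on a 50 km square with a smooth value surface."""
    xy = rng.uniform(0, 50_000, size=(20, 2))
    z = 5.0 + 1e-4 * xy[:, 0] + rng.normal(0, 0.1, 20)
    return xy, z
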