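import numpy as np
import pytest

from screenratio.synthetic import default_model, sample_actives, sample_decoys


@pytest.fixture(scope="session")
def small_model():
    """A compact generator model shared by read-only tests."""
    return default_model(k=4, d=64, seed=7)


@pytest.fixture(scope="session")
def small_pools(small_model):
    actives = sample_actives(small_model, 120)
    decoys = sample_decoys(small_model, 3000)
    return actives, decoys


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
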