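import numpy as np
import pytest

from guanosat import synth


@pytest.fixture(scope="session")
def library():
    return synth.default_library()


@pytest.fixture(scope="session")
def big_registry():
    """Large continental-parameter registry for distributional checks."""
    return synth.sample_colony_registry(
        {"continent": 100_000}, vhr_cv=0.0, seed=12345)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
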