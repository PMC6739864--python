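import numpy as np
import pytest

from untangling import make_population
from untangling.synth import fixture_population


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_pop():
    return make_population(40, "V1", np.random.default_rng(7))


@pytest.fixture(scope="session")
def mini_pipeline():
    """A seconds-scale end-to-end decoding fixture shared across tests."""
    return fixture_population(n_small=8, n_classes=3, rng=np.random.default_rng(11))
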