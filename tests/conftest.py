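import numpy as np
import pytest

from promforge import fixtures
from promforge.domestication import DEFAULT_CONFIG


@pytest.fixture(scope="session")
def reference_promoters():
    return fixtures.load_reference_promoters()


@pytest.fixture(scope="session")
def config():
    return DEFAULT_CONFIG


@pytest.fixture
def rng():
    return np.random.default_rng(0)
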