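import numpy as np
import pytest

from scsurvey.pairwise_align import default_scheme
from scsurvey.synthetic_data import background_frequencies


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def bg():
    return background_frequencies()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
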