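import numpy as np
import pytest

from ringdetect.bow import Dictionary
from ringdetect.dsift import GridSpec, SiftFeatures


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def spec():
    return GridSpec()


@pytest.fixture
def small_dictionary(rng):
    """10 well-spread random words in descriptor space."""
    words = rng.random((10, 128))
    return Dictionary(words=words, kmeans_seed=0)


def random_features(rng, n, d=128, locations_shape=None):
    desc = rng.random((n, d))
    locs = rng.integers(0, 64, size=(n, 2))
    return SiftFeatures(desc, locs.astype(np.intp))
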