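import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_rgb(rng):
    """A small random RGB raster in [0, 1]."""
    return rng.uniform(0.0, 1.0, size=(24, 32, 3))


@pytest.fixture
def random_gray(rng):
    return rng.uniform(0.0, 1.0, size=(24, 32))
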