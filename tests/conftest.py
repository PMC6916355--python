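import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def gaussian_data(rng):
    """A 40x8 raw Gaussian matrix with mild correlation."""
    A = rng.standard_normal((8, 8)) * 0.3 + np.eye(8)
    return rng.standard_normal((40, 8)) @ A
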