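import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240929)


def random_small_image(rng, max_side=10, integer=True):
    """A random image small enough for the brute-force Betti oracle."""
    n, m = rng.integers(1, max_side + 1, 2)
    if integer:
        return rng.integers(0, 6, (n, m)).astype(float)
    return rng.random((n, m))
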