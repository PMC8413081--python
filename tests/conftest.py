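import numpy as np
import pytest

from morphedge import GrayImage


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def random_image(rng):
    """One seeded random 8x8 8-bit image."""
    return GrayImage(rng.integers(0, 256, (8, 8), dtype=np.uint8))


def random_images(n, shape, seed=0):
    """A deterministic stream of random 8-bit images."""
    rng = np.random.default_rng(seed)
    return [GrayImage(rng.integers(0, 256, shape, dtype=np.uint8)) for _ in range(n)]
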