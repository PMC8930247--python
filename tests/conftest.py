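import numpy as np
import pytest

from knlmeans import GrayImage, PhantomSpec, SpeckleParams, add_speckle, make_phantom


@pytest.fixture(scope="session")
def phantom_clean() -> GrayImage:
    """128x128 three-class nested-ellipse phantom (the standard reference)."""
    return make_phantom(PhantomSpec(geometry_seed=0))


@pytest.fixture(scope="session")
def phantom_noisy(phantom_clean) -> GrayImage:
    """The standard phantom under sigma = 0.2 multiplicative speckle."""
    return add_speckle(phantom_clean, SpeckleParams(sigma=0.2, seed=1))


@pytest.fixture()
def random_image():
    """Factory for seeded uniform-random images."""

    def _make(shape=(12, 12), seed=0) -> GrayImage:
        rng = np.random.default_rng(seed)
        return GrayImage(rng.uniform(0.0, 1.0, size=shape))

    return _make
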