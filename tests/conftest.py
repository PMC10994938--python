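import numpy as np
import pytest

from mrisr.image import GrayImage
from mrisr.synthetic_data import PhantomRecipe, gen_anatomy_phantom, gen_label_set


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom128():
    """One deterministic brain-like phantom at 128x128."""
    return gen_anatomy_phantom(PhantomRecipe(seed=1, matrix=128))


@pytest.fixture(scope="session")
def label_set_small():
    """Twelve deterministic labels at 128x128, all three contrasts."""
    return gen_label_set(12, seed=9, matrix=128)


def random_image(rng, shape, spacing=(1.0, 1.0)) -> GrayImage:
    return GrayImage(rng.random(shape) * 100.0, spacing)
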