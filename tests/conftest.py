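import numpy as np
import pytest

from sonoderm.image import Image2D
from sonoderm.phantom import SkinPhantomSpec, make_skin_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def layered_phantom():
    """Default 128x128 layered skin phantom with its ground truth."""
    spec = SkinPhantomSpec()
    img, truth = make_skin_phantom(spec, seed=0)
    return spec, img, truth


@pytest.fixture(scope="session")
def clean_textureless():
    """Noise-free piecewise-constant phantom (texture off)."""
    spec = SkinPhantomSpec(texture_sigma=0.0)
    img, truth = make_skin_phantom(spec, seed=0)
    return spec, img, truth


@pytest.fixture
def random_image(rng):
    def make(h=16, w=16, lo=0.0, hi=255.0, spacing=None):
        return Image2D(rng.uniform(lo, hi, size=(h, w)), pixel_spacing=spacing)

    return make
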