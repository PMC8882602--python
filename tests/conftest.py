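import numpy as np
import pytest
from hypothesis import settings

from cutmirror.synthetic import PhantomSpec, make_phantom

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def disc_phantom():
    """Noise-free circular lesion with exact ground truth."""
    spec = PhantomSpec(height=96, width=96, center=(48.0, 48.0),
                       axes=(20.0, 20.0), boundary_roughness=0.0,
                       speckle_sigma=0.0, seed=3)
    return make_phantom(spec)


@pytest.fixture(scope="session")
def ellipse_phantom():
    """Rotated 2:1 ellipse lesion, speckled."""
    spec = PhantomSpec(height=128, width=128, center=(60.0, 70.0),
                       axes=(28.0, 14.0), rotation=np.deg2rad(30),
                       boundary_roughness=0.0, speckle_sigma=0.2, seed=4)
    return make_phantom(spec)


def random_mask(rng, shape):
    """A random blobby mask with at least one foreground pixel."""
    from scipy import ndimage

    m = ndimage.binary_dilation(rng.random(shape) < 0.05, iterations=2)
    if not m.any():
        m[shape[0] // 2, shape[1] // 2] = True
    return m
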