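import numpy as np
import pytest

from canalseg.phantom import PhantomSpec, generate_tooth
from canalseg.volume import BinaryMask, Volume3D


@pytest.fixture(scope="session")
def sr_phantom():
    """One straight single-rooted phantom with an analytic ground truth."""
    spec = PhantomSpec(seed=3)
    uct, tooth_gt, canal_gt = generate_tooth(spec)
    return spec, uct, tooth_gt, canal_gt


@pytest.fixture(scope="session")
def curved_phantom():
    """A curved-root phantom (asymmetric; suitable for pose recovery)."""
    spec = PhantomSpec(canal_curvature=0.3, seed=5)
    return spec, *generate_tooth(spec)


def make_mask(data, voxel=1.0, origin=(0.0, 0.0, 0.0)):
    return BinaryMask(np.asarray(data, dtype=np.uint8), voxel, origin)


def make_volume(data, voxel=1.0, origin=(0.0, 0.0, 0.0)):
    return Volume3D(np.asarray(data, dtype=np.float32), voxel, origin)


@pytest.fixture
def cube_mask():
    """Solid 3x3x3 cube centered in an 9x9x9 grid at unit voxels."""
    data = np.zeros((9, 9, 9), np.uint8)
    data[3:6, 3:6, 3:6] = 1
    return make_mask(data)
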