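import numpy as np
import pytest

from grain3d.pipeline import extract_grain_traits
from grain3d.synthetic import GrainParams, make_grain


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def default_grain():
    """One grooved grain at generator defaults, with its ground truth."""
    return make_grain(GrainParams(seed=1), gt_resolution=240)


@pytest.fixture(scope="session")
def default_grain_traits(default_grain):
    cloud, gt = default_grain
    record, grain = extract_grain_traits(cloud)
    return record, grain, gt


@pytest.fixture(scope="session")
def smooth_grain():
    """A grooveless (convex) grain: pure cheeked ellipsoid."""
    return make_grain(GrainParams(groove_depth=None, seed=2), gt_resolution=240)


def sphere_cloud(n=2000, radius=3.0, seed=0):
    g = np.random.default_rng(seed)
    u = g.standard_normal((n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    return u * radius


def random_rotation(seed=0):
    g = np.random.default_rng(seed)
    q, _ = np.linalg.qr(g.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
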