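import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from radius3d.frame import AxisLine, Point3
from radius3d.indices import ReferenceTriad


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def canonical_axis():
    return AxisLine(anchor=np.zeros(3), direction=np.array([0.0, 1.0, 0.0]))


@pytest.fixture
def sample_triad():
    # styloid radial-distal, sigmoid edges ulnar-proximal: plausible geometry
    return ReferenceTriad(
        Point3(-2.0, -6.0, 13.0),
        Point3(-5.0, 7.0, -15.0),
        Point3(4.9, 6.0, -12.0),
    )


def random_rotation(rng) -> np.ndarray:
    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()


def random_triad(rng, scale=15.0) -> ReferenceTriad:
    while True:
        m = rng.uniform(-scale, scale, size=(3, 3))
        tri = ReferenceTriad.from_matrix(m)
        if not (tri.is_degenerate or tri.is_collinear):
            return tri
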