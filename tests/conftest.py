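import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from lapnav.geometry import Pose, RigidTransform


def random_transform(rng: np.random.Generator, scale: float = 100.0) -> RigidTransform:
    """Uniformly random rotation plus a translation of the given scale."""
    R = Rotation.random(random_state=rng).as_matrix()
    return RigidTransform(R, rng.uniform(-scale, scale, 3))


def make_pivot_poses(
    tip: np.ndarray,
    pivot: np.ndarray,
    n: int,
    rng: np.random.Generator,
    sigma: float = 0.0,
) -> list[Pose]:
    """Poses of a tool pivoting about a fixed point, optional position noise."""
    poses = []
    for i in range(n):
        R = Rotation.random(random_state=rng).as_matrix()
        t = pivot - R @ tip + rng.normal(0.0, sigma, 3)
        poses.append(Pose(i * 0.02, "pointer", RigidTransform(R, t)))
    return poses


@pytest.fixture
def rng():
    return np.random.default_rng(42)
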