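import numpy as np
import pytest

from phytopoint.core import PointCloud


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_cube_cloud():
    import itertools

    return PointCloud(np.array(list(itertools.product([0.0, 1.0], repeat=3))))


@pytest.fixture
def planar_grid():
    """Regular 1-mm grid over 50×50 mm at z = 0 (2601 points)."""
    x, y = np.meshgrid(np.arange(51.0), np.arange(51.0))
    return PointCloud(np.column_stack([x.ravel(), y.ravel(),
                                      np.zeros(x.size)]))


@pytest.fixture
def cylinder_cloud():
    """Open cylinder r=10 mm, height 60 mm, sampled on a ~0.7 mm grid."""
    r = 10.0
    theta = np.linspace(0, 2 * np.pi, 90, endpoint=False)
    z = np.linspace(0.0, 60.0, 86)
    T, Z = np.meshgrid(theta, z)
    pts = np.column_stack([r * np.cos(T).ravel(), r * np.sin(T).ravel(),
                           Z.ravel()])
    return PointCloud(pts), r


def grid_mesh_faces(nx, ny):
    idx = np.arange(nx * ny).reshape(nx, ny)
    f1 = np.column_stack([idx[:-1, :-1].ravel(), idx[1:, :-1].ravel(),
                          idx[1:, 1:].ravel()])
    f2 = np.column_stack([idx[:-1, :-1].ravel(), idx[1:, 1:].ravel(),
                          idx[:-1, 1:].ravel()])
    return np.vstack([f1, f2])
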