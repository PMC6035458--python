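import numpy as np
import pytest

from rsdmtox.geometry import ContourStack, Slice, contours_to_mesh


def circle_stack(radius=10.0, n_points=64, n_slices=5, spacing=2.0,
                 z0=0.0):
    theta = np.arange(n_points) / n_points * 2 * np.pi
    pts = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
    slices = [Slice(z0 + i * spacing, pts.copy()) for i in range(n_slices)]
    return ContourStack(slices, spacing)


def square_stack(side=1.0, n_slices=3, spacing=1.0):
    pts = np.array([[0, 0], [side, 0], [side, side], [0, side]], dtype=float)
    slices = [Slice(i * spacing, pts.copy()) for i in range(n_slices)]
    return ContourStack(slices, spacing)


def box_mesh(lo, hi):
    """Closed axis-aligned box as 12 triangles with outward normals."""
    from rsdmtox.geometry import SurfaceMesh
    x0, y0, z0 = lo
    x1, y1, z1 = hi
    v = np.array([
        [x0, y0, z0], [x1, y0, z0], [x1, y1, z0], [x0, y1, z0],
        [x0, y0, z1], [x1, y0, z1], [x1, y1, z1], [x0, y1, z1],
    ], dtype=float)
    f = np.array([
        [0, 2, 1], [0, 3, 2],  # bottom
        [4, 5, 6], [4, 6, 7],  # top
        [0, 1, 5], [0, 5, 4],  # y0
        [2, 3, 7], [2, 7, 6],  # y1
        [1, 2, 6], [1, 6, 5],  # x1
        [3, 0, 4], [3, 4, 7],  # x0
    ])
    return SurfaceMesh(v, f)


@pytest.fixture
def cylinder():
    stack = circle_stack(radius=10.0, n_points=64, n_slices=11, spacing=2.0)
    return stack, contours_to_mesh(stack, samples_per_contour=None)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
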