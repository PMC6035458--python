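"""Core geometry types: slice contours, triangulated tube surfaces, dose grids.

Coordinate conventions: right-handed, +z = superior, units mm everywhere.
Contours are planar (axial) closed polygons, normalized at construction to
counter-clockwise orientation viewed from superior, with the starting vertex
rotated to the posterior-most point (minimum y) so that meshing and
flattening cuts are deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from shapely.geometry import LinearRing

log = logging.getLogger(__name__)

LENGTH_WARN_MM = (60.0, 90.0)


class ContourError(ValueError):
    """Raised for malformed contour input."""


def _signed_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _normalize_polygon(points: np.ndarray) -> np.ndarray:
    """CCW-from-superior orientation, start rotated to posterior-most point."""
    if _signed_area(points) < 0:
        points = points[::-1]
    # posterior-most = min y, ties broken by min x
    start = np.lexsort((points[:, 0], points[:, 1]))[0]
    return np.roll(points, -start, axis=0)


@dataclass(frozen=True)
class Slice:
    z: float
    points: np.ndarray  # (n, 2) closed polygon, last->first edge implied


@dataclass
class ContourStack:
    """Ordered closed planar rectum contours, one per axial slice."""

    slices: list[Slice]
    slice_spacing: float

    def __post_init__(self) -> None:
        if not self.slices:
            raise ContourError("empty contour stack")
        zs = [s.z for s in self.slices]
        if not all(b > a for a, b in zip(zs, zs[1:])):
            bad = next(i for i, (a, b) in enumerate(zip(zs, zs[1:])) if b <= a)
            raise ContourError(f"z not strictly increasing at slice {bad + 1}")
        norm = []
        for i, s in enumerate(self.slices):
            pts = np.asarray(s.points, dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
                raise ContourError(f"slice {i}: polygon needs >=3 2D points")
            if not LinearRing(pts).is_simple:
                raise ContourError(f"slice {i}: self-intersecting polygon")
            if abs(_signed_area(pts)) < 1e-9:
                raise ContourError(f"slice {i}: degenerate (zero-area) polygon")
            norm.append(Slice(float(s.z), _normalize_polygon(pts)))
        self.slices = norm
        length = zs[-1] - zs[0]
        if not (LENGTH_WARN_MM[0] <= length <= LENGTH_WARN_MM[1]):
            log.warning("rectum length %.1f mm outside typical %s range",
                        length, LENGTH_WARN_MM)

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def length(self) -> float:
        return self.slices[-1].z - self.slices[0].z

    def perimeters(self) -> np.ndarray:
        """Closed perimeter of each slice contour, mm."""
        out = []
        for s in self.slices:
            d = np.diff(np.vstack([s.points, s.points[:1]]), axis=0)
            out.append(float(np.linalg.norm(d, axis=1).sum()))
        return np.asarray(out)

    def allclose(self, other: "ContourStack", atol: float = 1e-6) -> bool:
        if self.n_slices != other.n_slices:
            return False
        if abs(self.slice_spacing - other.slice_spacing) > atol:
            return False
        for a, b in zip(self.slices, other.slices):
            if abs(a.z - b.z) > atol or a.points.shape != b.points.shape:
                return False
            if not np.allclose(a.points, b.points, atol=atol):
                return False
        return True


@dataclass
class SurfaceMesh:
    """Triangulated tube surface with optional per-vertex dose.

    Vertices produced by :func:`contours_to_mesh` are stored slice-major:
    ring ``i`` occupies a contiguous index block in contour order starting at
    the posterior cut; ``vertex_slice`` records the ring index of each vertex.
    """

    vertices: np.ndarray  # (N, 3)
    faces: np.ndarray  # (M, 3) int
    vertex_dose: np.ndarray | None = None
    vertex_slice: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face references missing vertex")
        if self.vertex_dose is not None:
            self.vertex_dose = np.asarray(self.vertex_dose, dtype=float)
            if len(self.vertex_dose) != len(self.vertices):
                raise ValueError("vertex_dose length mismatch")
        if self.vertex_slice is not None:
            self.vertex_slice = np.asarray(self.vertex_slice, dtype=int)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def triangle_areas(self) -> np.ndarray:
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def boundary_loops(self) -> list[np.ndarray]:
        """Vertex index loops of boundary edges (edges on exactly one face)."""
        edges: dict[tuple[int, int], int] = {}
        for f in self.faces:
            for i in range(3):
                e = (int(f[i]), int(f[(i + 1) % 3]))
                key = (min(e), max(e))
                edges[key] = edges.get(key, 0) + 1
        boundary = [e for e, n in edges.items() if n == 1]
        adj: dict[int, list[int]] = {}
        for a, b in boundary:
            adj.setdefault(a, []).append(b)
            adj.setdefault(b, []).append(a)
        loops, seen = [], set()
        for start in adj:
            if start in seen:
                continue
            loop, cur, prev = [start], start, -1
            seen.add(start)
            while True:
                nxt = [v for v in adj[cur] if v != prev]
                if not nxt or nxt[0] == start:
                    break
                prev, cur = cur, nxt[0]
                loop.append(cur)
                seen.add(cur)
            loops.append(np.asarray(loop))
        return loops

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(
            self.vertices.copy(), self.faces.copy(),
            None if self.vertex_dose is None else self.vertex_dose.copy(),
            None if self.vertex_slice is None else self.vertex_slice.copy(),
        )


@dataclass
class DoseGrid:
    """Axis-aligned 3D dose grid; origin is the center of voxel (0,0,0)."""

    values: np.ndarray  # (nx, ny, nz) Gy
    origin: np.ndarray  # (3,) mm
    spacing: np.ndarray  # (3,) mm
    is_eqd2: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("negative dose in grid")
        if np.any(self.spacing <= 0):
            raise ValueError("non-positive grid spacing")

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[i] + self.spacing[i] * np.arange(self.values.shape[i])
            for i in range(3)
        )


@dataclass
class FractionRecord:
    """One treatment fraction: geometry plus its planned dose."""

    phase: str  # "EBRT" | "BT"
    fraction_index: int
    geometry: SurfaceMesh
    dose: np.ndarray | DoseGrid | None  # per-vertex Gy or grid
    dose_per_fraction: float
    n_fractions: int = 1

    def __post_init__(self) -> None:
        if self.phase not in ("EBRT", "BT"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.dose_per_fraction <= 0:
            raise ValueError("dose_per_fraction must be > 0")
        if self.phase == "BT" and self.dose is None:
            raise ValueError("BT fraction requires a dose")

    def vertex_dose(self) -> np.ndarray:
        if isinstance(self.dose, DoseGrid):
            return sample_dose(self.geometry, self.dose)
        if self.dose is None:
            raise ValueError("fraction has no dose")
        return np.asarray(self.dose, dtype=float)


# ---------------------------------------------------------------------------
# operations


def resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polygon to n points, equally spaced by arc length,
    keeping the original starting vertex at index 0."""
    closed = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    targets = np.arange(n) * total / n
    out = np.empty((n, points.shape[1]))
    for d in range(points.shape[1]):
        out[:, d] = np.interp(targets, s, closed[:, d])
    return out


def contours_to_mesh(stack: ContourStack,
                     samples_per_contour: int | None = 128) -> SurfaceMesh:
    """Stitch adjacent slice contours into an open tube mesh.

    Each contour is arc-length resampled to ``samples_per_contour`` points
    (pass ``None`` to keep original vertices; then all slices must share a
    point count). Corresponding points on adjacent rings are laddered into
    triangle pairs. Returns a mesh with two boundary loops and per-vertex
    slice indices.
    """
    if stack.n_slices < 2:
        raise ContourError("need at least 2 slices to build a tube")
    rings = []
    for s in stack.slices:
        pts = s.points
        if samples_per_contour is not None:
            pts = resample_closed(pts, samples_per_contour)
        rings.append(np.column_stack([pts, np.full(len(pts), s.z)]))
    counts = {len(r) for r in rings}
    if len(counts) != 1:
        raise ContourError(
            "contours have unequal point counts; pass samples_per_contour")
    n = counts.pop()
    vertices = np.vstack(rings)
    vslice = np.repeat(np.arange(stack.n_slices), n)
    faces = []
    for i in range(stack.n_slices - 1):
        lo, hi = i * n, (i + 1) * n
        for j in range(n):
            k = (j + 1) % n
            faces.append([lo + j, lo + k, hi + k])
            faces.append([lo + j, hi + k, hi + j])
    mesh = SurfaceMesh(vertices, np.asarray(faces), vertex_slice=vslice)
    if surface_area(mesh) <= 0:
        raise ContourError("degenerate mesh (zero surface area)")
    return mesh


def surface_area(mesh: SurfaceMesh) -> float:
    """Total triangle area, mm^2."""
    return float(mesh.triangle_areas().sum())


def vertex_areas(mesh: SurfaceMesh) -> np.ndarray:
    """Per-vertex area: one third of each incident triangle's area.

    Partitions the surface: the sum equals :func:`surface_area`.
    """
    tri = mesh.triangle_areas() / 3.0
    out = np.zeros(mesh.n_vertices)
    for c in range(3):
        np.add.at(out, mesh.faces[:, c], tri)
    return out


def sample_dose(mesh: SurfaceMesh, grid: DoseGrid) -> np.ndarray:
    """Trilinearly interpolate grid dose at mesh vertices.

    Out-of-bounds vertices are clamped to the grid boundary with a warning.
    """
    axes = grid.axes()
    pts = mesh.vertices.copy()
    clipped = False
    for i, ax in enumerate(axes):
        lo, hi = ax[0], ax[-1]
        if np.any(pts[:, i] < lo) or np.any(pts[:, i] > hi):
            clipped = True
        np.clip(pts[:, i], lo, hi, out=pts[:, i])
    if clipped:
        warnings.warn("vertices outside dose grid were clamped to its bounds",
                      stacklevel=2)
    interp = RegularGridInterpolator(axes, grid.values)
    return interp(pts)
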