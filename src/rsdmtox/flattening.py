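"""Unroll cumulative 3D surface dose into the 2D rectum surface dose map.

Each inter-slice band is represented by its midpoint ring (the average of
the two adjacent slice rings), cut at the posterior-most point and unrolled
counter-clockwise (viewed from superior) by arc length into one map row, so
physical length is preserved in both the superior-inferior direction (rows x
row spacing = tube length exactly) and the circumferential direction (column
spacing, default 1 mm). Rows are left-aligned at the cut; columns beyond a row's
circumference are masked out, giving a ragged right edge. Map width is
patient specific (max circumference) — maps are never resampled across
patients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .accumulation import CumulativeSurfaceDose
from .geometry import ContourStack


@dataclass
class RSDM:
    """Flattened rectum surface dose map with physical spacing."""

    dose: np.ndarray  # (rows, cols) Gy; rows ordered inferior -> superior
    mask: np.ndarray  # (rows, cols) bool validity
    row_spacing: float  # mm, superior-inferior
    col_spacing: float  # mm, circumferential
    row_circumference: np.ndarray  # (rows,) mm
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.row_circumference = np.asarray(self.row_circumference,
                                            dtype=float)
        if self.dose.shape != self.mask.shape:
            raise ValueError("dose/mask shape mismatch")
        if len(self.row_circumference) != self.dose.shape[0]:
            raise ValueError("row_circumference length mismatch")
        if not np.all(np.isfinite(self.dose[self.mask])):
            raise ValueError("non-finite dose inside mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dose.shape

    def valid_values(self) -> np.ndarray:
        return self.dose[self.mask]


def flatten(cum: CumulativeSurfaceDose, contours: ContourStack,
            col_spacing: float = 1.0) -> RSDM:
    """Flatten a cumulative surface dose into an :class:`RSDM`.

    The reference mesh must have been built with :func:`contours_to_mesh`
    from ``contours`` (slice-major vertex order, rings starting at the
    posterior cut), so each ring unrolls directly into one row.
    """
    mesh = cum.reference
    if mesh.vertex_slice is None:
        raise ValueError("reference mesh lacks vertex slice indices")
    n_slices = contours.n_slices
    if mesh.vertex_slice.max() + 1 != n_slices:
        raise ValueError("mesh/contour slice count mismatch")
    rings, doses = [], []
    for i in range(n_slices):
        idx = np.nonzero(mesh.vertex_slice == i)[0]
        if idx.size < 3:
            raise ValueError(f"slice {i}: missing ring vertices")
        rings.append(mesh.vertices[idx])
        doses.append(cum.values[idx])
    # one row per inter-slice band, sampled at the band midpoint ring, so
    # n_rows * row_spacing equals the physical tube length exactly
    n_rows = n_slices - 1
    ring_s, ring_d, circumferences = [], [], []
    for i in range(n_rows):
        if len(rings[i]) != len(rings[i + 1]):
            raise ValueError("adjacent rings have unequal point counts")
        pts = 0.5 * (rings[i] + rings[i + 1])
        dose = 0.5 * (doses[i] + doses[i + 1])
        closed = np.vstack([pts, pts[:1]])
        seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        ring_s.append(s)
        ring_d.append(np.concatenate([dose, dose[:1]]))  # wrap for interp
        circumferences.append(s[-1])
    circumferences = np.asarray(circumferences)
    n_cols_per_row = np.maximum(
        np.round(circumferences / col_spacing).astype(int), 1)
    width = int(n_cols_per_row.max())
    dose_map = np.full((n_rows, width), np.nan)
    mask = np.zeros((n_rows, width), dtype=bool)
    for i in range(n_rows):
        n = n_cols_per_row[i]
        targets = np.arange(n) * col_spacing
        dose_map[i, :n] = np.interp(targets, ring_s[i], ring_d[i])
        mask[i, :n] = True
    return RSDM(dose_map, mask, row_spacing=contours.slice_spacing,
                col_spacing=col_spacing, row_circumference=circumferences)


def rsdm_area(m: RSDM) -> float:
    """Physical area represented by valid map pixels, mm^2."""
    return float(m.mask.sum()) * m.row_spacing * m.col_spacing


# ---------------------------------------------------------------------------
# serialization: dose CSV (NaN outside mask) + JSON header


def write_rsdm(m: RSDM, base: str | Path) -> None:
    base = Path(base)
    header = {
        "row_spacing": m.row_spacing,
        "col_spacing": m.col_spacing,
        "row_circumference": m.row_circumference.tolist(),
        "patient_id": m.patient_id,
    }
    base.with_suffix(".json").write_text(json.dumps(header, indent=1))
    out = np.where(m.mask, m.dose, np.nan)
    np.savetxt(base.with_suffix(".csv"), out, fmt="%.9g", delimiter=",")


def read_rsdm(base: str | Path) -> RSDM:
    base = Path(base)
    header = json.loads(base.with_suffix(".json").read_text())
    dose = np.loadtxt(base.with_suffix(".csv"), delimiter=",", ndmin=2)
    mask = np.isfinite(dose)
    return RSDM(np.where(mask, dose, 0.0), mask,
                row_spacing=header["row_spacing"],
                col_spacing=header["col_spacing"],
                row_circumference=np.asarray(header["row_circumference"]),
                patient_id=header.get("patient_id", ""))
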