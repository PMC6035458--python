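"""Dose-volume parameters Dx-cc from per-vertex surface dose.

Dx is the minimum dose within the most exposed x cm^3. The surface carries
no intrinsic volume; each vertex's area patch is extruded by a nominal wall
thickness (default 3 mm) to convert area to volume. The x grid is 0.1 cm^3
plus 0.5..10 cm^3 in 0.5 cm^3 steps (21 values).
"""

from __future__ import annotations

import logging

import numpy as np

log = logging.getLogger(__name__)

DVP_VOLUMES_CC: tuple[float, ...] = (0.1,) + tuple(
    np.round(np.arange(0.5, 10.0 + 1e-9, 0.5), 1))

DEFAULT_WALL_THICKNESS_MM = 3.0


def dvp_names() -> list[str]:
    return [f"D{x:g}cc" for x in DVP_VOLUMES_CC]


def compute_dvps(
    vertex_dose: np.ndarray,
    vertex_areas: np.ndarray,
    wall_thickness_mm: float = DEFAULT_WALL_THICKNESS_MM,
    volumes_cc: tuple[float, ...] = DVP_VOLUMES_CC,
) -> dict[str, float]:
    """Dx-cc values keyed by name, Gy.

    Vertices are sorted by dose descending; cumulative volume is
    area * wall thickness; Dx is the dose at which the cumulative volume
    first reaches x cm^3. If the whole structure is smaller than x cm^3 the
    minimum dose is returned (logged).
    """
    dose = np.asarray(vertex_dose, dtype=float)
    areas = np.asarray(vertex_areas, dtype=float)
    if dose.size == 0:
        raise ValueError("empty mesh")
    if dose.shape != areas.shape:
        raise ValueError("dose/area length mismatch")
    if wall_thickness_mm <= 0:
        raise ValueError("wall thickness must be > 0")
    order = np.argsort(-dose, kind="stable")
    sorted_dose = dose[order]
    cum_cc = np.cumsum(areas[order]) * wall_thickness_mm / 1000.0
    total = cum_cc[-1]
    out = {}
    for x in volumes_cc:
        if total < x:
            log.info("total volume %.2f cc < %g cc; Dx clipped to min dose",
                     total, x)
            out[f"D{x:g}cc"] = float(sorted_dose[-1])
        else:
            i = int(np.searchsorted(cum_cc, x))
            out[f"D{x:g}cc"] = float(sorted_dose[min(i, len(sorted_dose) - 1)])
    return out
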