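"""Feature extraction: 21 DVPs, 43 textures, 224 DGPs (288 per patient)."""

from __future__ import annotations

import pandas as pd

from ..flattening import RSDM
from .dgp import DGP_KINDS, DGP_LEVELS_GY, compute_dgps, dgp_names
from .dvp import (DEFAULT_WALL_THICKNESS_MM, DVP_VOLUMES_CC, compute_dvps,
                  dvp_names)
from .texture import (DEFAULT_N_LEVELS, TEXTURE_FAMILIES, first_order,
                      glcm_features, glrlm_features, glszm_features,
                      ngtdm_features, quantize, texture_features,
                      texture_names)

__all__ = [
    "DGP_KINDS", "DGP_LEVELS_GY", "DVP_VOLUMES_CC",
    "DEFAULT_N_LEVELS", "DEFAULT_WALL_THICKNESS_MM", "TEXTURE_FAMILIES",
    "assemble_features", "compute_dgps", "compute_dvps", "dgp_names",
    "dvp_names", "feature_family", "feature_names", "first_order",
    "glcm_features", "glrlm_features", "glszm_features", "ngtdm_features",
    "quantize", "texture_features", "texture_names",
]


def feature_names() -> list[str]:
    """Stable 288-name feature order: DVPs, textures, DGPs."""
    return dvp_names() + texture_names() + dgp_names()


def feature_family(name: str) -> str:
    """Coarse family tag of a feature name: DVP / texture / DGP."""
    if not isinstance(name, str):
        raise KeyError(f"unknown feature {name!r}")
    if name in TEXTURE_FAMILIES:
        return "texture"
    if name.startswith("D") and name.endswith("cc"):
        return "DVP"
    for kind in DGP_KINDS:
        if name.startswith(kind):
            return "DGP"
    raise KeyError(f"unknown feature {name!r}")


def assemble_features(
    vertex_dose,
    vertex_areas,
    rsdm: RSDM,
    wall_thickness_mm: float = DEFAULT_WALL_THICKNESS_MM,
    n_levels: int = DEFAULT_N_LEVELS,
    patient_id: str = "",
) -> pd.Series:
    """One patient's full named feature vector (length 288)."""
    try:
        vals: dict[str, float] = {}
        vals.update(compute_dvps(vertex_dose, vertex_areas,
                                 wall_thickness_mm))
        vals.update(texture_features(rsdm.dose, rsdm.mask, n_levels))
        vals.update(compute_dgps(rsdm))
    except Exception as exc:
        raise RuntimeError(
            f"feature extraction failed for patient {patient_id!r}") from exc
    out = pd.Series({n: vals[n] for n in feature_names()},
                    name=patient_id or None)
    return out
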