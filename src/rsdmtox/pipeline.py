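"""End-to-end glue: fractions -> cumulative dose -> map -> feature table."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .accumulation import (CumulativeSurfaceDose, EQD2Params, accumulate_bt,
                           add_ebrt)
from .features import assemble_features
from .flattening import RSDM, flatten
from .geometry import vertex_areas
from .registration import RegParams, register
from .synthetic import CohortSpec, SyntheticPatient


def patient_cumulative_dose(
    patient: SyntheticPatient,
    use_true_dvfs: bool = True,
    ebrt_total: float = 45.0,
    ebrt_dose_per_fraction: float = 1.8,
    params: EQD2Params = EQD2Params(),
    reg_params: RegParams | None = None,
) -> CumulativeSurfaceDose:
    """Accumulate a synthetic patient's fractions onto the reference surface.

    With ``use_true_dvfs`` the generator's ground-truth correspondence is
    injected; otherwise the registration module estimates each DVF.
    """
    reference, *others = patient.fractions
    if use_true_dvfs:
        dvfs = patient.true_dvfs
    else:
        rp = reg_params or RegParams()
        dvfs = {f.fraction_index: register(f.geometry, reference.geometry, rp)
                for f in others}
    cum = accumulate_bt(reference, others, dvfs, params)
    return add_ebrt(cum, ebrt_total, ebrt_dose_per_fraction, params)


def patient_features(patient: SyntheticPatient, spec: CohortSpec,
                     use_true_dvfs: bool = True) -> tuple[pd.Series, RSDM]:
    cum = patient_cumulative_dose(
        patient, use_true_dvfs=use_true_dvfs, ebrt_total=spec.ebrt_total,
        ebrt_dose_per_fraction=spec.ebrt_dose_per_fraction)
    m = flatten(cum, patient.contours)
    m.patient_id = patient.patient_id
    areas = vertex_areas(cum.reference)
    return assemble_features(cum.values, areas, m,
                             patient_id=patient.patient_id), m


def cohort_feature_table(cohort: list[SyntheticPatient], spec: CohortSpec,
                         use_true_dvfs: bool = True
                         ) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature matrix (patients x 288) and label vector for a cohort."""
    rows = [patient_features(p, spec, use_true_dvfs)[0] for p in cohort]
    table = pd.DataFrame(rows)
    table.index = [p.patient_id for p in cohort]
    labels = np.array([p.label for p in cohort])
    return table, labels
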