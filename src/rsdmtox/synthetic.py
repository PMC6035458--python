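"""Synthetic cohorts: tubular rectum surfaces, inter-fraction deformation,
brachytherapy-like anterior hotspots and planted dose-geometry effects.

Everything is deterministic under the cohort seed (one master
``SeedSequence`` spawns per-patient and per-fraction streams). Each patient
carries ground truth: the analytic cumulative EQD2 dose on the reference
surface, the true inter-fraction deformation fields, and the causal feature
value that drove the toxicity label.

Anatomical convention: +y is anterior, so hotspot sources sit at large y and
the posterior cut used for meshing/flattening falls at minimum y.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from shapely.geometry import LinearRing

from .accumulation import EQD2Params, _fraction_eqd2, eqd2
from .flattening import flatten
from .geometry import (ContourStack, FractionRecord, Slice, SurfaceMesh,
                       contours_to_mesh)
from .registration import DVF

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CohortSpec:
    n_patients: int = 42
    toxicity_prevalence: float = 12.0 / 42.0
    n_bt_fractions: int | None = None  # None: alternate 4 (7 Gy) / 5 (6 Gy)
    deformation_amplitude: float = 6.0  # mm, max inter-fraction displacement
    shape_irregularity: float = 1.5  # mm, contour harmonic perturbation
    hotspot_offset_range: tuple[float, float] = (3.0, 10.0)  # mm, anterior
    hotspot_reference_radius: float = 10.0  # mm, dose == strength there
    hotspot_exponent: float = 2.0
    effect_dose_level: float = 65.0  # Gy EQD2; causal = relative area >= it
    effect_slope: float = 0.0  # logistic slope beta; 0 => null cohort
    ebrt_total: float = 45.0
    ebrt_dose_per_fraction: float = 1.8
    slice_spacing: float = 2.5
    points_per_contour: int = 48
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.toxicity_prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.n_patients < 1:
            raise ValueError("need at least one patient")


@dataclass
class SyntheticPatient:
    patient_id: str
    contours: ContourStack  # reference (first BT fraction) geometry
    fractions: list[FractionRecord]
    true_dvfs: dict[int, DVF]  # fraction index -> DVF onto the reference
    label: int
    ground_truth: dict


@dataclass(frozen=True)
class BTDoseField:
    """Inverse-power point-source dose: strength * (r0 / r)^exponent,
    capped at 3x strength near the source."""

    source: np.ndarray  # (3,) mm
    strength: float  # Gy at the reference radius
    exponent: float = 2.0
    reference_radius: float = 10.0

    def __post_init__(self) -> None:
        if self.strength <= 0:
            raise ValueError("strength must be > 0")
        object.__setattr__(self, "source",
                           np.asarray(self.source, dtype=float))

    def __call__(self, points: np.ndarray) -> np.ndarray:
        r = np.linalg.norm(np.asarray(points, dtype=float) - self.source,
                           axis=-1)
        near = r < self.reference_radius * 3.0 ** (-1.0 / self.exponent)
        if np.any(near):
            log.debug("dose cap applied at %d points", int(near.sum()))
        with np.errstate(divide="ignore"):
            d = self.strength * (self.reference_radius
                                 / np.maximum(r, 1e-9)) ** self.exponent
        return np.minimum(d, 3.0 * self.strength)


def make_rectum(spec: CohortSpec, patient_seed) -> ContourStack:
    """Elliptical tube with smooth low-order radius and centerline
    perturbations; length uniform in [60, 90] mm."""
    rng = np.random.default_rng(patient_seed)
    length = rng.uniform(60.0, 90.0)
    n_slices = max(int(round(length / spec.slice_spacing)) + 1, 3)
    rx = rng.uniform(10.0, 14.0)
    ry = rng.uniform(8.0, 12.0)
    # low-order harmonics in theta and z
    amp = spec.shape_irregularity
    k_theta = rng.integers(2, 5)
    ph_theta = rng.uniform(0, 2 * np.pi)
    ph_z = rng.uniform(0, 2 * np.pi, size=2)
    ctr_amp = amp * rng.uniform(0.5, 1.5, size=2)
    theta = np.arange(spec.points_per_contour) / spec.points_per_contour \
        * 2.0 * np.pi
    slices = []
    for i in range(n_slices):
        z = i * spec.slice_spacing
        u = z / max(length, 1e-9)
        radial = amp * np.cos(k_theta * theta + ph_theta) \
            * np.sin(np.pi * u + ph_z[0]) if amp > 0 else 0.0
        cx = ctr_amp[0] * np.sin(2 * np.pi * u + ph_z[0]) if amp > 0 else 0.0
        cy = ctr_amp[1] * np.sin(2 * np.pi * u + ph_z[1]) if amp > 0 else 0.0
        x = cx + (rx + radial) * np.cos(theta)
        y = cy + (ry + radial) * np.sin(theta)
        slices.append(Slice(z, np.column_stack([x, y])))
    return ContourStack(slices, spec.slice_spacing)


class GaussianBumpField:
    """Smooth in-plane displacement field: sum of random 3D Gaussian bumps,
    scaled so the peak magnitude equals ``amplitude``."""

    def __init__(self, amplitude: float, seed,
                 bounds: tuple[np.ndarray, np.ndarray], n_bumps: int = 4):
        rng = np.random.default_rng(seed)
        lo, hi = np.asarray(bounds[0]), np.asarray(bounds[1])
        self.centers = rng.uniform(lo, hi, size=(n_bumps, 3))
        self.sigmas = rng.uniform(0.25, 0.6, size=n_bumps) \
            * float(np.max(hi - lo))
        vec = rng.normal(size=(n_bumps, 2))
        vec /= np.linalg.norm(vec, axis=1, keepdims=True) + 1e-12
        self.weights = vec * rng.uniform(0.5, 1.0, size=(n_bumps, 1))
        self.amplitude = float(amplitude)
        # normalize peak magnitude on a probe grid
        probe = lo + rng.uniform(0, 1, size=(512, 3)) * (hi - lo)
        peak = np.linalg.norm(self._raw(probe), axis=1).max()
        self.scale = self.amplitude / peak if peak > 0 else 0.0

    def _raw(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        out = np.zeros((len(points), 2))
        for c, s, w in zip(self.centers, self.sigmas, self.weights):
            g = np.exp(-((points - c) ** 2).sum(axis=1) / (2.0 * s * s))
            out += g[:, None] * w
        return out

    def __call__(self, points: np.ndarray) -> np.ndarray:
        """In-plane (x, y, 0) displacement at each 3D point; magnitude is
        hard-capped at the amplitude (probe normalization is approximate)."""
        uv = self._raw(points) * self.scale
        mag = np.linalg.norm(uv, axis=1)
        over = mag > self.amplitude
        if np.any(over):
            uv[over] *= (self.amplitude / mag[over])[:, None]
        return np.column_stack([uv, np.zeros(len(uv))])


def _stack_bounds(stack: ContourStack) -> tuple[np.ndarray, np.ndarray]:
    pts = np.vstack([np.column_stack([s.points, np.full(len(s.points), s.z)])
                     for s in stack.slices])
    return pts.min(axis=0), pts.max(axis=0)


def deform_fraction(stack: ContourStack, amplitude: float, fraction_seed,
                    return_field: bool = False):
    """Apply a smooth random in-plane displacement field to every contour
    point. Displacement magnitude never exceeds ``amplitude``; a
    self-intersecting result triggers regeneration with damped amplitude."""
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    bounds = _stack_bounds(stack)
    amp = amplitude
    for attempt in range(10):
        fld = GaussianBumpField(amp, fraction_seed, bounds)
        slices = []
        ok = True
        for s in stack.slices:
            pts3 = np.column_stack([s.points, np.full(len(s.points), s.z)])
            moved = pts3 + fld(pts3)
            poly = moved[:, :2]
            if not LinearRing(poly).is_simple:
                ok = False
                break
            slices.append(Slice(s.z, poly))
        if ok:
            out = ContourStack(slices, stack.slice_spacing)
            return (out, fld) if return_field else out
        amp *= 0.7
        log.warning("deformed contour self-intersects; damping amplitude "
                    "to %.2f mm (attempt %d)", amp, attempt + 1)
    raise RuntimeError("could not generate a valid deformation")


def bt_dose_field(source_position, strength: float, exponent: float = 2.0,
                  reference_radius: float = 10.0) -> BTDoseField:
    return BTDoseField(np.asarray(source_position, dtype=float), strength,
                       exponent, reference_radius)


def _scheme(spec: CohortSpec, patient_index: int) -> tuple[int, float]:
    """BT fractionation: alternate 28 Gy / 4 fx and 30 Gy / 5 fx."""
    if spec.n_bt_fractions is not None:
        n = spec.n_bt_fractions
        return n, 28.0 / n if n == 4 else 30.0 / n
    return (4, 7.0) if patient_index % 2 == 0 else (5, 6.0)


def _generate_patient(spec: CohortSpec, index: int, seed_seq) -> tuple:
    """Geometry, doses and ground truth for one patient (label drawn later)."""
    seeds = seed_seq.spawn(8)
    rng = np.random.default_rng(seeds[0])
    stack0 = make_rectum(spec, seeds[1])
    ref_mesh = contours_to_mesh(stack0, samples_per_contour=None)
    n_fx, d_fx = _scheme(spec, index)
    offset = rng.uniform(*spec.hotspot_offset_range)
    strength0 = d_fx * rng.uniform(0.9, 1.1)
    mid = len(stack0.slices) // 2
    anterior_y = max(s.points[:, 1].max() for s in stack0.slices[mid - 1:
                                                                mid + 2])
    mid_z = stack0.slices[mid].z
    eqd2_params = EQD2Params()
    fractions: list[FractionRecord] = []
    true_dvfs: dict[int, DVF] = {}
    total = np.zeros(ref_mesh.n_vertices)
    for f in range(n_fx):
        if f == 0:
            mesh_f = ref_mesh.copy()
        else:
            fld = GaussianBumpField(spec.deformation_amplitude, seeds[2 + f],
                                    _stack_bounds(stack0))
            disp = fld(ref_mesh.vertices)
            mesh_f = SurfaceMesh(ref_mesh.vertices + disp, ref_mesh.faces,
                                 vertex_slice=ref_mesh.vertex_slice)
            true_dvfs[f] = DVF(-disp)  # warps fraction f back onto reference
        src = np.array([
            rng.normal(0.0, 2.0),
            anterior_y + offset + rng.normal(0.0, 1.5),
            mid_z + rng.normal(0.0, 6.0),
        ])
        dose_field = BTDoseField(src, strength0 * rng.uniform(0.95, 1.05),
                                 spec.hotspot_exponent,
                                 spec.hotspot_reference_radius)
        dose_f = dose_field(mesh_f.vertices)
        fractions.append(FractionRecord("BT", f, mesh_f, dose_f, d_fx, n_fx))
        total += _fraction_eqd2(dose_f, eqd2_params)
    total += eqd2(spec.ebrt_total, spec.ebrt_dose_per_fraction, eqd2_params)
    # causal feature: relative area (%) at the effect dose level on the
    # ground-truth RSDM
    from .accumulation import CumulativeSurfaceDose
    cum = CumulativeSurfaceDose(ref_mesh, total)
    m = flatten(cum, stack0)
    causal = 100.0 * float((m.valid_values()
                            >= spec.effect_dose_level).mean())
    ground_truth = {
        "cumulative_eqd2": total,
        "causal_feature": f"area{spec.effect_dose_level:g}",
        "causal_value": causal,
    }
    return stack0, fractions, true_dvfs, ground_truth


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def draw_labels(causal_values: np.ndarray, prevalence: float, beta: float,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Bernoulli labels from logistic(alpha + beta * standardized causal),
    with alpha = logit(prevalence). Standardization is cohort-internal
    (median / IQR-based scale), so beta = 0 reproduces the prevalence
    exactly in expectation."""
    c = np.asarray(causal_values, dtype=float)
    alpha = np.log(prevalence / (1.0 - prevalence))
    if beta == 0.0 or len(c) < 2:
        p = np.full(len(c), prevalence)
    else:
        center = np.median(c)
        q75, q25 = np.percentile(c, [75, 25])
        scale = max((q75 - q25) / 1.349, 1e-9)
        p = _sigmoid(alpha + beta * (c - center) / scale)
    labels = (rng.uniform(size=len(c)) < p).astype(int)
    return labels, p


def generate_cohort(spec: CohortSpec) -> list[SyntheticPatient]:
    """Deterministically generate the full cohort for ``spec``."""
    master = np.random.SeedSequence(spec.seed)
    label_seed, *patient_seeds = master.spawn(spec.n_patients + 1)
    raw = [_generate_patient(spec, i, s)
           for i, s in enumerate(patient_seeds)]
    causal = np.array([r[3]["causal_value"] for r in raw])
    labels, probs = draw_labels(causal, spec.toxicity_prevalence,
                                spec.effect_slope,
                                np.random.default_rng(label_seed))
    cohort = []
    for i, (stack0, fractions, dvfs, gt) in enumerate(raw):
        gt = dict(gt, toxicity_probability=float(probs[i]))
        cohort.append(SyntheticPatient(
            patient_id=f"P{i:03d}", contours=stack0, fractions=fractions,
            true_dvfs=dvfs, label=int(labels[i]), ground_truth=gt))
    return cohort
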