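# rsdmtox

Toolkit for rectal surface dose–toxicity analysis in combined external-beam
(EBRT) + brachytherapy (BT) cervical-cancer radiotherapy:

1. **Geometry** — ordered slice contours → stitched tube surface meshes,
   trilinear dose sampling, per-vertex area weights
   (`rsdmtox.geometry`, `rsdmtox.io`).
2. **Registration** — non-rigid surface point matching (Gaussian-mixture
   coherent point matching with Laplacian-smoothed displacement fields)
   producing deformation vector fields, plus DC / PE / VVD / HD similarity
   metrics on voxelized enclosed volumes (`rsdmtox.registration`).
3. **Accumulation** — per-fraction EQD2 conversion (linear-quadratic model,
   α/β = 3 Gy) and deformable summation of BT fractions onto the
   first-fraction reference surface; homogeneous EBRT added as one scalar;
   a static (no-deformation) baseline (`rsdmtox.accumulation`).
4. **Flattening** — cut each slice ring at its posterior-most point and
   unroll by arc length into a 2D rectum surface dose map (RSDM) that
   preserves physical length in both directions (`rsdmtox.flattening`).
5. **Features** — 21 dose-volume parameters (D0.1cc … D10cc), 43 texture
   features (3 first-order, 9 GLCM, 13 GLRLM, 13 GLSZM, 5 NGTDM) and
   224 dose-geometric parameters (relative area, perimeter, relative width,
   length at 45–100 Gy, 1 Gy steps) — 288 named features per patient
   (`rsdmtox.features`).
6. **Screening** — PCA representative features (>99 % variance) and
   Mann-Whitney U screening with raw p-values (`rsdmtox.screening`).
7. **Prediction** — SMOTE-balanced RBF-SVM with sequential forward feature
   selection under repeated stratified 5-fold cross-validation, ACC / SEN /
   SPE / AUC, selection-frequency feature ranking, DeLong ROC comparison
   with Bonferroni correction (`rsdmtox.prediction`).
8. **Synthetic cohorts** — deterministic generator of tubular rectum
   surfaces (6–9 cm), smooth inter-fraction deformations with ground-truth
   correspondences, BT-like anterior hotspots (4×7 Gy / 5×6 Gy schemes),
   a 45 Gy/25 fx EBRT phase, and toxicity labels driven by a planted
   high-dose relative-area effect (`rsdmtox.synthetic`).

## CLI

```sh
rsdmtox simulate --out cohort/ --n 42 --beta 4 --seed 17
rsdmtox mesh --contours cohort/P000/contours.txt --out mesh.ply
rsdmtox register --moving f2.ply --fixed f1.ply --out dvf.json --metrics m.json
rsdmtox accumulate --fractions manifest.json --dvf-dir dvfs/ \
    --alpha-beta 3 --ebrt 45:1.8 --out cum.ply
rsdmtox flatten --cum cum.ply --contours cohort/P000/contours.txt --out rsdm
rsdmtox features --rsdm rsdm --cum cum.ply --patient-id P000 --out feats.csv
rsdmtox screen --features feats.csv --labels labels.csv --mode sta \
    --out screened.csv --report pvalues.csv
rsdmtox predict --features screened.csv --labels labels.csv \
    --repeats 100 --out result.json --ranking ranking.csv
```

### Slice-contour text format

```
# rsdmtox contours v1
spacing 2.5
z 0.0
x1 y1
x2 y2
...
z 2.5
...
```

One block per axial slice (z strictly increasing, mm); ≥3 `x y` points per
closed polygon. Polygons are normalized at load time to counter-clockwise
orientation (viewed from superior) with the starting point rotated to the
posterior-most vertex (+y is anterior). Meshes are ASCII PLY with optional
per-vertex `dose` (Gy) and `slice` properties; RSDMs are a dose CSV (NaN
outside the valid mask) plus a JSON header.

## Conventions worth knowing

- Coordinates are right-handed, mm, +z superior, +y anterior.
- The EQD2 fraction size used for BT vertices is the vertex's own
  fractional dose (surface dose is heterogeneous); EBRT uses 1.8 Gy.
- RSDM rows lie at inter-slice band midpoints (rows × row-spacing = tube
  length exactly); rows are left-aligned at the posterior cut with a
  ragged masked right edge; map width is patient specific.
- Texture quantization is 32 equal-width levels over the valid-pixel dose
  range; zones are 8-connected; GLRLM uses 4 directions at distance 1.
- All randomness flows from explicit seeds; identical seeds give
  byte-identical cohorts, feature tables and prediction results.
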