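"""Texture features of the 2D dose map: 3 first-order statistics plus
GLCM (9), GLRLM (13), GLSZM (13) and NGTDM (5) families — 43 in total.

Conventions (pinned by tests, configurable where noted):
  * quantization: equal-width bins over the valid-pixel dose range,
    default 32 levels, level index 1..n (0 marks masked pixels);
  * GLCM: distance 1, four directions (0/45/90/135 deg), symmetric,
    direction-averaged normalized matrix;
  * GLRLM: runs along the same four directions inside the mask, matrices
    summed over directions before feature computation;
  * GLSZM: zones are 8-connected constant-level components inside the mask;
  * NGTDM: 8-neighborhood restricted to valid pixels.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.stats import skew

_EPS = np.finfo(float).tiny

GLCM_NAMES = ["energy", "contrast", "correlation", "homogeneity", "entropy",
              "variance", "sum_average", "dissimilarity", "autocorrelation"]
GLRLM_NAMES = ["sre", "lre", "gln", "rln", "rp", "lgre", "hgre",
               "srlge", "srhge", "lrlge", "lrhge", "glv", "rlv"]
GLSZM_NAMES = ["sze", "lze", "gln", "zsn", "zp", "lgze", "hgze",
               "szlge", "szhge", "lzlge", "lzhge", "glv", "zsv"]
NGTDM_NAMES = ["coarseness", "contrast", "busyness", "complexity", "strength"]
FIRST_ORDER_NAMES = ["mean", "std", "skewness"]

DEFAULT_N_LEVELS = 32

#: feature name -> family tag, in stable output order
TEXTURE_FAMILIES: dict[str, str] = {}
for _n in FIRST_ORDER_NAMES:
    TEXTURE_FAMILIES[f"fo_{_n}"] = "first_order"
for _n in GLCM_NAMES:
    TEXTURE_FAMILIES[f"glcm_{_n}"] = "glcm"
for _n in GLRLM_NAMES:
    TEXTURE_FAMILIES[f"glrlm_{_n}"] = "glrlm"
for _n in GLSZM_NAMES:
    TEXTURE_FAMILIES[f"glszm_{_n}"] = "glszm"
for _n in NGTDM_NAMES:
    TEXTURE_FAMILIES[f"ngtdm_{_n}"] = "ngtdm"


def texture_names() -> list[str]:
    return list(TEXTURE_FAMILIES)


def quantize(dose: np.ndarray, mask: np.ndarray,
             n_levels: int = DEFAULT_N_LEVELS) -> np.ndarray:
    """Equal-width quantization of valid pixels to integer levels 1..n;
    masked pixels get level 0. A constant map maps to level 1."""
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    dose = np.asarray(dose, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    vals = dose[mask]
    if vals.size == 0:
        raise ValueError("empty mask")
    lo, hi = vals.min(), vals.max()
    levels = np.zeros(dose.shape, dtype=int)
    if hi - lo <= 0:
        levels[mask] = 1
        return levels
    q = np.floor((dose[mask] - lo) / (hi - lo) * n_levels).astype(int) + 1
    levels[mask] = np.clip(q, 1, n_levels)
    return levels


def first_order(dose: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    vals = np.asarray(dose, dtype=float)[np.asarray(mask, dtype=bool)]
    if vals.size < 2:
        raise ValueError("need at least 2 valid pixels")
    sd = float(vals.std())
    return {
        "fo_mean": float(vals.mean()),
        "fo_std": sd,
        "fo_skewness": float(skew(vals)) if sd > 0 else 0.0,
    }


# four distance-1 directions in (drow, dcol) image convention
_DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


def glcm_matrix(levels: np.ndarray,
                directions: tuple = _DIRECTIONS) -> np.ndarray:
    """Symmetric, direction-averaged, normalized co-occurrence matrix."""
    ng = int(levels.max())
    if ng < 1:
        raise ValueError("no valid pixels")
    acc = np.zeros((ng, ng))
    rows, cols = levels.shape
    for dr, dc in directions:
        mat = np.zeros((ng, ng))
        r0, r1 = max(0, -dr), min(rows, rows - dr)
        c0, c1 = max(0, -dc), min(cols, cols - dc)
        a = levels[r0:r1, c0:c1]
        b = levels[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        ok = (a > 0) & (b > 0)
        np.add.at(mat, (a[ok] - 1, b[ok] - 1), 1.0)
        mat = mat + mat.T  # symmetric
        if mat.sum() > 0:
            acc += mat / mat.sum()
    return acc / len(directions)


def glcm_features(levels: np.ndarray,
                  directions: tuple = _DIRECTIONS) -> dict[str, float]:
    p = glcm_matrix(levels, directions)
    ng = p.shape[0]
    i, j = np.meshgrid(np.arange(1, ng + 1), np.arange(1, ng + 1),
                       indexing="ij")
    px = p.sum(axis=1)
    mu = float((px * np.arange(1, ng + 1)).sum())
    var = float((px * (np.arange(1, ng + 1) - mu) ** 2).sum())
    sigma = np.sqrt(var)
    if sigma > 1e-12:
        corr = float(((p * (i - mu) * (j - mu)).sum()) / (sigma * sigma))
    else:
        corr = 1.0
    pos = p[p > 0]
    return {
        "glcm_energy": float((p ** 2).sum()),
        "glcm_contrast": float((p * (i - j) ** 2).sum()),
        "glcm_correlation": corr,
        "glcm_homogeneity": float((p / (1.0 + (i - j) ** 2)).sum()),
        "glcm_entropy": float(-(pos * np.log2(pos)).sum()),
        "glcm_variance": var,
        "glcm_sum_average": float((p * (i + j)).sum()),
        "glcm_dissimilarity": float((p * np.abs(i - j)).sum()),
        "glcm_autocorrelation": float((p * i * j).sum()),
    }


def _lines(levels: np.ndarray, direction: tuple[int, int]):
    """1D level sequences along a direction (0 breaks runs at the mask)."""
    if direction == (0, 1):
        yield from levels
    elif direction == (-1, 0):
        yield from levels.T
    elif direction == (-1, 1):  # 45 deg: anti-diagonals bottom-left -> top-right
        flipped = levels[::-1]
        for k in range(-flipped.shape[0] + 1, flipped.shape[1]):
            yield np.diagonal(flipped, offset=k)
    elif direction == (-1, -1):  # 135 deg
        flipped = levels[::-1, ::-1]
        for k in range(-flipped.shape[0] + 1, flipped.shape[1]):
            yield np.diagonal(flipped, offset=k)
    else:  # pragma: no cover
        raise ValueError(direction)


def glrlm_matrix(levels: np.ndarray) -> np.ndarray:
    """Run-length matrix P[level-1, length-1] summed over 4 directions."""
    ng = int(levels.max())
    max_len = max(levels.shape)
    mat = np.zeros((ng, max_len))
    for d in _DIRECTIONS:
        for line in _lines(levels, d):
            run_level, run_len = 0, 0
            for v in list(line) + [0]:
                if v == run_level and v != 0:
                    run_len += 1
                else:
                    if run_level != 0:
                        mat[run_level - 1, run_len - 1] += 1
                    run_level, run_len = v, 1
    return mat


def _rl_features(mat: np.ndarray, n_pixels: int, prefix: str,
                 names: list[str], n_dirs: int = 1) -> dict[str, float]:
    """Shared run-length / size-zone feature formulas."""
    ns = mat.sum()
    if ns <= 0:
        raise ValueError("empty matrix")
    p = mat / ns
    ng, jm = mat.shape
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, jm + 1)[None, :]
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float((pi * i[:, 0]).sum())
    mu_j = float((pj * j[0]).sum())
    vals = [
        float((p / j ** 2).sum()),                      # short emphasis
        float((p * j ** 2).sum()),                      # long emphasis
        float((mat.sum(axis=1) ** 2).sum() / ns),       # gray-level nonunif.
        float((mat.sum(axis=0) ** 2).sum() / ns),       # length nonunif.
        float(ns / (n_dirs * n_pixels)),                # percentage
        float((p / i ** 2).sum()),                      # low gray emphasis
        float((p * i ** 2).sum()),                      # high gray emphasis
        float((p / (i ** 2 * j ** 2)).sum()),           # short + low
        float((p * i ** 2 / j ** 2).sum()),             # short + high
        float((p * j ** 2 / i ** 2).sum()),             # long + low
        float((p * i ** 2 * j ** 2).sum()),             # long + high
        float((pi * (i[:, 0] - mu_i) ** 2).sum()),      # gray-level variance
        float((pj * (j[0] - mu_j) ** 2).sum()),         # length variance
    ]
    return {f"{prefix}_{n}": v for n, v in zip(names, vals)}


def glrlm_features(levels: np.ndarray) -> dict[str, float]:
    n_pixels = int((levels > 0).sum())
    if n_pixels < 2:
        raise ValueError("need at least 2 valid pixels")
    return _rl_features(glrlm_matrix(levels), n_pixels, "glrlm", GLRLM_NAMES,
                        n_dirs=len(_DIRECTIONS))


def glszm_matrix(levels: np.ndarray) -> np.ndarray:
    """Size-zone matrix P[level-1, size-1]; zones are 8-connected."""
    ng = int(levels.max())
    n_pixels = int((levels > 0).sum())
    mat = np.zeros((ng, n_pixels))
    structure = np.ones((3, 3), dtype=int)
    for lv in range(1, ng + 1):
        lab, n_zones = ndimage.label(levels == lv, structure=structure)
        if n_zones == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            mat[lv - 1, s - 1] += 1
    return mat


def glszm_features(levels: np.ndarray) -> dict[str, float]:
    n_pixels = int((levels > 0).sum())
    if n_pixels < 2:
        raise ValueError("need at least 2 valid pixels")
    mat = glszm_matrix(levels)
    mat = mat[:, :max(1, int(np.nonzero(mat.any(axis=0))[0].max()) + 1)]
    return _rl_features(mat, n_pixels, "glszm", GLSZM_NAMES, n_dirs=1)


def ngtdm_features(levels: np.ndarray) -> dict[str, float]:
    """Amadasun-Kanellopoulos neighborhood gray-tone difference features."""
    valid = levels > 0
    if valid.sum() < 2:
        raise ValueError("need at least 2 valid pixels")
    ng = int(levels.max())
    padded = np.pad(levels.astype(float), 1)
    pmask = np.pad(valid, 1)
    nbr_sum = np.zeros(levels.shape)
    nbr_cnt = np.zeros(levels.shape)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            sl = (slice(1 + dr, padded.shape[0] - 1 + dr),
                  slice(1 + dc, padded.shape[1] - 1 + dc))
            nbr_sum += np.where(pmask[sl], padded[sl], 0.0)
            nbr_cnt += pmask[sl]
    use = valid & (nbr_cnt > 0)
    n = int(use.sum())
    s = np.zeros(ng + 1)
    cnt = np.zeros(ng + 1)
    lv = levels[use]
    diff = np.abs(lv - nbr_sum[use] / nbr_cnt[use])
    np.add.at(s, lv, diff)
    np.add.at(cnt, lv, 1.0)
    p = cnt / n
    present = np.nonzero(p > 0)[0]
    ngp = len(present)
    i = np.arange(ng + 1)
    coarseness = 1.0 / max((p * s).sum(), _EPS)
    if ngp > 1:
        pij = p[present][:, None] * p[present][None, :]
        dij2 = (present[:, None] - present[None, :]) ** 2
        contrast = (pij * dij2).sum() / (ngp * (ngp - 1)) * s.sum() / n
        denom = np.abs(present[:, None] * p[present][:, None]
                       - present[None, :] * p[present][None, :]).sum()
        busyness = (p * s).sum() / denom if denom > 0 else 0.0
        absdiff = np.abs(present[:, None] - present[None, :]).astype(float)
        ps = (p * s)[present]
        complexity = (absdiff * (ps[:, None] + ps[None, :])
                      / (p[present][:, None] + p[present][None, :])).sum() / n
        strength = ((p[present][:, None] + p[present][None, :])
                    * dij2).sum() / max(s.sum(), _EPS)
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "ngtdm_coarseness": float(coarseness),
        "ngtdm_contrast": float(contrast),
        "ngtdm_busyness": float(busyness),
        "ngtdm_complexity": float(complexity),
        "ngtdm_strength": float(strength),
    }


def texture_features(dose: np.ndarray, mask: np.ndarray,
                     n_levels: int = DEFAULT_N_LEVELS) -> dict[str, float]:
    """All 43 texture features of a masked dose map, in stable order."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("need at least 2 valid pixels")
    levels = quantize(dose, mask, n_levels)
    out: dict[str, float] = {}
    out.update(first_order(dose, mask))
    out.update(glcm_features(levels))
    out.update(glrlm_features(levels))
    out.update(glszm_features(levels))
    out.update(ngtdm_features(levels))
    return {name: out[name] for name in TEXTURE_FAMILIES}
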