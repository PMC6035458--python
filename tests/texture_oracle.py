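"""Brute-force texture feature oracle: every matrix is built by explicit
pixel enumeration with plain Python loops, independently of the package's
vectorized implementation. Shares only the documented conventions
(directions, symmetry, aggregation rules)."""

import math

DIRECTIONS = [(0, 1), (-1, 1), (-1, 0), (-1, -1)]


def oracle_first_order(dose, mask):
    vals = [dose[r][c] for r in range(len(dose)) for c in range(len(dose[0]))
            if mask[r][c]]
    n = len(vals)
    mean = sum(vals) / n
    var = sum((v - mean) ** 2 for v in vals) / n
    sd = math.sqrt(var)
    if sd > 0:
        skew = sum((v - mean) ** 3 for v in vals) / n / sd ** 3
    else:
        skew = 0.0
    return {"fo_mean": mean, "fo_std": sd, "fo_skewness": skew}


def oracle_glcm_matrix(levels, directions=DIRECTIONS):
    rows, cols = len(levels), len(levels[0])
    ng = max(max(r) for r in levels)
    acc = [[0.0] * ng for _ in range(ng)]
    for dr, dc in directions:
        mat = [[0.0] * ng for _ in range(ng)]
        total = 0
        for r in range(rows):
            for c in range(cols):
                r2, c2 = r + dr, c + dc
                if not (0 <= r2 < rows and 0 <= c2 < cols):
                    continue
                a, b = levels[r][c], levels[r2][c2]
                if a == 0 or b == 0:
                    continue
                mat[a - 1][b - 1] += 1
                mat[b - 1][a - 1] += 1
                total += 2
        if total:
            for i in range(ng):
                for j in range(ng):
                    acc[i][j] += mat[i][j] / total
    return [[x / len(directions) for x in row] for row in acc]


def oracle_glcm(levels, directions=DIRECTIONS):
    p = oracle_glcm_matrix(levels, directions)
    ng = len(p)
    px = [sum(p[i]) for i in range(ng)]
    mu = sum(px[i] * (i + 1) for i in range(ng))
    var = sum(px[i] * (i + 1 - mu) ** 2 for i in range(ng))
    sigma = math.sqrt(var)
    energy = contrast = homog = entropy = sum_avg = dissim = autoc = 0.0
    corr_num = 0.0
    for i in range(ng):
        for j in range(ng):
            v = p[i][j]
            energy += v * v
            contrast += v * (i - j) ** 2
            homog += v / (1.0 + (i - j) ** 2)
            if v > 0:
                entropy -= v * math.log2(v)
            sum_avg += v * (i + j + 2)
            dissim += v * abs(i - j)
            autoc += v * (i + 1) * (j + 1)
            corr_num += v * (i + 1 - mu) * (j + 1 - mu)
    corr = corr_num / (sigma * sigma) if sigma > 1e-12 else 1.0
    return {"glcm_energy": energy, "glcm_contrast": contrast,
            "glcm_correlation": corr, "glcm_homogeneity": homog,
            "glcm_entropy": entropy, "glcm_variance": var,
            "glcm_sum_average": sum_avg, "glcm_dissimilarity": dissim,
            "glcm_autocorrelation": autoc}


def _runs_along(levels, start, step):
    """Run-length encode one line starting at `start`, walking by `step`."""
    rows, cols = len(levels), len(levels[0])
    r, c = start
    seq = []
    while 0 <= r < rows and 0 <= c < cols:
        seq.append(levels[r][c])
        r += step[0]
        c += step[1]
    runs = []
    cur, n = 0, 0
    for v in seq + [0]:
        if v == cur and v != 0:
            n += 1
        else:
            if cur != 0:
                runs.append((cur, n))
            cur, n = v, 1
    return runs


def oracle_glrlm_matrix(levels):
    rows, cols = len(levels), len(levels[0])
    ng = max(max(r) for r in levels)
    max_len = max(rows, cols)
    mat = [[0.0] * max_len for _ in range(ng)]
    starts = {
        (0, 1): [(r, 0) for r in range(rows)],
        (-1, 0): [(rows - 1, c) for c in range(cols)],
        # 45 deg: walk up-right from left column and bottom row
        (-1, 1): [(r, 0) for r in range(rows)]
        + [(rows - 1, c) for c in range(1, cols)],
        # 135 deg: walk up-left from right column and bottom row
        (-1, -1): [(r, cols - 1) for r in range(rows)]
        + [(rows - 1, c) for c in range(cols - 1)],
    }
    for step, origin_list in starts.items():
        for origin in origin_list:
            for lv, ln in _runs_along(levels, origin, step):
                mat[lv - 1][ln - 1] += 1
    return mat


def _rl_oracle(mat, n_pixels, prefix, names, n_dirs):
    ns = sum(sum(r) for r in mat)
    ng, jm = len(mat), len(mat[0])
    p = [[v / ns for v in row] for row in mat]
    pi = [sum(p[i]) for i in range(ng)]
    pj = [sum(p[i][j] for i in range(ng)) for j in range(jm)]
    mu_i = sum(pi[i] * (i + 1) for i in range(ng))
    mu_j = sum(pj[j] * (j + 1) for j in range(jm))
    def S(fun):
        return sum(fun(i + 1, j + 1) * p[i][j]
                   for i in range(ng) for j in range(jm))
    vals = [
        S(lambda i, j: 1.0 / j ** 2),
        S(lambda i, j: j ** 2),
        sum(sum(mat[i]) ** 2 for i in range(ng)) / ns,
        sum(sum(mat[i][j] for i in range(ng)) ** 2 for j in range(jm)) / ns,
        ns / (n_dirs * n_pixels),
        S(lambda i, j: 1.0 / i ** 2),
        S(lambda i, j: i ** 2),
        S(lambda i, j: 1.0 / (i ** 2 * j ** 2)),
        S(lambda i, j: i ** 2 / j ** 2),
        S(lambda i, j: j ** 2 / i ** 2),
        S(lambda i, j: i ** 2 * j ** 2),
        sum(pi[i] * (i + 1 - mu_i) ** 2 for i in range(ng)),
        sum(pj[j] * (j + 1 - mu_j) ** 2 for j in range(jm)),
    ]
    return {f"{prefix}_{n}": v for n, v in zip(names, vals)}


def oracle_glrlm(levels):
    from rsdmtox.features.texture import GLRLM_NAMES
    n_pixels = sum(1 for row in levels for v in row if v != 0)
    return _rl_oracle(oracle_glrlm_matrix(levels), n_pixels, "glrlm",
                      GLRLM_NAMES, n_dirs=4)


def oracle_glszm_matrix(levels):
    rows, cols = len(levels), len(levels[0])
    ng = max(max(r) for r in levels)
    seen = [[False] * cols for _ in range(rows)]
    zones = []
    for r in range(rows):
        for c in range(cols):
            if levels[r][c] == 0 or seen[r][c]:
                continue
            lv = levels[r][c]
            stack, size = [(r, c)], 0
            seen[r][c] = True
            while stack:
                rr, cc = stack.pop()
                size += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        r2, c2 = rr + dr, cc + dc
                        if (0 <= r2 < rows and 0 <= c2 < cols
                                and not seen[r2][c2]
                                and levels[r2][c2] == lv):
                            seen[r2][c2] = True
                            stack.append((r2, c2))
            zones.append((lv, size))
    max_size = max(s for _, s in zones)
    mat = [[0.0] * max_size for _ in range(ng)]
    for lv, s in zones:
        mat[lv - 1][s - 1] += 1
    return mat


def oracle_glszm(levels):
    from rsdmtox.features.texture import GLSZM_NAMES
    n_pixels = sum(1 for row in levels for v in row if v != 0)
    return _rl_oracle(oracle_glszm_matrix(levels), n_pixels, "glszm",
                      GLSZM_NAMES, n_dirs=1)


def oracle_ngtdm(levels):
    rows, cols = len(levels), len(levels[0])
    ng = max(max(r) for r in levels)
    s = [0.0] * (ng + 1)
    cnt = [0] * (ng + 1)
    n = 0
    for r in range(rows):
        for c in range(cols):
            lv = levels[r][c]
            if lv == 0:
                continue
            nb = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < rows and 0 <= c2 < cols \
                            and levels[r2][c2] != 0:
                        nb.append(levels[r2][c2])
            if not nb:
                continue
            s[lv] += abs(lv - sum(nb) / len(nb))
            cnt[lv] += 1
            n += 1
    p = [c / n for c in cnt]
    present = [i for i in range(ng + 1) if p[i] > 0]
    ngp = len(present)
    tiny = 2.2250738585072014e-308
    coarse = 1.0 / max(sum(p[i] * s[i] for i in present), tiny)
    if ngp > 1:
        contrast = sum(p[i] * p[j] * (i - j) ** 2
                       for i in present for j in present) \
            / (ngp * (ngp - 1)) * sum(s) / n
        denom = sum(abs(i * p[i] - j * p[j])
                    for i in present for j in present)
        busy = sum(p[i] * s[i] for i in present) / denom if denom > 0 else 0.0
        cplx = sum(abs(i - j) * (p[i] * s[i] + p[j] * s[j])
                   / (p[i] + p[j])
                   for i in present for j in present) / n
        strength = sum((p[i] + p[j]) * (i - j) ** 2
                       for i in present for j in present) \
            / max(sum(s), tiny)
    else:
        contrast = busy = cplx = strength = 0.0
    return {"ngtdm_coarseness": coarse, "ngtdm_contrast": contrast,
            "ngtdm_busyness": busy, "ngtdm_complexity": cplx,
            "ngtdm_strength": strength}


def oracle_all_textures(dose, mask, levels):
    out = {}
    out.update(oracle_first_order(dose, mask))
    out.update(oracle_glcm(levels))
    out.update(oracle_glrlm(levels))
    out.update(oracle_glszm(levels))
    out.update(oracle_ngtdm(levels))
    return out
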