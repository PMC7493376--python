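"""Independent brute-force oracles for the texture-matrix families.

Everything here is written as plain nested loops over voxels, offsets and
neighbourhoods — deliberately naive and separate from the package's vectorized
implementations — so agreement on small fixtures is a genuine cross-check.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np

OFFSETS_13 = [(dx, dy, dz)
              for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
              if (dx, dy, dz) > (0, 0, 0)]
OFFSETS_26 = [o for o in product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]
OFFSETS_8_2D = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]
TFC_PAIRS = [((-1, 0), (1, 0)), ((0, -1), (0, 1)),
             ((-1, -1), (1, 1)), ((-1, 1), (1, -1))]


def _inside(shape, v):
    return all(0 <= c < n for c, n in zip(v, shape))


def _in_mask(mask, v):
    return _inside(mask.shape, v) and bool(mask[v])


def _entropy2(p):
    return -sum(x * math.log2(x) for x in np.ravel(p) if x > 0)


def cooccurrence_matrix(levels, mask, n_levels, offsets=OFFSETS_13, base=1):
    """Symmetric pooled GLCM counts by exhaustive ordered-pair enumeration."""
    c = np.zeros((n_levels, n_levels))
    for v in product(*(range(n) for n in mask.shape)):
        if not mask[v]:
            continue
        for off in offsets:
            for sgn in (1, -1):
                w = tuple(a + sgn * d for a, d in zip(v, off))
                if _in_mask(mask, w):
                    c[levels[v] - base, levels[w] - base] += 1
    return c


def haralick_features(p, values):
    i = np.asarray(values, float)[:, None]
    j = np.asarray(values, float)[None, :]
    mu = (i * p).sum()
    var = (((i - mu) ** 2) * p).sum()
    corr = ((i - mu) * (j - mu) * p).sum() / var if var > 0 else 0.0
    return {
        "second_angular_moment": (p ** 2).sum(),
        "contrast": (p * (i - j) ** 2).sum(),
        "entropy": _entropy2(p),
        "homogeneity": (p / (1 + abs(i - j))).sum(),
        "dissimilarity": (p * abs(i - j)).sum(),
        "inverse_difference_moment": (p / (1 + (i - j) ** 2)).sum(),
        "correlation": corr,
        "intensity": (p * (i + j) / 2).sum(),
        "variance": (p * ((i - mu) ** 2 + (j - mu) ** 2) / 2).sum(),
    }


def glcm_features(levels, mask, n_levels):
    c = cooccurrence_matrix(levels, mask, n_levels)
    h = haralick_features(c / c.sum(), range(1, n_levels + 1))
    keys = ["second_angular_moment", "contrast", "entropy", "homogeneity",
            "dissimilarity", "inverse_difference_moment", "correlation"]
    return {k: h[k] for k in keys}


def nglcm_features(levels, mask, n_levels):
    c = cooccurrence_matrix(levels, mask, n_levels)
    p = np.zeros_like(c)
    for r in range(n_levels):
        if c[r].sum() > 0:
            p[r] = c[r] / c[r].sum()
    p = p / p.sum()
    h = haralick_features(p, range(1, n_levels + 1))
    keys = ["second_angular_moment", "contrast", "entropy", "homogeneity",
            "inverse_difference_moment", "dissimilarity"]
    return {k: h[k] for k in keys}


def run_list(levels, mask, offsets=OFFSETS_13):
    """All maximal collinear same-level in-mask runs as (level, length)."""
    runs = []
    for off in offsets:
        for v in product(*(range(n) for n in mask.shape)):
            if not mask[v]:
                continue
            prev = tuple(a - d for a, d in zip(v, off))
            if _in_mask(mask, prev) and levels[prev] == levels[v]:
                continue  # not a run start
            length = 1
            w = tuple(a + d for a, d in zip(v, off))
            while _in_mask(mask, w) and levels[w] == levels[v]:
                length += 1
                w = tuple(a + d for a, d in zip(w, off))
            runs.append((int(levels[v]), length))
    return runs


def emphasis_features(entries, n_voxels, denom_count, kind):
    """11 run-length/size-zone indices from (level, length) entries."""
    n = len(entries)
    short = f"short_{kind}"
    long_ = ("long" if kind == "run" else "large") + f"_{kind}"
    f = {
        f"{short}_emphasis": sum(1 / l ** 2 for _, l in entries) / n,
        f"{long_}_emphasis": sum(l ** 2 for _, l in entries) / n,
        f"{kind}_percentage": n / denom_count,
        f"low_intensity_{kind}_emphasis": sum(1 / i ** 2 for i, _ in entries) / n,
        f"high_intensity_{kind}_emphasis": sum(i ** 2 for i, _ in entries) / n,
        f"low_intensity_{short}_emphasis": sum(1 / (i * l) ** 2 for i, l in entries) / n,
        f"high_intensity_{short}_emphasis": sum(i ** 2 / l ** 2 for i, l in entries) / n,
        f"low_intensity_{long_}_emphasis": sum(l ** 2 / i ** 2 for i, l in entries) / n,
        f"high_intensity_{long_}_emphasis": sum((i * l) ** 2 for i, l in entries) / n,
    }
    by_level, by_len = {}, {}
    for i, l in entries:
        by_level[i] = by_level.get(i, 0) + 1
        by_len[l] = by_len.get(l, 0) + 1
    f["intensity_variability"] = sum(c ** 2 for c in by_level.values()) / n
    f["run_length_variability" if kind == "run" else "size_zone_variability"] = \
        sum(c ** 2 for c in by_len.values()) / n
    return f


def rlm_features(levels, mask, offsets=OFFSETS_13):
    runs = run_list(levels, mask, offsets)
    nvox = int(mask.sum())
    return emphasis_features(runs, nvox, nvox * len(offsets), "run")


def zone_list(levels, mask):
    """26-connected same-level zones via BFS flood fill."""
    seen = np.zeros(mask.shape, bool)
    zones = []
    for v in product(*(range(n) for n in mask.shape)):
        if not mask[v] or seen[v]:
            continue
        level = levels[v]
        stack, size = [v], 0
        seen[v] = True
        while stack:
            u = stack.pop()
            size += 1
            for off in OFFSETS_26:
                w = tuple(a + d for a, d in zip(u, off))
                if _in_mask(mask, w) and not seen[w] and levels[w] == level:
                    seen[w] = True
                    stack.append(w)
        zones.append((int(level), size))
    return zones


def szm_features(levels, mask):
    zones = zone_list(levels, mask)
    nvox = int(mask.sum())
    return emphasis_features(zones, nvox, nvox, "zone")


def ngtdm_features(levels, mask, n_levels, eps=1e-6, cap=1e6):
    s = {}
    n_i = {}
    nvox = 0
    for v in product(*(range(n) for n in mask.shape)):
        if not mask[v]:
            continue
        nb = [levels[tuple(a + d for a, d in zip(v, off))]
              for off in OFFSETS_26
              if _in_mask(mask, tuple(a + d for a, d in zip(v, off)))]
        if not nb:
            continue
        nvox += 1
        i = int(levels[v])
        s[i] = s.get(i, 0.0) + abs(i - sum(nb) / len(nb))
        n_i[i] = n_i.get(i, 0) + 1
    if nvox == 0:
        return {k: float("nan") for k in
                ["coarseness", "contrast", "busyness", "complexity", "strength"]}
    p = {i: c / nvox for i, c in n_i.items()}
    present = sorted(p)
    ngr = len(present)
    psum = sum(p[i] * s.get(i, 0.0) for i in present)
    coarseness = min(1.0 / (eps + psum), cap)
    if ngr <= 1:
        return {"coarseness": coarseness, "contrast": 0.0, "busyness": 0.0,
                "complexity": 0.0, "strength": 0.0}
    contrast = (sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
                / (ngr * (ngr - 1))) * (sum(s.values()) / nvox)
    denom = sum(abs(i * p[i] - j * p[j]) for i in present for j in present)
    busyness = psum / denom if denom > 0 else 0.0
    complexity = sum(abs(i - j) * (p[i] * s.get(i, 0.0) + p[j] * s.get(j, 0.0))
                     / (nvox * (p[i] + p[j])) for i in present for j in present)
    strength = sum((p[i] + p[j]) * (i - j) ** 2 for i in present for j in present) \
        / (eps + sum(s.values()))
    return {"coarseness": coarseness, "contrast": contrast, "busyness": busyness,
            "complexity": complexity, "strength": strength}


def ngldm_features(levels, mask, n_levels):
    q = {}
    for v in product(*(range(n) for n in mask.shape)):
        if not mask[v]:
            continue
        k = sum(1 for off in OFFSETS_26
                if _in_mask(mask, tuple(a + d for a, d in zip(v, off)))
                and levels[tuple(a + d for a, d in zip(v, off))] == levels[v])
        key = (int(levels[v]), k + 1)
        q[key] = q.get(key, 0) + 1
    nq = sum(q.values())
    by_d = {}
    for (_, d), c in q.items():
        by_d[d] = by_d.get(d, 0) + c
    return {
        "small_number_emphasis": sum(c / d ** 2 for (_, d), c in q.items()) / nq,
        "large_number_emphasis": sum(c * d ** 2 for (_, d), c in q.items()) / nq,
        "number_nonuniformity": sum(c ** 2 for c in by_d.values()) / nq,
        "second_moment": sum(c ** 2 for c in q.values()) / nq ** 2,
        "entropy": _entropy2(np.array(list(q.values())) / nq),
    }


def _valid_2d_centers(mask):
    out = []
    for v in product(*(range(n) for n in mask.shape)):
        if not mask[v]:
            continue
        if all(_in_mask(mask, (v[0] + dx, v[1] + dy, v[2]))
               for dx, dy in OFFSETS_8_2D):
            out.append(v)
    return out


def texture_spectrum_features(levels, mask):
    centers = _valid_2d_centers(mask)
    if not centers:
        return {"max_spectrum": float("nan"), "black_white_symmetry": float("nan")}
    spec = np.zeros(6561)
    for v in centers:
        unit = 0
        for digit, (dx, dy) in enumerate(OFFSETS_8_2D):
            nb = levels[v[0] + dx, v[1] + dy, v[2]]
            e = 0 if nb < levels[v] else (1 if nb == levels[v] else 2)
            unit += e * 3 ** digit
        spec[unit] += 1
    total = spec.sum()
    bws = 1 - sum(abs(spec[j] - spec[6560 - j]) for j in range(6561)) / (2 * total)
    return {"max_spectrum": spec.max() / total, "black_white_symmetry": bws}


def tfc_code(levels, v):
    code = 0
    for (ax, ay), (bx, by) in TFC_PAIRS:
        a = int(levels[v[0] + ax, v[1] + ay, v[2]])
        b = int(levels[v[0] + bx, v[1] + by, v[2]])
        c = int(levels[v])
        d1, d2 = c - a, b - c
        if d1 == 0 and d2 == 0:
            cls = 0
        elif d1 * d2 >= 0:
            cls = 1
        else:
            cls = 2
        code += cls
    return code


def tfc_features(levels, mask):
    centers = _valid_2d_centers(mask)
    if not centers:
        return {k: float("nan") for k in
                ["coarseness", "homogeneity", "mean_convergence", "variance"]}
    codes = [tfc_code(levels, v) for v in centers]
    hist = np.bincount(codes, minlength=9) / len(codes)
    mu = float(np.mean(codes))
    return {
        "coarseness": float((hist ** 2).sum()),
        "homogeneity": float((hist / (1 + np.arange(9))).sum()),
        "mean_convergence": mu,
        "variance": float(np.mean((np.array(codes) - mu) ** 2)),
    }


def tfcc_features(levels, mask):
    keys = ["second_angular_moment", "contrast", "entropy", "homogeneity",
            "intensity", "inverse_difference_moment", "correlation", "variance"]
    centers = _valid_2d_centers(mask)
    if not centers:
        return {k: float("nan") for k in keys}
    codemap = np.zeros(mask.shape, int)
    valid = np.zeros(mask.shape, bool)
    for v in centers:
        codemap[v] = tfc_code(levels, v)
        valid[v] = True
    c = cooccurrence_matrix(codemap, valid, 9, base=0)
    if c.sum() == 0:
        return {k: float("nan") for k in keys}
    h = haralick_features(c / c.sum(), range(9))
    return {k: h[k] for k in keys}
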