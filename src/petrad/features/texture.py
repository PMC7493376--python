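"""Texture-matrix feature families on a quantized lesion.

Nine parent matrices, all built in 3D with 26-voxel connectivity except the
texture-spectrum and texture-feature-coding maps, whose 3x3 neighbourhood is
in-plane (their original 2D definition).  Directional matrices (co-occurrence,
run length, coded co-occurrence) are accumulated over the 13 unique distance-1
offsets of the 26-neighbourhood before normalization, so direction-pooled
features are invariant under in-plane 90-degree rotation.  Only in-mask voxel
pairs/neighbourhoods contribute.  All entropies are in bits (log base 2).

Degenerate lesions (single voxel, too thin for a 3x3 neighbourhood) yield NaN
for the affected features, with the reason logged.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from ..volume import STRUCT_26
from .quantize import QuantizedLesion

log = logging.getLogger(__name__)

#: The 13 unique distance-1 offsets of the 26-neighbourhood.
OFFSETS_13: list[tuple[int, int, int]] = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]

#: In-plane 8-neighbour offsets, clockwise; digit i has weight 3**i.
OFFSETS_8_2D: list[tuple[int, int]] = [
    (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1),
]

#: Opposite-neighbour pairs (a, b) through the centre, for gradient coding.
TFC_PAIRS: list[tuple[tuple[int, int], tuple[int, int]]] = [
    ((-1, 0), (1, 0)), ((0, -1), (0, 1)), ((-1, -1), (1, 1)), ((-1, 1), (1, -1)),
]


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p, dtype=np.float64)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _offset_pairs(grid: np.ndarray, mask: np.ndarray, offset) -> tuple[np.ndarray, np.ndarray]:
    """Values of (source, destination) for every in-mask voxel pair at offset."""
    src, dst = [], []
    for d, n in zip(offset, grid.shape):
        if d >= 0:
            src.append(slice(0, n - d))
            dst.append(slice(d, n))
        else:
            src.append(slice(-d, n))
            dst.append(slice(0, n + d))
    both = mask[tuple(src)] & mask[tuple(dst)]
    return grid[tuple(src)][both], grid[tuple(dst)][both]


def _cooccurrence_counts(grid: np.ndarray, mask: np.ndarray, n_levels: int,
                         base: int = 1) -> np.ndarray:
    """Symmetric co-occurrence counts pooled over the 13 offsets.

    ``base`` is the smallest level value (1 for quantized grids, 0 for coded
    maps)."""
    c = np.zeros((n_levels, n_levels), dtype=np.float64)
    for off in OFFSETS_13:
        a, b = _offset_pairs(grid, mask, off)
        if a.size:
            np.add.at(c, (a - base, b - base), 1.0)
            np.add.at(c, (b - base, a - base), 1.0)
    return c


def _haralick(p: np.ndarray, level_values: np.ndarray) -> dict[str, float]:
    """The co-occurrence indices shared by several families.

    ``p`` must sum to 1; ``level_values`` are the grey values attached to the
    matrix rows/columns."""
    i = level_values[:, None].astype(np.float64)
    j = level_values[None, :].astype(np.float64)
    diff = np.abs(i - j)
    out = {
        "second_angular_moment": float((p ** 2).sum()),
        "contrast": float((p * (i - j) ** 2).sum()),
        "entropy": float(-_xlog2(p).sum()),
        "homogeneity": float((p / (1.0 + diff)).sum()),
        "dissimilarity": float((p * diff).sum()),
        "inverse_difference_moment": float((p / (1.0 + (i - j) ** 2)).sum()),
    }
    mu = float((i * p).sum())
    var = float(((i - mu) ** 2 * p).sum())
    if var > 0:
        out["correlation"] = float(((i - mu) * (j - mu) * p).sum() / var)
    else:
        out["correlation"] = 0.0
        log.info("co-occurrence correlation undefined (zero variance); set to 0")
    out["intensity"] = float((p * (i + j) / 2.0).sum())
    out["variance"] = float((p * ((i - mu) ** 2 + (j - mu) ** 2) / 2.0).sum())
    return out


# ---------------------------------------------------------------------------
# 1. Co-occurrence matrix (7) and 5. normalized co-occurrence matrix (6)
# ---------------------------------------------------------------------------

def cooccurrence_features(q: QuantizedLesion) -> dict[str, float]:
    """Haralick indices of the pooled symmetric grey-level co-occurrence matrix."""
    names = ["second_angular_moment", "contrast", "entropy", "homogeneity",
             "dissimilarity", "inverse_difference_moment", "correlation"]
    c = _cooccurrence_counts(q.levels, q.mask, q.n_levels)
    if c.sum() == 0:
        log.info("co-occurrence features NaN: lesion has no voxel pairs")
        return {k: float("nan") for k in names}
    h = _haralick(c / c.sum(), np.arange(1, q.n_levels + 1))
    return {k: h[k] for k in names}


def normalized_cooccurrence_features(q: QuantizedLesion) -> dict[str, float]:
    """Same indices (minus correlation, plus nothing) on the row-normalized
    co-occurrence form: each nonzero row is scaled to unit sum, then the whole
    matrix to unit sum, de-emphasizing dominant grey levels."""
    names = ["second_angular_moment", "contrast", "entropy", "homogeneity",
             "inverse_difference_moment", "dissimilarity"]
    c = _cooccurrence_counts(q.levels, q.mask, q.n_levels)
    if c.sum() == 0:
        log.info("normalized co-occurrence features NaN: lesion has no voxel pairs")
        return {k: float("nan") for k in names}
    rows = c.sum(axis=1)
    nz = rows > 0
    p = np.zeros_like(c)
    p[nz] = c[nz] / rows[nz, None]
    p /= p.sum()
    h = _haralick(p, np.arange(1, q.n_levels + 1))
    return {k: h[k] for k in names}


# ---------------------------------------------------------------------------
# 2. Voxel-alignment (run-length) matrix (11)
# ---------------------------------------------------------------------------

def _run_length_matrix(q: QuantizedLesion, offsets=None) -> tuple[np.ndarray, int]:
    """Counts R[level-1, length-1] of maximal collinear same-level in-mask runs,
    pooled over the given directions (default: all 13).
    Returns (matrix, n_directions)."""
    offsets = offsets if offsets is not None else OFFSETS_13
    lv, m = q.levels, q.mask
    shape = lv.shape
    max_len = int(max(shape))
    r = np.zeros((q.n_levels, max_len), dtype=np.float64)
    coords = np.argwhere(m)
    for off in offsets:
        d = np.array(off)
        # run starts: in-mask voxels whose predecessor is outside mask/grid
        # or has a different level
        prev = coords - d
        ok_prev = np.all((prev >= 0) & (prev < shape), axis=1)
        starts = np.ones(len(coords), dtype=bool)
        pv = prev[ok_prev]
        same_prev = m[pv[:, 0], pv[:, 1], pv[:, 2]] & (
            lv[pv[:, 0], pv[:, 1], pv[:, 2]] == lv[coords[ok_prev, 0],
                                                    coords[ok_prev, 1],
                                                    coords[ok_prev, 2]]
        )
        starts[ok_prev] = ~same_prev
        for c in coords[starts]:
            level = lv[c[0], c[1], c[2]]
            length = 1
            nxt = c + d
            while (np.all(nxt >= 0) and np.all(nxt < shape)
                   and m[nxt[0], nxt[1], nxt[2]]
                   and lv[nxt[0], nxt[1], nxt[2]] == level):
                length += 1
                nxt = nxt + d
            r[level - 1, length - 1] += 1.0
    return r, len(offsets)


def _emphasis_features(mat: np.ndarray, n_voxels: int, denom_count: int,
                       prefix_run: str) -> dict[str, float]:
    """The 11 shared run-length / size-zone index forms.

    ``mat[i-1, s-1]`` counts runs (zones) of level i and length (size) s;
    ``denom_count`` is voxels * directions for runs, voxels for zones."""
    n = mat.sum()
    i = np.arange(1, mat.shape[0] + 1, dtype=np.float64)[:, None]
    s = np.arange(1, mat.shape[1] + 1, dtype=np.float64)[None, :]
    short = f"short_{prefix_run}"
    long_ = ("long" if prefix_run == "run" else "large") + f"_{prefix_run}"
    return {
        f"{short}_emphasis": float((mat / s ** 2).sum() / n),
        f"{long_}_emphasis": float((mat * s ** 2).sum() / n),
        "intensity_variability": float((mat.sum(axis=1) ** 2).sum() / n),
        ("run_length_variability" if prefix_run == "run" else "size_zone_variability"):
            float((mat.sum(axis=0) ** 2).sum() / n),
        (f"{prefix_run}_percentage"): float(n / denom_count),
        f"low_intensity_{prefix_run}_emphasis": float((mat / i ** 2).sum() / n),
        f"high_intensity_{prefix_run}_emphasis": float((mat * i ** 2).sum() / n),
        f"low_intensity_{short}_emphasis": float((mat / (i ** 2 * s ** 2)).sum() / n),
        f"high_intensity_{short}_emphasis": float((mat * i ** 2 / s ** 2).sum() / n),
        f"low_intensity_{long_}_emphasis": float((mat * s ** 2 / i ** 2).sum() / n),
        f"high_intensity_{long_}_emphasis": float((mat * i ** 2 * s ** 2).sum() / n),
    }


def voxel_alignment_features(q: QuantizedLesion, offsets=None) -> dict[str, float]:
    """Run-length (grey-level run) indices; a run is a maximal set of
    consecutive collinear in-mask voxels sharing a grey level.  ``offsets``
    restricts the pooled directions (e.g. a single axis for 1D profiles)."""
    mat, ndir = _run_length_matrix(q, offsets)
    nvox = int(q.mask.sum())
    return _emphasis_features(mat, nvox, nvox * ndir, "run")


# ---------------------------------------------------------------------------
# 4. Intensity size-zone matrix (11)
# ---------------------------------------------------------------------------

def size_zone_features(q: QuantizedLesion) -> dict[str, float]:
    """Size-zone indices; a zone is a 26-connected same-level component."""
    lv, m = q.levels, q.mask
    nvox = int(m.sum())
    mat = np.zeros((q.n_levels, nvox), dtype=np.float64)
    for level in np.unique(lv[m]):
        lab, ncomp = ndimage.label((lv == level) & m, structure=STRUCT_26)
        if ncomp:
            sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, ncomp + 1))
            for sz in sizes:
                mat[level - 1, int(sz) - 1] += 1.0
    feats = _emphasis_features(mat, nvox, nvox, "zone")
    return feats


# ---------------------------------------------------------------------------
# 3. Neighbourhood intensity-difference matrix (5, Amadasun-King)
# ---------------------------------------------------------------------------

NGTDM_EPS = 1e-6
NGTDM_COARSENESS_CAP = 1e6


def nid_features(q: QuantizedLesion) -> dict[str, float]:
    """Coarseness, contrast, busyness, complexity and strength from the
    neighbourhood grey-tone difference matrix (26-neighbour in-mask means)."""
    lv, m = q.levels, q.mask
    kern = np.ones((3, 3, 3), dtype=np.float64)
    kern[1, 1, 1] = 0.0
    nb_sum = ndimage.correlate(np.where(m, lv, 0).astype(np.float64), kern, mode="constant")
    nb_cnt = ndimage.correlate(m.astype(np.float64), kern, mode="constant")
    valid = m & (nb_cnt > 0)
    nvox = int(valid.sum())
    if nvox == 0:
        log.info("NGTDM features NaN: no voxel has an in-mask neighbour")
        return {k: float("nan") for k in
                ["coarseness", "contrast", "busyness", "complexity", "strength"]}
    abar = nb_sum[valid] / nb_cnt[valid]
    levels = lv[valid].astype(np.float64)

    L = q.n_levels
    s = np.zeros(L + 1)
    n_i = np.zeros(L + 1)
    np.add.at(s, lv[valid], np.abs(levels - abar))
    np.add.at(n_i, lv[valid], 1.0)
    p = n_i / nvox
    present = np.nonzero(p > 0)[0]
    ngr = len(present)
    ivals = present.astype(np.float64)

    coarseness = min(1.0 / (NGTDM_EPS + float((p * s).sum())), NGTDM_COARSENESS_CAP)

    if ngr > 1:
        pi = p[present][:, None]
        pj = p[present][None, :]
        di = ivals[:, None] - ivals[None, :]
        contrast = float((pi * pj * di ** 2).sum() / (ngr * (ngr - 1))) * float(s.sum() / nvox)
        denom = float(np.abs(ivals[:, None] * pi - ivals[None, :] * pj).sum())
        busyness = float((p * s).sum() / denom) if denom > 0 else 0.0
        si = s[present][:, None]
        sj = s[present][None, :]
        complexity = float((np.abs(di) * (pi * si + pj * sj) / (nvox * (pi + pj))).sum())
        strength = float(((pi + pj) * di ** 2).sum() / (NGTDM_EPS + s.sum()))
    else:
        contrast = busyness = complexity = strength = 0.0
    return {"coarseness": coarseness, "contrast": contrast, "busyness": busyness,
            "complexity": complexity, "strength": strength}


# ---------------------------------------------------------------------------
# 9. Neighbourhood grey-level dependence matrix (5, Sun-Wee)
# ---------------------------------------------------------------------------

def ngld_features(q: QuantizedLesion) -> dict[str, float]:
    """Dependence of each voxel = 1 + number of its 26 in-mask neighbours with
    the same level (tolerance 0); Q[i, d] counts voxels of level i with
    dependence d."""
    lv, m = q.levels, q.mask
    k = np.zeros(lv.shape, dtype=np.int64)
    for off in OFFSETS_13:
        src, dst = [], []
        for d, n in zip(off, lv.shape):
            if d >= 0:
                src.append(slice(0, n - d))
                dst.append(slice(d, n))
            else:
                src.append(slice(-d, n))
                dst.append(slice(0, n + d))
        src, dst = tuple(src), tuple(dst)
        eq = m[src] & m[dst] & (lv[src] == lv[dst])
        k[src] += eq
        k[dst] += eq
    dep = k[m] + 1  # dependence includes the voxel itself
    levels = lv[m]
    nq = dep.size
    qmat = np.zeros((q.n_levels, 28), dtype=np.float64)
    np.add.at(qmat, (levels - 1, dep), 1.0)
    d = np.arange(28, dtype=np.float64)[None, :]
    d[0, 0] = 1.0  # column 0 is always empty; avoid 0/0
    p = qmat / nq
    return {
        "small_number_emphasis": float((qmat / d ** 2).sum() / nq),
        "large_number_emphasis": float((qmat * d ** 2).sum() / nq),
        "number_nonuniformity": float((qmat.sum(axis=0) ** 2).sum() / nq),
        "second_moment": float((qmat ** 2).sum() / nq ** 2),
        "entropy": float(-_xlog2(p).sum()),
    }


# ---------------------------------------------------------------------------
# 6. Texture spectrum (2, He-Wang)
# ---------------------------------------------------------------------------

def _full_neighbourhood_valid(mask: np.ndarray) -> np.ndarray:
    """In-mask voxels whose whole 3x3 in-plane neighbourhood is in-mask."""
    valid = mask.copy()
    for dx, dy in OFFSETS_8_2D:
        shifted = np.zeros_like(mask)
        xs = slice(max(dx, 0), mask.shape[0] + min(dx, 0))
        xd = slice(max(-dx, 0), mask.shape[0] + min(-dx, 0))
        ys = slice(max(dy, 0), mask.shape[1] + min(dy, 0))
        yd = slice(max(-dy, 0), mask.shape[1] + min(-dy, 0))
        shifted[xd, yd, :] = mask[xs, ys, :]
        valid &= shifted
    return valid


def _shift2d(grid: np.ndarray, dx: int, dy: int) -> np.ndarray:
    out = np.zeros_like(grid)
    xs = slice(max(dx, 0), grid.shape[0] + min(dx, 0))
    xd = slice(max(-dx, 0), grid.shape[0] + min(-dx, 0))
    ys = slice(max(dy, 0), grid.shape[1] + min(dy, 0))
    yd = slice(max(-dy, 0), grid.shape[1] + min(-dy, 0))
    out[xd, yd, :] = grid[xs, ys, :]
    return out


def texture_spectrum_features(q: QuantizedLesion) -> dict[str, float]:
    """He-Wang texture units: each valid voxel's 8 in-plane neighbours are
    ternary-coded against the centre (0 below, 1 equal, 2 above) into a unit
    number in [0, 6560].  Max spectrum is the peak relative frequency;
    black-white symmetry compares the spectrum with its intensity-inverted
    mirror (unit n -> 6560 - n)."""
    valid = _full_neighbourhood_valid(q.mask)
    if not valid.any():
        log.info("texture spectrum NaN: lesion thinner than a 3x3 in-plane patch")
        return {"max_spectrum": float("nan"), "black_white_symmetry": float("nan")}
    lv = q.levels
    unit = np.zeros(lv.shape, dtype=np.int64)
    for digit, (dx, dy) in enumerate(OFFSETS_8_2D):
        nb = _shift2d(lv, dx, dy)
        code = np.where(nb < lv, 0, np.where(nb == lv, 1, 2))
        unit += code * 3 ** digit
    spec = np.bincount(unit[valid], minlength=6561).astype(np.float64)
    total = spec.sum()
    bws = 1.0 - float(np.abs(spec - spec[::-1]).sum()) / (2.0 * total)
    return {"max_spectrum": float(spec.max() / total), "black_white_symmetry": bws}


# ---------------------------------------------------------------------------
# 7./8. Texture feature coding (4) and its co-occurrence matrix (8, Horng-style)
# ---------------------------------------------------------------------------

def tfc_code_map(q: QuantizedLesion) -> tuple[np.ndarray, np.ndarray]:
    """Gradient-class code of each voxel from its 3x3 in-plane neighbourhood.

    Along each of the 4 opposite-neighbour pairs (a, c, b) the two first
    differences d1 = c - a, d2 = b - c are classed 0 (both zero: flat),
    1 (monotone: same sign or one zero) or 2 (convex/concave: opposite signs);
    the voxel code is the sum of the 4 classes (0..8), a total
    gradient-variation score.  Codes depend only on level differences and not
    on pair order, so the map is unchanged by a uniform level shift and by
    in-plane 90-degree rotation.  Returns (code map, valid-voxel mask)."""
    valid = _full_neighbourhood_valid(q.mask)
    lv = q.levels.astype(np.int64)
    code = np.zeros(lv.shape, dtype=np.int64)
    for (ax, ay), (bx, by) in TFC_PAIRS:
        a = _shift2d(lv, ax, ay)
        b = _shift2d(lv, bx, by)
        d1 = lv - a
        d2 = b - lv
        cls = np.where((d1 == 0) & (d2 == 0), 0, np.where(d1 * d2 >= 0, 1, 2))
        code += cls
    return code, valid


def tfc_features(q: QuantizedLesion) -> dict[str, float]:
    """First-level indices of the coded-map histogram p(c):
    coarseness = sum p^2 (few codes dominate a coarse texture),
    homogeneity = sum p/(1+c) (maximal when everything is flat-coded),
    mean convergence = mean code value, variance = code variance."""
    names = ["coarseness", "homogeneity", "mean_convergence", "variance"]
    code, valid = tfc_code_map(q)
    if not valid.any():
        log.info("TFC features NaN: lesion thinner than a 3x3 in-plane patch")
        return {k: float("nan") for k in names}
    c = code[valid].astype(np.float64)
    hist = np.bincount(code[valid], minlength=9).astype(np.float64)
    p = hist / hist.sum()
    cvals = np.arange(9, dtype=np.float64)
    mu = float(c.mean())
    return {
        "coarseness": float((p ** 2).sum()),
        "homogeneity": float((p / (1.0 + cvals)).sum()),
        "mean_convergence": mu,
        "variance": float(((c - mu) ** 2).mean()),
    }


def tfcc_features(q: QuantizedLesion) -> dict[str, float]:
    """Co-occurrence indices on the coded map (codes as grey values), pooled
    over the 13 offsets between valid-coded voxels."""
    names = ["second_angular_moment", "contrast", "entropy", "homogeneity",
             "intensity", "inverse_difference_moment", "correlation", "variance"]
    code, valid = tfc_code_map(q)
    if not valid.any():
        log.info("TFC co-occurrence NaN: lesion thinner than a 3x3 in-plane patch")
        return {k: float("nan") for k in names}
    c = _cooccurrence_counts(code, valid, 9, base=0)
    if c.sum() == 0:
        log.info("TFC co-occurrence NaN: no valid voxel pairs")
        return {k: float("nan") for k in names}
    h = _haralick(c / c.sum(), np.arange(9))
    return {k: h[k] for k in names}
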