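"""Fully automatic biological-target-volume delineation.

The pipeline is seeded at the global SUV maximum: a 26-connected region
growing from that voxel gives a rough in-plane estimate of the lesion, which
a localized region-based active contour (level set with a local Chan–Vese /
uniform-modelling energy) then refines slice by slice.  Each refined slice
initializes its superior and inferior neighbours, and propagation in a
direction stops when a disease-free slice is reached — a criterion driven
purely by image statistics, since the contour itself has no notion of whether
tumour is present.  Lesions are delineated one at a time in decreasing order
of their SUV maximum, excluding previously segmented voxels from the seed
search, until the next candidate falls below the SUV stop threshold
(default 2 g/ml, below which uptake is not considered malignant).

Everything here is deterministic: identical inputs give identical masks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .volume import BtvMask, SuvVolume, STRUCT_26

log = logging.getLogger(__name__)


class SeedsExhaustedError(RuntimeError):
    """Every voxel is excluded from the seed search."""


class SegmentationFailedError(RuntimeError):
    """The contour on the seed slice vanished."""


class BorderWarning(UserWarning):
    """Lesion estimate touches the volume border (possible truncation)."""


@dataclass
class SeedPoint:
    index: tuple[int, int, int]
    suv_value: float


@dataclass
class InitialRoi:
    """Rough in-plane lesion estimate from region growing."""

    slice_index: int
    region: np.ndarray          # 2D bool, (x, y)
    bbox: tuple[int, int, int, int]  # (x0, x1, y0, y1), margin included
    region3d: Optional[np.ndarray] = None
    border_warning: bool = False


@dataclass
class LacParams:
    """Localized active contour tuning knobs.

    local_radius_mm: ball over which interior/exterior means are compared.
    curvature_weight: strength of the smoothing (curve-shortening) term.
    convergence_tol: fraction of narrow-band voxels allowed to change state
    over a 10-iteration window before the contour counts as converged.
    """

    local_radius_mm: float = 5.0
    curvature_weight: float = 0.2
    max_iterations: int = 300
    convergence_tol: float = 0.005
    narrow_band: int = 3
    dt: float = 0.45
    region_grow_fraction: float = 0.4
    background_factor: float = 1.5
    relative_stop_fraction: float = 0.4
    min_slice_area_vox: int = 2

    def __post_init__(self) -> None:
        if self.local_radius_mm <= 0:
            raise ValueError("local radius must be positive")
        if self.curvature_weight < 0:
            raise ValueError("curvature weight must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class LesionSet:
    """Segmented lesions ordered by descending SUV_max; the first contains
    the global maximum."""

    masks: list[BtvMask] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.masks)

    def __iter__(self):
        return iter(self.masks)


# ---------------------------------------------------------------------------
# Seeding and region growing
# ---------------------------------------------------------------------------

def find_global_seed(vol: SuvVolume, exclusion: Optional[np.ndarray] = None) -> SeedPoint:
    """Voxel of maximum SUV outside ``exclusion``; ties break at the lowest
    linear (C-order) index, so the result is deterministic."""
    v = vol.voxels
    if exclusion is not None:
        if exclusion.shape != v.shape:
            raise ValueError("exclusion mask geometry mismatch")
        if exclusion.all():
            raise SeedsExhaustedError("all voxels excluded from seed search")
        v = np.where(exclusion, -np.inf, v)
    flat = int(np.argmax(v))  # argmax returns the first (lowest linear) maximum
    idx = np.unravel_index(flat, v.shape)
    return SeedPoint(tuple(int(i) for i in idx), float(vol.voxels[idx]))


def region_grow(vol: SuvVolume, seed: SeedPoint,
                threshold_fraction: float = 0.4) -> InitialRoi:
    """26-connected region >= ``threshold_fraction`` * seed SUV containing the
    seed.  Restricted to the seed slice for the returned 2D region; the
    bounding box is dilated by a 2-voxel margin."""
    if not (0 < threshold_fraction < 1):
        raise ValueError("threshold_fraction must be in (0, 1)")
    v = vol.voxels
    thr = threshold_fraction * seed.suv_value
    above = v >= thr
    lab, _ = ndimage.label(above, structure=STRUCT_26)
    comp = lab == lab[seed.index]
    border = (
        comp[0].any() or comp[-1].any() or comp[:, 0].any() or comp[:, -1].any()
        or comp[:, :, 0].any() or comp[:, :, -1].any()
    )
    if border:
        warnings.warn("initial region touches the volume border; lesion may be truncated",
                      BorderWarning, stacklevel=2)

    k = seed.index[2]
    plane = comp[:, :, k]
    lab2, _ = ndimage.label(plane, structure=np.ones((3, 3), bool))
    region = lab2 == lab2[seed.index[0], seed.index[1]]
    xs, ys = np.nonzero(region)
    x0 = max(int(xs.min()) - 2, 0)
    x1 = min(int(xs.max()) + 3, plane.shape[0])
    y0 = max(int(ys.min()) - 2, 0)
    y1 = min(int(ys.max()) + 3, plane.shape[1])
    return InitialRoi(k, region, (x0, x1, y0, y1), region3d=comp, border_warning=border)


# ---------------------------------------------------------------------------
# Localized active contour (2D slice refinement)
# ---------------------------------------------------------------------------

def _disk_kernel(radius_vox_x: float, radius_vox_y: float) -> np.ndarray:
    rx = max(int(np.floor(radius_vox_x)), 1)
    ry = max(int(np.floor(radius_vox_y)), 1)
    x = np.arange(-rx, rx + 1)
    y = np.arange(-ry, ry + 1)
    d = (x[:, None] / radius_vox_x) ** 2 + (y[None, :] / radius_vox_y) ** 2
    return (d <= 1.0).astype(np.float32)


def _signed_distance(mask: np.ndarray) -> np.ndarray:
    """Signed distance, positive outside, negative inside (voxel units)."""
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    return (outside - inside).astype(np.float32)


def _curvature(phi: np.ndarray) -> np.ndarray:
    px, py = np.gradient(phi)
    pxx = np.gradient(px, axis=0)
    pyy = np.gradient(py, axis=1)
    pxy = np.gradient(px, axis=1)
    denom = (px ** 2 + py ** 2) ** 1.5 + 1e-8
    kappa = (pxx * py ** 2 - 2.0 * px * py * pxy + pyy * px ** 2) / denom
    return np.clip(kappa, -1.0, 1.0)


def lac_refine_slice(slice2d: np.ndarray, init: np.ndarray, params: LacParams,
                     spacing2d: tuple[float, float] = (1.0, 1.0)) -> np.ndarray:
    """Refine a 2D initialization with a localized uniform-modelling level set.

    At each contour point the energy compares the mean image value inside and
    outside the curve within a disk of ``local_radius_mm``; the curve moves to
    separate those local means, with curve-shortening regularization.  Returns
    the interior mask (possibly empty if the contour collapsed).
    """
    img = np.asarray(slice2d, dtype=np.float32)
    init = np.asarray(init, dtype=bool)
    if not init.any():
        raise ValueError("initialization mask is empty")

    kernel = _disk_kernel(params.local_radius_mm / spacing2d[0],
                          params.local_radius_mm / spacing2d[1])

    # work inside a padded bounding box for speed
    pad = kernel.shape[0] + params.narrow_band + 2
    xs, ys = np.nonzero(init)
    x0 = max(int(xs.min()) - pad, 0)
    x1 = min(int(xs.max()) + pad + 1, img.shape[0])
    y0 = max(int(ys.min()) - pad, 0)
    y1 = min(int(ys.max()) + pad + 1, img.shape[1])
    sub = img[x0:x1, y0:y1]
    phi = _signed_distance(init[x0:x1, y0:y1])

    history: list[np.ndarray] = []
    stable_streak = 0
    for it in range(params.max_iterations):
        inside = phi <= 0
        if not inside.any():
            return np.zeros_like(init)
        outside = ~inside
        a_in = ndimage.correlate(inside.astype(np.float32), kernel, mode="constant")
        s_in = ndimage.correlate(np.where(inside, sub, 0.0), kernel, mode="constant")
        a_out = ndimage.correlate(outside.astype(np.float32), kernel, mode="constant")
        s_out = ndimage.correlate(np.where(outside, sub, 0.0), kernel, mode="constant")
        u = s_in / (a_in + 1e-8)
        v = s_out / (a_out + 1e-8)
        force = (sub - u) ** 2 - (sub - v) ** 2

        band = np.abs(phi) <= params.narrow_band
        fmax = np.abs(force[band]).max() if band.any() else 0.0
        dphi = force / (fmax + 1e-8) + params.curvature_weight * _curvature(phi)
        phi = phi + np.where(band, params.dt * dphi, 0.0).astype(np.float32)

        if (it + 1) % 20 == 0:
            phi = _signed_distance(phi <= 0)

        history.append(phi <= 0)
        if len(history) > 10:
            old = history.pop(0)
            nband = max(int(band.sum()), 1)
            changed = int(np.count_nonzero(history[-1] ^ old))
            if changed <= params.convergence_tol * nband:
                stable_streak += 1
                if stable_streak >= 10:
                    break
            else:
                stable_streak = 0

    out = np.zeros_like(init)
    out[x0:x1, y0:y1] = phi <= 0
    if out.any():
        # keep the component overlapping (or nearest to) the initialization
        lab, n = ndimage.label(out, structure=np.ones((3, 3), bool))
        if n > 1:
            overlaps = ndimage.sum_labels(init.astype(np.int64), lab, index=range(1, n + 1))
            best = int(np.argmax(overlaps)) + 1
            if overlaps.max() == 0:
                sizes = ndimage.sum_labels(np.ones_like(out, np.int64), lab,
                                           index=range(1, n + 1))
                best = int(np.argmax(sizes)) + 1
            out = lab == best
    return out


# ---------------------------------------------------------------------------
# Single-lesion and multi-lesion segmentation
# ---------------------------------------------------------------------------

def _slice_background(plane: np.ndarray, bbox) -> float:
    """Background estimate: median SUV of the slice outside the dilated
    initialization box."""
    x0, x1, y0, y1 = bbox
    m = np.ones(plane.shape, bool)
    m[x0:x1, y0:y1] = False
    if not m.any():
        return float(np.median(plane))
    return float(np.median(plane[m]))


def _disease_free(plane: np.ndarray, mask2d: np.ndarray, bbox, params: LacParams,
                  seed_suv: float) -> bool:
    """A slice is disease-free when the refined contour vanished, is tiny, or
    its interior is not convincingly hotter than the slice background.

    Two intensity tests are ORed: an absolute floor (mean below
    ``background_factor`` x the background median) and a lesion-relative one
    (mean below background + ``relative_stop_fraction`` of the
    background-corrected seed SUV) — residual blur from a neighbouring
    diseased slice scales with lesion brightness, so an absolute multiple of
    the background alone cannot separate tail from tumour at high contrast."""
    if not mask2d.any():
        return True
    if int(mask2d.sum()) < params.min_slice_area_vox:
        return True
    bg = _slice_background(plane, bbox)
    mean_in = float(plane[mask2d].mean())
    if mean_in < params.background_factor * bg:
        return True
    return mean_in < bg + params.relative_stop_fraction * (seed_suv - bg)


def segment_lesion(vol: SuvVolume, seed: SeedPoint,
                   params: Optional[LacParams] = None) -> BtvMask:
    """Delineate the lesion around ``seed``.

    The seed slice is refined from the region-growing estimate; each refined
    slice (dilated by 1 voxel) initializes its neighbour, superiorly then
    inferiorly, until a disease-free slice is reached.
    """
    params = params or LacParams()
    roi = region_grow(vol, seed, params.region_grow_fraction)
    v = vol.voxels
    nz = v.shape[2]
    spacing2d = (vol.spacing[0], vol.spacing[1])
    k0 = roi.slice_index

    per_slice: dict[int, np.ndarray] = {}
    seed_mask = lac_refine_slice(v[:, :, k0], roi.region, params, spacing2d)
    if not seed_mask.any():
        raise SegmentationFailedError("contour vanished on the seed slice")
    per_slice[k0] = seed_mask

    for direction in (+1, -1):
        prev = seed_mask
        k = k0 + direction
        while 0 <= k < nz:
            init = ndimage.binary_dilation(prev, structure=np.ones((3, 3), bool))
            refined = lac_refine_slice(v[:, :, k], init, params, spacing2d)
            if _disease_free(v[:, :, k], refined, roi.bbox, params, seed.suv_value):
                break
            per_slice[k] = refined
            prev = refined
            k += direction

    mask3d = np.zeros(v.shape, bool)
    for k, m in per_slice.items():
        mask3d[:, :, k] = m
    lab, n = ndimage.label(mask3d, structure=STRUCT_26)
    comp = lab == lab[seed.index]
    if not comp[seed.index]:
        # seed sits just outside the refined contour: keep the largest
        # component on the seed slice instead
        sizes = ndimage.sum_labels(np.ones(v.shape, np.int64), lab, index=range(1, n + 1))
        comp = lab == (int(np.argmax(sizes)) + 1)

    warns = []
    if roi.border_warning:
        warns.append("lesion touches the volume border; mask may be truncated")
    return BtvMask(comp, vol.spacing, vol.origin,
                   suv_max=float(v[comp].max()), warnings=warns)


def segment_all(vol: SuvVolume, params: Optional[LacParams] = None,
                suv_stop: float = 2.0, max_lesions: int = 20,
                interactive: bool = False) -> LesionSet:
    """Iterative multi-lesion loop.

    Repeatedly seeds at the highest remaining SUV (excluding already-segmented
    voxels, dilated by 1), segments, and stops when the candidate seed falls
    below ``suv_stop`` g/ml.  Emits a warning entry when more than one lesion
    is found (healthy foci above threshold are possible false positives).
    """
    params = params or LacParams()
    result = LesionSet()
    exclusion = np.zeros(vol.shape, bool)
    for lesion_id in range(max_lesions):
        try:
            seed = find_global_seed(vol, exclusion if exclusion.any() else None)
        except SeedsExhaustedError:
            break
        if seed.suv_value < suv_stop:
            break
        try:
            mask = segment_lesion(vol, seed, params)
        except SegmentationFailedError as exc:
            result.warnings.append(f"lesion {lesion_id}: {exc}")
            exclusion[seed.index] = True
            continue
        # enforce disjointness against earlier (higher-uptake) lesions
        vox = mask.voxels & ~exclusion
        if not vox.any():
            exclusion[seed.index] = True
            continue
        lab, n = ndimage.label(vox, structure=STRUCT_26)
        if n > 1:
            comp = lab[seed.index]
            if comp == 0:
                sizes = ndimage.sum_labels(np.ones(vox.shape, np.int64), lab,
                                           index=range(1, n + 1))
                comp = int(np.argmax(sizes)) + 1
            vox = lab == comp
        mask = BtvMask(vox, vol.spacing, vol.origin, lesion_id=lesion_id,
                       suv_max=float(vol.voxels[vox].max()), warnings=mask.warnings)
        result.masks.append(mask)
        exclusion |= ndimage.binary_dilation(vox, structure=STRUCT_26)

    result.masks.sort(key=lambda m: -m.suv_max)
    for i, m in enumerate(result.masks):
        m.lesion_id = i
    if len(result.masks) > 1:
        msg = (f"multiple lesions segmented (n={len(result.masks)}); review for "
               f"false positives (healthy tissue with SUVmax > {suv_stop} g/ml)")
        result.warnings.append(msg)
        if interactive:
            log.warning(msg)
    return result
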