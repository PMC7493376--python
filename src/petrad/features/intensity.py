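"""First-order SUV indices (49 per lesion).

Statistics of the in-mask SUV distribution, metabolic volume and TLG/TLP,
histogram entropy, SULpeak, mesh surface area, asphericity, surface-restricted
SUV statistics in four surface definitions, and the eight product features.

Surface-definition variants (recorded here because no standard fixes them):

1. mask voxels with a 6-connected (face) background neighbour;
2. mask voxels lost under erosion with the 18-connected structuring element;
3. mask voxels lost under erosion with the 26-connected structuring element;
4. voxels traversed by the marching-cubes isosurface (vertex positions
   snapped to the nearest voxel).

Asphericity A = (S^3 / (36 pi V^2))^(1/3) - 1 (0 for a perfect sphere) with
three surface estimates: (1) summed exposed-face area, (2) marching-cubes
mesh area, (3) 26-connected surface-voxel count times the mean face area.
The mesh is extracted from a lightly Gaussian-smoothed (sigma = 1 mm,
isotropic) mask, which removes the staircase bias a binary isosurface carries.
Product features use the mesh surface area and asphericity 2.

Skewness and kurtosis (kurtosis is the non-excess, Pearson form) of a
zero-variance lesion are defined as 0 so constant phantoms stay usable.
Entropies are in bits.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage, signal, stats
from skimage import measure

from ..volume import BtvMask, SuvVolume
from .quantize import quantize_values

log = logging.getLogger(__name__)

PEAK_SPHERE_VOLUME_ML = 1.0


def _entropy_bits(levels_1d: np.ndarray, n_levels: int = 64) -> float:
    hist = np.bincount(levels_1d, minlength=n_levels + 1)[1:]
    p = hist / hist.sum()
    nz = p > 0
    return float(-(p[nz] * np.log2(p[nz])).sum())


def _skew_kurt(vals: np.ndarray) -> tuple[float, float, float, float]:
    """(skewness, kurtosis, skewness bias-corrected, kurtosis bias-corrected)."""
    n = vals.size
    m2 = float(np.var(vals))
    if m2 <= 0:
        log.info("zero-variance lesion: skewness/kurtosis set to 0")
        return 0.0, 0.0, 0.0, 0.0
    skew = float(stats.skew(vals, bias=True))
    kurt = float(stats.kurtosis(vals, fisher=False, bias=True))
    if n > 3:
        skew_bc = float(stats.skew(vals, bias=False))
        kurt_bc = float(stats.kurtosis(vals, fisher=False, bias=False))
    else:
        skew_bc, kurt_bc = skew, kurt
    return skew, kurt, skew_bc, kurt_bc


def sul_peak(sul_vol: SuvVolume, mask: BtvMask,
             sphere_volume_ml: float = PEAK_SPHERE_VOLUME_ML) -> float:
    """Maximal mean SUL in a 1 ml sphere centred on an in-mask voxel.

    The sphere may extend beyond the mask (PERCIST convention) but is clipped
    to the grid; the mean uses the in-grid part."""
    radius_mm = (3.0 * sphere_volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    r_vox = [radius_mm / s for s in sul_vol.spacing]
    half = [max(int(np.floor(r)), 0) for r in r_vox]
    grids = np.meshgrid(*[np.arange(-h, h + 1) for h in half], indexing="ij")
    dist = sum((g / r) ** 2 for g, r in zip(grids, r_vox))
    kernel = (dist <= 1.0).astype(np.float64)
    v = sul_vol.voxels.astype(np.float64)
    sums = signal.fftconvolve(v, kernel, mode="same")
    counts = signal.fftconvolve(np.ones_like(v), kernel, mode="same")
    means = sums / np.maximum(counts, 1.0)
    return float(means[mask.voxels].max())


def _surface_voxel_sets(mask: np.ndarray) -> dict[int, np.ndarray]:
    out = {}
    for variant, conn in ((1, 1), (2, 2), (3, 3)):
        struct = ndimage.generate_binary_structure(3, conn)
        eroded = ndimage.binary_erosion(mask, structure=struct)
        surf = mask & ~eroded
        out[variant] = surf if surf.any() else mask.copy()
    return out


MESH_SMOOTH_SIGMA_MM = 1.0


def _mesh(mask: np.ndarray, spacing) -> tuple[np.ndarray, np.ndarray] | None:
    """Marching-cubes mesh of the (smoothed, padded) mask; verts in mm
    relative to the unpadded grid.  Smoothing is isotropic in mm (1 mm sigma):
    it removes the staircase-area bias of a binary isosurface without eroding
    anisotropic grids along the slice axis."""
    padded = np.pad(mask.astype(np.float64), 2)
    smoothed = ndimage.gaussian_filter(padded, sigma=[MESH_SMOOTH_SIGMA_MM / s
                                                      for s in spacing])
    field = smoothed if smoothed.max() > 0.5 else padded
    try:
        verts, faces, _, _ = measure.marching_cubes(field, level=0.5, spacing=spacing)
    except (ValueError, RuntimeError):
        return None
    verts = verts - 2.0 * np.asarray(spacing)
    return verts, faces


def _exposed_face_area(mask: np.ndarray, spacing) -> float:
    sx, sy, sz = spacing
    areas = (sy * sz, sx * sz, sx * sy)
    total = 0.0
    for axis, a in enumerate(areas):
        padded = np.pad(mask, [(1, 1) if ax == axis else (0, 0) for ax in range(3)])
        total += a * float(np.abs(np.diff(padded.astype(np.int8), axis=axis)).sum())
    return total


def _asphericity(surface_mm2: float, volume_mm3: float) -> float:
    if volume_mm3 <= 0:
        return float("nan")
    return float((surface_mm2 ** 3 / (36.0 * np.pi * volume_mm3 ** 2)) ** (1.0 / 3.0) - 1.0)


def _surface_stats(vals: np.ndarray, tag: str) -> dict[str, float]:
    mean = float(vals.mean())
    var = float(np.var(vals))
    sd = float(np.sqrt(var))
    ent = _entropy_bits(quantize_values(vals)) if vals.size else float("nan")
    nsr = sd / mean if mean != 0 else float("nan")
    return {
        f"surface_mean_suv_{tag}": mean,
        f"surface_total_suv_{tag}": float(vals.sum()),
        f"surface_suv_entropy_{tag}": ent,
        f"surface_suv_variance_{tag}": var,
        f"surface_suv_sd_{tag}": sd,
        f"surface_suv_nsr_{tag}": nsr,
    }


def suv_indices(vol: SuvVolume, mask: BtvMask,
                sul_vol: SuvVolume | None = None, levels: int = 64) -> dict[str, float]:
    """The 49 first-order indices.  SUL-based values are NaN (logged) when no
    SUL volume is supplied."""
    mask.check_aligned(vol)
    m = mask.voxels
    vals = vol.voxels[m].astype(np.float64)
    n = vals.size
    voxel_ml = vol.voxel_volume_ml
    volume_ml = n * voxel_ml
    volume_mm3 = volume_ml * 1000.0

    mean = float(vals.mean())
    var = float(np.var(vals))
    skew, kurt, skew_bc, kurt_bc = _skew_kurt(vals)
    entropy = _entropy_bits(quantize_values(vals, levels), levels)

    if sul_vol is not None:
        peak = sul_peak(sul_vol, mask)
    else:
        peak = float("nan")
        log.info("no SUL volume supplied: SULpeak and its products are NaN")

    spacing = vol.spacing
    mesh = _mesh(m, spacing)
    if mesh is not None:
        verts, faces = mesh
        surface_mm2 = float(measure.mesh_surface_area(verts, faces))
        vox_idx = np.round(verts / np.asarray(spacing)).astype(int)
        vox_idx = np.clip(vox_idx, 0, np.asarray(m.shape) - 1)
        mc_voxels = np.zeros(m.shape, bool)
        mc_voxels[vox_idx[:, 0], vox_idx[:, 1], vox_idx[:, 2]] = True
        if not (mc_voxels & m).any():
            mc_voxels = m.copy()
    else:
        log.info("marching cubes failed on this mask; mesh features NaN")
        surface_mm2 = float("nan")
        mc_voxels = m.copy()

    surf = _surface_voxel_sets(m)
    face_area = _exposed_face_area(m, spacing)
    mean_face = (spacing[0] * spacing[1] + spacing[1] * spacing[2]
                 + spacing[0] * spacing[2]) / 3.0
    asph1 = _asphericity(face_area, volume_mm3)
    asph2 = _asphericity(surface_mm2, volume_mm3) if np.isfinite(surface_mm2) else float("nan")
    asph3 = _asphericity(float(surf[3].sum()) * mean_face, volume_mm3)

    out: dict[str, float] = {
        "min": float(vals.min()),
        "max": float(vals.max()),
        "mean": mean,
        "variance": var,
        "sd": float(np.sqrt(var)),
        "skewness": skew,
        "kurtosis": kurt,
        "skewness_bias_corrected": skew_bc,
        "kurtosis_bias_corrected": kurt_bc,
        "tlg": mean * volume_ml,
        "volume_ml": volume_ml,
        "entropy": entropy,
        "sul_peak": peak,
        "surface_area_mm2": surface_mm2,
        "asphericity_1": asph1,
        "asphericity_2": asph2,
        "asphericity_3": asph3,
    }
    for variant in (1, 2, 3):
        out.update(_surface_stats(vol.voxels[surf[variant]].astype(np.float64), str(variant)))
    out.update(_surface_stats(vol.voxels[mc_voxels].astype(np.float64), "4"))

    out.update({
        "suv_mean_prod_asphericity": mean * asph2,
        "suv_max_prod_asphericity": out["max"] * asph2,
        "entropy_prod_asphericity": entropy * asph2,
        "sul_peak_prod_asphericity": peak * asph2,
        "suv_mean_prod_surface_area": mean * surface_mm2,
        "suv_max_prod_surface_area": out["max"] * surface_mm2,
        "entropy_prod_surface_area": entropy * surface_mm2,
        "sul_peak_prod_surface_area": peak * surface_mm2,
    })
    return out
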