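"""Grey-level quantization of a lesion for texture-matrix construction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..volume import BtvMask, SuvVolume


@dataclass
class QuantizedLesion:
    """Integer grid with levels 1..n_levels inside the mask, 0 outside.

    Equal-width binning between the in-mask SUV minimum and maximum; the
    maximum maps to the top level, and a constant lesion maps entirely to
    level 1.  Out-of-mask voxels carry the 0 sentinel and are excluded from
    every texture matrix.
    """

    levels: np.ndarray            # int grid, 0 = outside mask
    mask: np.ndarray              # bool grid
    n_levels: int
    suv_min: float
    suv_max: float
    spacing: tuple[float, float, float]


def quantize(vol: SuvVolume, mask: BtvMask, levels: int = 64) -> QuantizedLesion:
    mask.check_aligned(vol)
    m = mask.voxels
    if not m.any():
        raise ValueError("mask is empty")
    vals = vol.voxels[m]
    lo, hi = float(vals.min()), float(vals.max())
    q = np.zeros(vol.shape, dtype=np.int32)
    if hi > lo:
        idx = np.floor((vol.voxels[m] - lo) / (hi - lo) * levels).astype(np.int32) + 1
        q[m] = np.clip(idx, 1, levels)
    else:
        q[m] = 1
    return QuantizedLesion(q, m, levels, lo, hi, vol.spacing)


def quantize_values(vals: np.ndarray, levels: int = 64) -> np.ndarray:
    """Same binning rule applied to a 1D value array (histogram entropies)."""
    vals = np.asarray(vals, dtype=np.float64)
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        return np.ones(vals.shape, dtype=np.int32)
    idx = np.floor((vals - lo) / (hi - lo) * levels).astype(np.int32) + 1
    return np.clip(idx, 1, levels)
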