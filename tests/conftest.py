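from __future__ import annotations

import numpy as np
import pytest

from petrad.features.quantize import QuantizedLesion
from petrad.phantom import sphere_phantom
from petrad.volume import BtvMask, SuvVolume

SPACING = (1.17, 1.17, 3.27)


def make_suv(arr, spacing=SPACING) -> SuvVolume:
    return SuvVolume(np.asarray(arr, dtype=np.float32), spacing)


def make_quantized(levels, mask=None, n_levels=None) -> QuantizedLesion:
    """Build a QuantizedLesion directly from an integer level grid."""
    levels = np.asarray(levels, dtype=np.int32)
    if levels.ndim == 1:
        levels = levels[None, None, :]
    if mask is None:
        mask = levels > 0
    mask = np.asarray(mask, bool)
    lv = np.where(mask, levels, 0)
    n = n_levels or int(lv.max())
    return QuantizedLesion(lv, mask, n, 0.0, float(n), SPACING)


def random_quantized(rng, shape=(5, 5, 3), n_levels=5, p_mask=0.8) -> QuantizedLesion:
    mask = rng.random(shape) < p_mask
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    levels = rng.integers(1, n_levels + 1, size=shape).astype(np.int32)
    return make_quantized(np.where(mask, levels, 0), mask, n_levels)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def standard_phantom():
    """Blurred sphere r=8 mm, SUV 6, background 0.5, FWHM 5 mm, noiseless."""
    return sphere_phantom(radius_mm=8.0, peak_suv=6.0, background=0.5, fwhm_mm=5.0)


@pytest.fixture(scope="session")
def standard_features(standard_phantom):
    from petrad.features import extract_features

    vol, truth = standard_phantom
    return extract_features(vol, truth, sul_vol=vol)
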