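"""Per-lesion radiomics: 49 first-order SUV indices plus 59 texture features
from nine parent matrices on a 64-level quantized grid."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..volume import BtvMask, SuvVolume
from . import texture
from .intensity import suv_indices
from .quantize import QuantizedLesion, quantize
from .registry import FAMILIES, FAMILY_COUNTS, N_FEATURES, N_TEXTURE, feature_names, registry_dict

log = logging.getLogger(__name__)

__all__ = [
    "FeatureVector", "extract_features", "quantize", "QuantizedLesion",
    "suv_indices", "feature_names", "registry_dict", "FAMILIES",
    "FAMILY_COUNTS", "N_FEATURES", "N_TEXTURE", "texture",
]

_TEXTURE_FUNCS = {
    "glcm": texture.cooccurrence_features,
    "rlm": texture.voxel_alignment_features,
    "ngtdm": texture.nid_features,
    "szm": texture.size_zone_features,
    "nglcm": texture.normalized_cooccurrence_features,
    "ts": texture.texture_spectrum_features,
    "tfc": texture.tfc_features,
    "tfcc": texture.tfcc_features,
    "ngldm": texture.ngld_features,
}


@dataclass
class FeatureVector:
    """Exactly 108 named values for one lesion, in registry order."""

    names: list[str]
    values: np.ndarray
    lesion_id: int = 0
    units: str = "mixed"
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.names) != len(self.values):
            raise ValueError("names/values length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names, name=self.lesion_id)


def extract_features(vol: SuvVolume, mask: BtvMask,
                     sul_vol: SuvVolume | None = None,
                     levels: int = 64, lesion_id: int = 0) -> FeatureVector:
    """Compute the full 108-feature vector for one lesion.

    Texture families are computed on the ``levels``-level quantized grid,
    first-order indices directly on the SUV values.  ``sul_vol`` enables the
    SULpeak-based indices; without it they are NaN (logged)."""
    mask.check_aligned(vol)
    q = quantize(vol, mask, levels)
    values: list[float] = []
    names: list[str] = []
    notes: list[str] = []
    for fam, fam_names in FAMILIES:
        if fam == "suv":
            fdict = suv_indices(vol, mask, sul_vol=sul_vol, levels=levels)
        else:
            fdict = _TEXTURE_FUNCS[fam](q)
        for name in fam_names:
            full = f"{fam}_{name}"
            val = float(fdict[name])
            if not np.isfinite(val):
                notes.append(f"{full}: not finite (degenerate lesion or missing input)")
            names.append(full)
            values.append(val)
    assert len(values) == N_FEATURES
    return FeatureVector(names, np.array(values), lesion_id=lesion_id, notes=notes)
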