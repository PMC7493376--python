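"""Synthetic data generators.

Two families of ground-truthed inputs:

* :func:`make_pet_phantom` — 3D brain amino-acid-PET-like phantoms: a low
  uniform background, one or more hyperintense quasi-spherical lesions
  (peak SUV in the 3–10 g/ml range typical of methionine-avid metastases),
  Gaussian scanner blur (PSF FWHM ~5 mm) and voxel noise.  The default grid
  mirrors a clinical brain PET reconstruction (1.17 x 1.17 mm in-plane,
  3.27 mm slices).  Ground truth is the pre-blur lesion indicator, i.e. the
  "true" biological extent against which segmentation accuracy is judged.

* :func:`make_feature_cohort` — labelled lesion-by-feature tables with
  planted class effects and correlated feature blocks, emulating the input
  of the feature-selection and classification stages.

Both are fully deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import BtvMask, SuvVolume

DEFAULT_SPACING = (1.17, 1.17, 3.27)  # mm, clinical brain PET grid
FWHM_TO_SIGMA = 1.0 / 2.3548200450309493  # sigma = FWHM / (2 sqrt(2 ln 2))


@dataclass
class Lesion:
    """One quasi-spherical lesion: center in mm (world, origin at grid corner)."""

    center_mm: tuple[float, float, float]
    radius_mm: float | tuple[float, float, float]
    peak_suv: float
    shape: str = "sphere"  # sphere | ellipsoid

    @property
    def radii_mm(self) -> tuple[float, float, float]:
        r = self.radius_mm
        if np.isscalar(r):
            return (float(r),) * 3
        return tuple(float(v) for v in r)


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (64, 64, 32)
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    background_suv: float = 0.5
    lesions: Sequence[Lesion] = field(default_factory=list)
    psf_fwhm_mm: float = 5.0
    noise: str = "none"          # none | gaussian | poisson-scaled
    noise_sigma: float = 0.0     # gaussian: absolute SUV sigma
    noise_factor: float = 0.0    # poisson-scaled: counts per SUV unit
    seed: int = 0
    supersample: int = 3

    def validate(self) -> None:
        extent = np.asarray(self.shape) * np.asarray(self.spacing)
        for les in self.lesions:
            c, r = np.asarray(les.center_mm), np.asarray(les.radii_mm)
            if np.any(c - r < 0) or np.any(c + r > extent):
                raise ValueError(f"lesion at {les.center_mm} extends outside the grid")
            if les.peak_suv <= self.background_suv:
                raise ValueError("lesion peak SUV must exceed the background")
        if self.psf_fwhm_mm < 0:
            raise ValueError("PSF FWHM must be >= 0")
        for i in range(len(self.lesions)):
            for j in range(i + 1, len(self.lesions)):
                ci = np.asarray(self.lesions[i].center_mm)
                cj = np.asarray(self.lesions[j].center_mm)
                ri = max(self.lesions[i].radii_mm)
                rj = max(self.lesions[j].radii_mm)
                if np.linalg.norm(ci - cj) < ri + rj:
                    raise ValueError(f"lesions {i} and {j} overlap")


def _lesion_fraction(spec: PhantomSpec, les: Lesion) -> np.ndarray:
    """Partial-volume fraction of each native voxel inside the analytic lesion,
    computed on a ``supersample``x finer grid and block-averaged."""
    ss = spec.supersample
    shape = np.asarray(spec.shape)
    spacing = np.asarray(spec.spacing)
    fine_spacing = spacing / ss
    axes = [
        (np.arange(n * ss) + 0.5) * fs for n, fs in zip(shape, fine_spacing)
    ]
    cx, cy, cz = les.center_mm
    rx, ry, rz = les.radii_mm
    gx = ((axes[0] - cx) / rx) ** 2
    gy = ((axes[1] - cy) / ry) ** 2
    gz = ((axes[2] - cz) / rz) ** 2
    inside = (gx[:, None, None] + gy[None, :, None] + gz[None, None, :]) <= 1.0
    frac = inside.reshape(shape[0], ss, shape[1], ss, shape[2], ss).mean(axis=(1, 3, 5))
    return frac.astype(np.float32)


def make_pet_phantom(spec: PhantomSpec) -> tuple[SuvVolume, list[BtvMask]]:
    """Rasterize, blur and corrupt a phantom; return the volume and truth masks.

    Truth masks are the pre-blur indicators (voxel majority inside the
    analytic lesion), ordered as in ``spec.lesions``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    vol = np.full(spec.shape, spec.background_suv, dtype=np.float32)
    masks: list[BtvMask] = []
    for k, les in enumerate(spec.lesions):
        frac = _lesion_fraction(spec, les)
        vol += (les.peak_suv - spec.background_suv) * frac
        truth = frac >= 0.5
        masks.append(BtvMask(truth, spec.spacing, lesion_id=k, suv_max=les.peak_suv))

    if spec.psf_fwhm_mm > 0:
        sigma_vox = [spec.psf_fwhm_mm * FWHM_TO_SIGMA / s for s in spec.spacing]
        vol = ndimage.gaussian_filter(vol, sigma=sigma_vox).astype(np.float32)

    if spec.noise == "gaussian" and spec.noise_sigma > 0:
        vol = vol + rng.normal(0.0, spec.noise_sigma, size=vol.shape).astype(np.float32)
    elif spec.noise == "poisson-scaled" and spec.noise_factor > 0:
        # counts ~ Poisson(SUV * factor); noisy SUV = counts / factor
        vol = (rng.poisson(np.maximum(vol, 0) * spec.noise_factor) / spec.noise_factor)
        vol = vol.astype(np.float32)
    vol = np.maximum(vol, 0.0)
    return SuvVolume(vol, spec.spacing), masks


def sphere_phantom(radius_mm: float = 8.0, peak_suv: float = 6.0,
                   background: float = 0.5, fwhm_mm: float = 5.0,
                   noise_sigma: float = 0.0, seed: int = 0,
                   shape=(64, 64, 32), spacing=DEFAULT_SPACING,
                   center_mm=None) -> tuple[SuvVolume, BtvMask]:
    """Convenience: one centred blurred sphere; returns (volume, truth mask)."""
    if center_mm is None:
        # centre on a voxel centre: keeps the digitized volume unbiased
        center_mm = tuple((n // 2 + 0.5) * s for n, s in zip(shape, spacing))
    spec = PhantomSpec(
        shape=shape, spacing=spacing, background_suv=background,
        lesions=[Lesion(center_mm, radius_mm, peak_suv)],
        psf_fwhm_mm=fwhm_mm,
        noise="gaussian" if noise_sigma > 0 else "none",
        noise_sigma=noise_sigma, seed=seed,
    )
    vol, masks = make_pet_phantom(spec)
    return vol, masks[0]


# ---------------------------------------------------------------------------
# Feature cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Class-conditional Gaussian feature table with planted effects.

    Features are unit-variance Gaussians; informative features differ between
    classes by ``effect_size`` standard deviations.  Correlated blocks share a
    latent factor so that within-block pairwise correlation is ``block_r``.
    """

    n_per_class: tuple[int, int] = (30, 30)
    n_features: int = 108
    informative: dict[int, float] = field(default_factory=dict)  # index -> effect size
    blocks: Sequence[Sequence[int]] = field(default_factory=list)
    block_r: float = 0.95
    seed: int = 0
    feature_names: Optional[Sequence[str]] = None

    def validate(self) -> None:
        if not (0 <= self.block_r < 1):
            raise ValueError("block_r must be in [0, 1)")
        for idx, eff in self.informative.items():
            if not (0 <= idx < self.n_features) or not np.isfinite(eff):
                raise ValueError(f"bad informative feature spec {idx}: {eff}")
        for blk in self.blocks:
            if any(not 0 <= i < self.n_features for i in blk):
                raise ValueError("block index out of range")


@dataclass
class FeatureCohort:
    features: pd.DataFrame        # rows = lesions/patients, columns = features
    labels: pd.Series             # 1 = responder, 0 = non-responder
    informative: dict[int, float]
    blocks: list[list[int]]


def default_feature_names(n: int) -> list[str]:
    """Registry names when n == 108, generic names otherwise."""
    if n == 108:
        from .features.registry import feature_names

        return list(feature_names())
    return [f"feature_{i:03d}" for i in range(n)]


def make_feature_cohort(spec: CohortSpec) -> FeatureCohort:
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n0, n1 = spec.n_per_class
    n = n0 + n1
    p = spec.n_features
    labels = np.r_[np.zeros(n0, dtype=int), np.ones(n1, dtype=int)]

    x = rng.normal(size=(n, p))
    # correlated blocks: shared latent factor, x = sqrt(r) z + sqrt(1-r) eps
    for blk in spec.blocks:
        z = rng.normal(size=n)
        for i in blk:
            x[:, i] = np.sqrt(spec.block_r) * z + np.sqrt(1.0 - spec.block_r) * x[:, i]
    # planted class effects on standardized scale
    for idx, eff in spec.informative.items():
        x[labels == 1, idx] += eff

    names = list(spec.feature_names) if spec.feature_names is not None else default_feature_names(p)
    if len(names) != p:
        raise ValueError("feature_names length mismatch")
    df = pd.DataFrame(x, columns=names)
    return FeatureCohort(df, pd.Series(labels, name="label"),
                         dict(spec.informative), [list(b) for b in spec.blocks])
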