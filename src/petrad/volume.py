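"""PET volume I/O and quantitative-unit conversion.

Volumes are 3D scalar grids with axis order ``(x, y, z)`` (z = slice axis),
0-based voxel indices, per-axis spacing in mm and a world origin taken from
the source header.  Activity concentration is carried in Bq/ml and converted
to the body-weight standardized uptake value (SUV, g/ml) or to SUV normalized
to lean body mass (SUL) on demand.

Decay correction is assumed to have been applied by the scanner, the norm for
reconstructed DICOM PET; :func:`decay_correct` is available when it was not
(11C half-life 20.4 min).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import nibabel as nib
from scipy import ndimage

C11_HALF_LIFE_MIN = 20.4

#: 26-connectivity structuring element used for mask topology checks.
STRUCT_26 = ndimage.generate_binary_structure(3, 3)


class FormatError(ValueError):
    """Input file or series is malformed (missing slices, mixed geometry...)."""


class AlignmentError(ValueError):
    """Two grids that must share geometry do not."""


class MetadataMissingWarning(UserWarning):
    """Dose/weight tags absent; SUV conversion needs explicit parameters."""


def _check_geometry(voxels: np.ndarray, spacing) -> None:
    if voxels.ndim != 3 or min(voxels.shape) < 1:
        raise ValueError(f"expected a 3D grid, got shape {voxels.shape}")
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive values, got {spacing}")


@dataclass
class ActivityVolume:
    """Raw PET grid in activity-concentration units (Bq/ml)."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    injected_dose_mbq: Optional[float] = None
    weight_kg: Optional[float] = None
    injection_time: Optional[str] = None
    acquisition_time: Optional[str] = None
    decay_corrected: bool = True

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        _check_geometry(self.voxels, self.spacing)
        if np.any(self.voxels < 0):
            raise ValueError("activity concentration must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class SuvVolume:
    """3D grid in SUV units (g/ml), or SUL when ``units == "sul"``."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    weight_kg: Optional[float] = None
    injected_dose_mbq: Optional[float] = None
    units: str = "g/ml"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        _check_geometry(self.voxels, self.spacing)
        if not np.all(np.isfinite(self.voxels)) or np.any(self.voxels < 0):
            raise ValueError("SUV values must be finite and non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0


@dataclass
class BtvMask:
    """Binary biological-target-volume mask aligned to a parent volume.

    Nonempty and a single 26-connected component by construction.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    lesion_id: int = 0
    suv_max: Optional[float] = None
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        _check_geometry(self.voxels, self.spacing)
        if not self.voxels.any():
            raise ValueError("BTV mask must be nonempty")
        _, n = ndimage.label(self.voxels, structure=STRUCT_26)
        if n != 1:
            raise ValueError(f"BTV mask must be one 26-connected component, found {n}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def volume_ml(self) -> float:
        return float(self.voxels.sum()) * float(np.prod(self.spacing)) / 1000.0

    def check_aligned(self, other) -> None:
        if self.voxels.shape != other.voxels.shape:
            raise AlignmentError(
                f"mask shape {self.voxels.shape} != parent shape {other.voxels.shape}"
            )
        if not np.allclose(self.spacing, other.spacing, rtol=1e-4):
            raise AlignmentError(f"mask spacing {self.spacing} != parent {other.spacing}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def load_volume(path, format: Optional[str] = None) -> ActivityVolume:
    """Read a PET volume from a NIfTI file or a DICOM series directory.

    ``format`` is auto-detected from the path when not given: a directory is
    treated as a DICOM series, a file as NIfTI.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such path: {path}")
    if format is None:
        format = "dicom-series" if path.is_dir() else "nifti"
    if format == "nifti":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float32)
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in img.affine[:3, 3])
        return ActivityVolume(np.maximum(data, 0.0), spacing, origin)
    if format == "dicom-series":
        return _load_dicom_series(path)
    raise ValueError(f"unknown format {format!r}")


def _load_dicom_series(path: Path) -> ActivityVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise FormatError(f"no DICOM image slices found under {path}")

    orients = {tuple(np.round(np.asarray(s.ImageOrientationPatient, float), 6)) for s in slices}
    if len(orients) != 1:
        raise FormatError("DICOM slices have inconsistent orientation")
    spac = {tuple(np.round(np.asarray(s.PixelSpacing, float), 6)) for s in slices}
    if len(spac) != 1:
        raise FormatError("DICOM slices have inconsistent pixel spacing")

    orient = np.asarray(slices[0].ImageOrientationPatient, float)
    normal = np.cross(orient[:3], orient[3:])
    slices.sort(key=lambda s: float(np.dot(np.asarray(s.ImagePositionPatient, float), normal)))
    zpos = np.array(
        [float(np.dot(np.asarray(s.ImagePositionPatient, float), normal)) for s in slices]
    )
    dz = np.diff(zpos)
    if len(dz) == 0:
        raise FormatError("a DICOM series needs at least two slices")
    step = float(np.median(dz))
    gaps = np.where(np.abs(dz - step) > 0.05 * abs(step))[0]
    if gaps.size:
        raise FormatError(
            f"missing/irregular DICOM slice between positions {zpos[gaps[0]]:.2f} "
            f"and {zpos[gaps[0] + 1]:.2f} mm (expected step {step:.2f} mm)"
        )

    planes = []
    for s in slices:
        arr = s.pixel_array.astype(np.float32)
        slope = float(getattr(s, "RescaleSlope", 1.0))
        intercept = float(getattr(s, "RescaleIntercept", 0.0))
        # pixel_array is (rows, cols) = (y, x); package convention is (x, y, z)
        planes.append((arr * slope + intercept).T)
    vox = np.stack(planes, axis=-1)

    py, px = (float(v) for v in slices[0].PixelSpacing)
    spacing = (px, py, abs(step))
    origin = tuple(float(v) for v in slices[0].ImagePositionPatient)

    ds0 = slices[0]
    dose_mbq = weight = inj_time = None
    if getattr(ds0, "PatientWeight", None):
        weight = float(ds0.PatientWeight)
    rinfo = getattr(ds0, "RadiopharmaceuticalInformationSequence", None)
    if rinfo:
        item = rinfo[0]
        if getattr(item, "RadionuclideTotalDose", None):
            dose_mbq = float(item.RadionuclideTotalDose) / 1e6  # stored in Bq
        inj_time = str(getattr(item, "RadiopharmaceuticalStartTime", "")) or None
    if dose_mbq is None or weight is None:
        warnings.warn(
            "injected dose and/or patient weight missing from DICOM headers; "
            "SUV conversion will need explicit weight/dose arguments",
            MetadataMissingWarning,
            stacklevel=2,
        )
    return ActivityVolume(
        np.maximum(vox, 0.0),
        spacing,
        origin,
        injected_dose_mbq=dose_mbq,
        weight_kg=weight,
        injection_time=inj_time,
        acquisition_time=str(getattr(ds0, "AcquisitionTime", "")) or None,
        decay_corrected=str(getattr(ds0, "DecayCorrection", "START")) != "NONE",
    )


def save_volume(vol, path) -> None:
    """Write an Activity/SuvVolume to NIfTI-1 (float32)."""
    img = nib.Nifti1Image(np.asarray(vol.voxels, dtype=np.float32), _affine(vol.spacing, vol.origin))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def save_mask(mask: BtvMask, path) -> None:
    """Write a BTV mask to NIfTI-1 as uint8 {0, 1}."""
    if not mask.voxels.any():  # unreachable through the constructor; defensive
        raise ValueError("refusing to save an empty mask")
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine(mask.spacing, mask.origin))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def load_mask(path, parent: SuvVolume, lesion_id: int = 0) -> BtvMask:
    """Read a binary mask and check its geometry against ``parent``."""
    img = nib.load(str(path))
    vox = np.asarray(img.dataobj) > 0
    if vox.shape != parent.shape:
        raise AlignmentError(f"mask shape {vox.shape} != parent shape {parent.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if not np.allclose(spacing, parent.spacing, rtol=1e-4):
        raise AlignmentError(f"mask spacing {spacing} != parent {parent.spacing}")
    return BtvMask(vox, parent.spacing, parent.origin, lesion_id=lesion_id)


# ---------------------------------------------------------------------------
# Quantitative conversion
# ---------------------------------------------------------------------------

def decay_correct(vol: ActivityVolume, elapsed_min: float,
                  half_life_min: float = C11_HALF_LIFE_MIN) -> ActivityVolume:
    """Decay-correct activity back to injection time by ``elapsed_min`` minutes."""
    factor = 2.0 ** (elapsed_min / half_life_min)
    return ActivityVolume(
        vol.voxels * factor, vol.spacing, vol.origin,
        injected_dose_mbq=vol.injected_dose_mbq, weight_kg=vol.weight_kg,
        injection_time=vol.injection_time, acquisition_time=vol.acquisition_time,
        decay_corrected=True,
    )


def to_suv(vol: ActivityVolume, weight_kg: Optional[float] = None,
           dose_mbq: Optional[float] = None) -> SuvVolume:
    """Convert activity concentration to body-weight SUV (g/ml).

    SUV = activity [Bq/ml] / (injected dose [Bq] / body weight [g]); with
    decay-corrected activity this is the standard body-weight SUV.
    """
    weight_kg = weight_kg if weight_kg is not None else vol.weight_kg
    dose_mbq = dose_mbq if dose_mbq is not None else vol.injected_dose_mbq
    if weight_kg is None or dose_mbq is None:
        raise ValueError("weight_kg and dose_mbq required (not found in metadata)")
    if weight_kg <= 0 or dose_mbq <= 0:
        raise ValueError("weight and injected dose must be positive")
    scale = (weight_kg * 1e3) / (dose_mbq * 1e6)  # g / Bq
    return SuvVolume(vol.voxels * scale, vol.spacing, vol.origin,
                     weight_kg=weight_kg, injected_dose_mbq=dose_mbq)


def lean_body_mass_kg(sex: str, weight_kg: float, height_cm: float) -> float:
    """James (1976) lean body mass, the classical PET convention.

    male:   1.10 W - 128 (W/H)^2
    female: 1.07 W - 148 (W/H)^2      (W in kg, H in cm)
    """
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    s = sex.upper()[:1]
    if s == "M":
        return 1.10 * weight_kg - 128.0 * (weight_kg / height_cm) ** 2
    if s == "F":
        return 1.07 * weight_kg - 148.0 * (weight_kg / height_cm) ** 2
    raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")


def to_sul(vol: SuvVolume, sex: str, height_cm: float) -> SuvVolume:
    """Rescale a body-weight SUV volume to lean-body-mass SUL units."""
    if vol.weight_kg is None:
        raise ValueError("SuvVolume carries no patient weight; supply it at SUV conversion")
    if sex is None or height_cm is None:
        raise ValueError("SUL conversion needs patient sex and height")
    lbm = lean_body_mass_kg(sex, vol.weight_kg, height_cm)
    return SuvVolume(vol.voxels * (lbm / vol.weight_kg), vol.spacing, vol.origin,
                     weight_kg=vol.weight_kg, injected_dose_mbq=vol.injected_dose_mbq,
                     units="sul")
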