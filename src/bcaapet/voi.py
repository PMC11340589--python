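"""VOI construction and quantification on paired CT/PET voxel grids.

Adipose VOIs are refined in two sequential steps mirroring standard
practice: a CT radiodensity window restricts a hand-drawn seed region to
adipose-density voxels (-190..-30 HU, inclusive), then a PET percentile cut
removes focal hot voxels attributable to spill-over from adjacent muscle.
Statistics (SUV_mean in g/mL, mean HU, volume) are computed over the final
mask.  Everything operates in voxel-index space: masks must be grid-aligned
with their parent volumes, and no world-coordinate transforms are applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import (
    AlignmentError,
    ConfigurationError,
    EmptyVOIError,
    ScheduleError,
    VOITooSmallError,
)
from .kinetic import FrameSchedule, TimeActivityCurve

__all__ = [
    "ImageVolume",
    "VOIMask",
    "VOIStats",
    "adipose_hu_mask",
    "spillover_exclusion",
    "voi_stats",
    "extract_tac",
    "read_nifti",
    "write_nifti",
    "write_mask_nifti",
    "read_mask_nifti",
    "ADIPOSE_HU_WINDOW",
    "SUV_WINDOW_MIN",
    "CANONICAL_SPACING_MM",
]

#: Adipose radiodensity window, HU, inclusive on both ends.
ADIPOSE_HU_WINDOW = (-190.0, -30.0)

#: Static SUV frame: 4th to 14th minute post-injection (10 min duration),
#: chosen after the vascular phase and before late muscle uptake dominates.
SUV_WINDOW_MIN = (4.0, 14.0)

#: Isotropic voxel size of the canonical reconstruction, mm.
CANONICAL_SPACING_MM = 2.344

#: Default spill-over exclusion percentile of in-VOI PET values.  The source
#: protocol applies an exclusion without publishing its threshold; this
#: stand-in removes focal hot voxels without biasing the depot mean and is
#: recorded in output metadata.
DEFAULT_SPILLOVER_PERCENTILE = 97.5

#: Minimum VOI volume, mL.
MIN_VOI_VOLUME_ML = 5.0


@dataclass(frozen=True)
class ImageVolume:
    """A 3-D voxel grid: HU for flavor "ct", kBq/mL for flavor "pet"."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (
        CANONICAL_SPACING_MM,
        CANONICAL_SPACING_MM,
        CANONICAL_SPACING_MM,
    )
    flavor: str = "pet"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        if v.ndim != 3:
            raise ValueError("values must be a 3-D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive in all axes")
        if not np.all(np.isfinite(v)):
            raise ValueError("volume contains non-finite values")
        if self.flavor not in ("ct", "pet"):
            raise ValueError("flavor must be 'ct' or 'pet'")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class VOIMask:
    """Boolean region mask aligned to an ImageVolume grid."""

    mask: np.ndarray
    spacing: tuple[float, float, float] = (
        CANONICAL_SPACING_MM,
        CANONICAL_SPACING_MM,
        CANONICAL_SPACING_MM,
    )

    def __post_init__(self):
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        if m.ndim != 3:
            raise ValueError("mask must be 3-D")

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.mask))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volume_ml(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3 / 1000.0


@dataclass(frozen=True)
class VOIStats:
    suv_mean: float  # g/mL
    radiodensity_mean: float  # HU
    volume_ml: float
    n_voxels: int
    metadata: dict = field(default_factory=dict)


def _check_aligned(volume: ImageVolume, mask: VOIMask) -> None:
    if volume.values.shape != mask.mask.shape:
        raise AlignmentError(
            f"shape mismatch: volume {volume.values.shape} vs mask {mask.mask.shape}"
        )


def adipose_hu_mask(
    ct: ImageVolume,
    seed_mask: VOIMask,
    hu_window: tuple[float, float] = ADIPOSE_HU_WINDOW,
) -> VOIMask:
    """Restrict a seed VOI to adipose-density voxels.

    Returns seed_mask AND (lo <= HU <= hi), inclusive on both ends.
    """
    if ct.flavor != "ct":
        raise ValueError("adipose_hu_mask requires a CT-flavor volume")
    _check_aligned(ct, seed_mask)
    lo, hi = hu_window
    keep = (ct.values >= lo) & (ct.values <= hi)
    return VOIMask(seed_mask.mask & keep, spacing=seed_mask.spacing)


def spillover_exclusion(
    pet: ImageVolume,
    mask: VOIMask,
    percentile: float = DEFAULT_SPILLOVER_PERCENTILE,
) -> VOIMask:
    """Drop in-mask voxels whose PET value exceeds the given percentile.

    The percentile of in-mask values is computed with linear interpolation
    between closest ranks; voxels strictly above the threshold are removed,
    so at most (100-percentile)% of voxels (plus ties at the threshold,
    which are kept) can be excluded.
    """
    if pet.flavor != "pet":
        raise ValueError("spillover_exclusion requires a PET-flavor volume")
    _check_aligned(pet, mask)
    if not (0.0 < percentile < 100.0):
        raise ConfigurationError("percentile must lie strictly between 0 and 100")
    if mask.n_voxels == 0:
        raise EmptyVOIError("mask selects no voxels")
    vals = pet.values[mask.mask]
    thr = np.percentile(vals, percentile)
    keep = mask.mask & ~(pet.values > thr)
    return VOIMask(keep, spacing=mask.spacing)


def voi_stats(
    pet_static: ImageVolume,
    ct: ImageVolume,
    mask: VOIMask,
    dose_MBq: float,
    weight_kg: float,
    min_volume_ml: float = MIN_VOI_VOLUME_ML,
    allow_small: bool = False,
) -> VOIStats:
    """SUV_mean, mean radiodensity and volume over a final VOI.

    SUV_mean (g/mL) = mean PET concentration (kBq/mL) divided by injected
    dose per body weight (kBq/g); with dose in MBq and weight in kg the
    normalizer is simply dose_MBq/weight_kg.  ``pet_static`` should be the
    single static frame over the 4-14 min window; the window designation is
    recorded in the returned metadata.
    """
    if dose_MBq <= 0 or weight_kg <= 0:
        raise ValueError("dose_MBq and weight_kg must be positive")
    if pet_static.flavor != "pet" or ct.flavor != "ct":
        raise ValueError("voi_stats requires a PET and a CT volume")
    _check_aligned(pet_static, mask)
    _check_aligned(ct, mask)
    if mask.n_voxels == 0:
        raise EmptyVOIError("mask selects no voxels")
    if mask.volume_ml < min_volume_ml and not allow_small:
        raise VOITooSmallError(
            f"VOI volume {mask.volume_ml:.2f} mL below minimum {min_volume_ml} mL"
        )
    # dose_MBq*1000 kBq / (weight_kg*1000 g) = dose_MBq/weight_kg in kBq/g
    suv_norm = dose_MBq / weight_kg
    mean_conc = float(pet_static.values[mask.mask].mean())
    return VOIStats(
        suv_mean=mean_conc / suv_norm,
        radiodensity_mean=float(ct.values[mask.mask].mean()),
        volume_ml=mask.volume_ml,
        n_voxels=mask.n_voxels,
        metadata={
            "suv_window_start_min": SUV_WINDOW_MIN[0],
            "suv_window_end_min": SUV_WINDOW_MIN[1],
            "suv_window_duration_min": SUV_WINDOW_MIN[1] - SUV_WINDOW_MIN[0],
            "dose_MBq": float(dose_MBq),
            "weight_kg": float(weight_kg),
            "min_volume_ml": float(min_volume_ml),
        },
    )


def extract_tac(
    dynamic_pet: list[ImageVolume],
    mask: VOIMask,
    schedule: FrameSchedule,
) -> TimeActivityCurve:
    """Mean in-mask concentration per frame, as a TimeActivityCurve."""
    if len(dynamic_pet) != schedule.n_frames:
        raise ScheduleError(
            f"{len(dynamic_pet)} volumes for {schedule.n_frames} frames"
        )
    if mask.n_voxels == 0:
        raise EmptyVOIError("mask selects no voxels")
    values = np.empty(schedule.n_frames)
    for i, vol in enumerate(dynamic_pet):
        _check_aligned(vol, mask)
        values[i] = vol.values[mask.mask].mean()
    return TimeActivityCurve(schedule=schedule, values=values)


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_nifti(volume: ImageVolume, path) -> None:
    nib.save(nib.Nifti1Image(volume.values.astype(np.float32), _affine(volume.spacing)), str(path))


def read_nifti(path, flavor: str) -> ImageVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(np.asarray(img.get_fdata()), spacing=spacing, flavor=flavor)


def write_mask_nifti(mask: VOIMask, path) -> None:
    """Masks are stored as 0/1 integer volumes."""
    nib.save(
        nib.Nifti1Image(mask.mask.astype(np.uint8), _affine(mask.spacing)), str(path)
    )


def read_mask_nifti(path) -> VOIMask:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VOIMask(np.asarray(img.get_fdata()) > 0.5, spacing=spacing)
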