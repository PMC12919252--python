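"""CT body-composition morphometry at the L3 level.

Visceral adipose tissue (VAT) is quantified on a single HU-calibrated
axial slice: fat voxels in the closed window [−150, −50] HU inside the
abdominal-cavity mask are grown from seed points (8-connectivity),
smoothed with a morphological closing (disk, radius 2 px by default)
and reported as an area in cm².  Visceral obesity (VO) is a VAT area
of at least 100 cm².  The module also measures waist circumference as
the perimeter of a truncal outline polygon and kidney volume as the
slice-area sum times section thickness.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import LinearRing
from skimage.measure import label
from skimage.morphology import closing as _closing, disk

logger = logging.getLogger(__name__)

__all__ = [
    "CTSlice",
    "FatSegmentation",
    "KidneyVolumetry",
    "HU_FAT_WINDOW",
    "VO_THRESHOLD_CM2",
    "segment_vat",
    "classify_vo",
    "waist_circumference",
    "kidney_volume",
    "load_ct_slice",
    "load_mask",
]

#: Fat attenuation window in Hounsfield units (closed interval).
HU_FAT_WINDOW = (-150.0, -50.0)
#: Visceral-obesity threshold on the L3 VAT area, cm² (inclusive).
VO_THRESHOLD_CM2 = 100.0


@dataclass
class CTSlice:
    """A single HU-calibrated axial CT slice with its cavity mask."""

    hu: np.ndarray  # 2-D, Hounsfield units
    pixel_spacing: tuple[float, float]  # (row, col) mm
    cavity_mask: np.ndarray  # 2-D bool, abdominal cavity
    body_outline: Optional[np.ndarray] = None  # (N, 2) ring in mm

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=float)
        self.cavity_mask = np.asarray(self.cavity_mask, dtype=bool)
        if self.hu.ndim != 2:
            raise ValueError("hu must be a 2-D array")
        if self.hu.shape != self.cavity_mask.shape:
            raise ValueError(
                f"shape mismatch: hu {self.hu.shape} vs cavity {self.cavity_mask.shape}"
            )
        if not all(s > 0 for s in self.pixel_spacing):
            raise ValueError("pixel_spacing must be positive")

    @property
    def pixel_area_cm2(self) -> float:
        return self.pixel_spacing[0] * self.pixel_spacing[1] / 100.0


@dataclass
class FatSegmentation:
    """VAT segmentation result on one slice."""

    vat_mask: np.ndarray  # 2-D bool
    vat_area_cm2: float
    vo: bool


@dataclass
class KidneyVolumetry:
    """Kidney volume from summed cross-sectional areas."""

    slice_areas_cm2: list[float]
    slice_thickness_cm: float
    volume_cm3: float
    height_adjusted_cm3_per_m: Optional[float] = None


def classify_vo(vat_area_cm2: float, threshold: float = VO_THRESHOLD_CM2) -> bool:
    """Visceral obesity: VAT area >= threshold (inclusive, default 100 cm²)."""
    if vat_area_cm2 < 0:
        raise ValueError(f"vat_area_cm2 must be >= 0, got {vat_area_cm2}")
    return vat_area_cm2 >= threshold


def segment_vat(
    ct: CTSlice,
    seeds: Sequence[tuple[int, int]],
    hu_window: tuple[float, float] = HU_FAT_WINDOW,
    closing_radius: int = 2,
    connectivity: int = 2,
    vo_threshold: float = VO_THRESHOLD_CM2,
) -> FatSegmentation:
    """Segment VAT on an L3 slice by seeded region growing.

    Pixels within the closed ``hu_window`` and inside the cavity mask
    form the candidate fat mask; connected components (8-connectivity
    by default, ``connectivity=1`` for 4-connectivity) touching any
    seed are kept, then a binary closing with a disk structuring
    element of ``closing_radius`` px fills pinholes.  The result is
    clipped to the cavity mask so VAT never exceeds the cavity.
    """
    lo, hi = hu_window
    candidate = (ct.hu >= lo) & (ct.hu <= hi) & ct.cavity_mask
    labels = label(candidate, connectivity=connectivity)
    keep: set[int] = set()
    for r, c in seeds:
        if not ct.cavity_mask[r, c]:
            raise ValueError(f"seed ({r}, {c}) lies outside the cavity mask")
        if labels[r, c] > 0:
            keep.add(int(labels[r, c]))
    if not keep:
        warnings.warn("no seed falls inside the fat HU window; empty segmentation")
        mask = np.zeros_like(candidate)
    else:
        mask = np.isin(labels, sorted(keep))
        if closing_radius > 0:
            mask = _closing(mask, disk(closing_radius)) & ct.cavity_mask
    area = float(mask.sum()) * ct.pixel_area_cm2
    return FatSegmentation(vat_mask=mask, vat_area_cm2=area,
                           vo=classify_vo(area, vo_threshold))


def waist_circumference(body_outline_mm: Sequence[Sequence[float]]) -> float:
    """Waist circumference (cm) as the perimeter of the truncal outline.

    The outline is a simple closed ring in mm (an explicitly repeated
    first point is accepted); degenerate or self-intersecting rings
    raise a ``ValueError``.
    """
    coords = np.asarray(body_outline_mm, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("body outline must be an (N, 2) array of mm coordinates")
    if np.allclose(coords[0], coords[-1]):
        coords = coords[:-1]
    if coords.shape[0] < 3:
        raise ValueError("body outline must close a ring of >= 3 distinct points")
    ring = LinearRing(coords)
    if not ring.is_valid:
        raise ValueError("body outline ring is self-intersecting")
    return ring.length / 10.0


def kidney_volume(
    slice_areas_cm2: Sequence[float],
    slice_thickness_cm: float,
    height_m: Optional[float] = None,
) -> KidneyVolumetry:
    """Kidney volume: sum of cross-sectional areas × section thickness.

    Optionally height-adjusted (cm³ per m of body height).
    """
    if not slice_thickness_cm > 0:
        raise ValueError(f"slice_thickness_cm must be > 0, got {slice_thickness_cm}")
    areas = [float(a) for a in slice_areas_cm2]
    if any(a < 0 for a in areas):
        raise ValueError("slice areas must be >= 0")
    if not areas:
        warnings.warn("empty slice-area list; kidney volume is 0")
    volume = slice_thickness_cm * float(np.sum(areas)) if areas else 0.0
    adjusted = None
    if height_m is not None:
        if not height_m > 0:
            raise ValueError(f"height_m must be > 0, got {height_m}")
        adjusted = volume / height_m
    return KidneyVolumetry(areas, slice_thickness_cm, volume, adjusted)


def load_ct_slice(
    image_path: str | Path,
    cavity_mask_path: str | Path,
    pixel_spacing: Optional[tuple[float, float]] = None,
) -> CTSlice:
    """Load an HU-calibrated axial slice plus its cavity mask.

    DICOM (``.dcm``) pixel data are rescaled with the stored slope and
    intercept and the spacing read from ``PixelSpacing``; NIfTI
    (``.nii``/``.nii.gz``) data are assumed pre-calibrated, with the
    spacing from the header zooms unless overridden.
    """
    image_path = Path(image_path)
    suffixes = "".join(image_path.suffixes).lower()
    if suffixes.endswith(".dcm"):
        import pydicom

        ds = pydicom.dcmread(image_path)
        hu = ds.pixel_array.astype(float)
        hu = hu * float(getattr(ds, "RescaleSlope", 1.0)) + float(
            getattr(ds, "RescaleIntercept", 0.0)
        )
        spacing = pixel_spacing or tuple(float(v) for v in ds.PixelSpacing)
    elif ".nii" in suffixes:
        import nibabel as nib

        img = nib.load(str(image_path))
        data = np.asanyarray(img.dataobj).astype(float)
        hu = np.squeeze(data)
        if hu.ndim != 2:
            raise ValueError(f"{image_path}: expected a single 2-D slice")
        spacing = pixel_spacing or tuple(float(z) for z in img.header.get_zooms()[:2])
    else:
        raise ValueError(f"unsupported CT image format: {image_path.name}")
    cavity = load_mask(cavity_mask_path)
    return CTSlice(hu=hu, pixel_spacing=spacing, cavity_mask=cavity)


def load_mask(path: str | Path) -> np.ndarray:
    """Load a binary mask from PNG or NIfTI (nonzero = inside)."""
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith(".png"):
        from PIL import Image

        return np.asarray(Image.open(path)) > 0
    if ".nii" in suffixes:
        import nibabel as nib

        return np.squeeze(np.asanyarray(nib.load(str(path)).dataobj)) > 0
    raise ValueError(f"unsupported mask format: {path.name}")
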