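"""Egg segmentation and diameter measurement.

Eggs absorb visible light more strongly than the surrounding seawater, so
they appear as dark, roughly circular regions against a bright background.
Segmentation averages the cube over a reference band (visible by default,
where contrast is highest), thresholds, cleans up, and keeps circular
non-border components.  The equivalent-circle diameter of a region is the
egg "thickness" x used by the attenuation coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.morphology import disk as disk_footprint

from .errors import CoverageError, ValidationError
from .spectral_io import BandDefinition, HyperspectralCube, VISIBLE_BAND

logger = logging.getLogger(__name__)

__all__ = [
    "EggRegion",
    "BackgroundMask",
    "SegmentationParams",
    "segment_eggs",
    "background_mask",
    "estimate_diameter",
    "export_regions",
]


def _default_min_area(pixel_size_um: float) -> int:
    # area of a 50-um-diameter disk, the smallest plausible egg
    r_px = 25.0 / pixel_size_um
    return max(4, int(round(np.pi * r_px**2)))


@dataclass(frozen=True)
class EggRegion:
    """One segmented egg.

    ``mask`` is a full-frame boolean array; ``equivalent_diameter_um`` is
    the diameter of the circle with the same pixel area, converted to
    micrometres -- the thickness entering the attenuation coefficient.
    ``circularity`` is 4*pi*area/perimeter^2, clipped to 1.
    """

    label: int
    mask: np.ndarray = field(repr=False)
    centroid: tuple[float, float]
    area_px: int
    equivalent_diameter_um: float
    circularity: float
    major_axis_um: float = float("nan")
    minor_axis_um: float = float("nan")


@dataclass(frozen=True)
class BackgroundMask:
    """Pixels outside every egg region plus a guard margin."""

    mask: np.ndarray = field(repr=False)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable segmentation knobs.

    threshold_mode ``"relative"`` marks pixels darker than
    ``relative_level`` times the frame median (eggs only need to dim the
    light by ~1% relative to seawater); ``"otsu"`` is the classic
    bimodal-histogram split, better for strongly pigmented eggs.
    """

    reference_band: BandDefinition = VISIBLE_BAND
    threshold_mode: str = "relative"
    relative_level: float = 0.99
    min_area_px: int | None = None
    min_circularity: float = 0.6

    def __post_init__(self):
        if self.threshold_mode not in ("otsu", "relative"):
            raise ValidationError(
                f"threshold_mode must be 'otsu' or 'relative', got {self.threshold_mode!r}"
            )
        if not 0 < self.relative_level < 1:
            raise ValidationError("relative_level must be in (0, 1)")


def estimate_diameter(area_px: int | float, pixel_size_um: float) -> float:
    """Equivalent-circle diameter in um: ``2 * pixel * sqrt(area / pi)``."""
    if area_px < 0:
        raise ValidationError("area_px must be >= 0")
    if pixel_size_um <= 0:
        raise ValidationError("pixel_size_um must be > 0")
    return 2.0 * pixel_size_um * float(np.sqrt(area_px / np.pi))


def segment_eggs(cube: HyperspectralCube,
                 params: SegmentationParams | None = None) -> list[EggRegion]:
    """Locate egg regions in a cube.

    Fixed procedure: (1) average intensity over the reference band to a
    2-D image; (2) threshold (Otsu or relative-to-median); (3) fill holes
    and remove objects below ``min_area_px``; (4) 4-connected components;
    (5) drop components with circularity below ``min_circularity`` or
    touching the image border.  Regions are returned sorted by centroid
    (row, then col).  An empty frame yields an empty list, not an error.
    """
    params = params or SegmentationParams()
    sel = params.reference_band.selector(cube.grid)
    if not sel.any():
        raise ValidationError(
            f"reference band {params.reference_band.name} does not overlap the grid"
        )
    ref = cube.intensities[:, :, sel].mean(axis=2)

    span = ref.max() - ref.min()
    if span <= 1e-12 * max(1.0, abs(float(ref.max()))):
        return []  # constant frame: nothing to segment

    if params.threshold_mode == "otsu":
        thresh = threshold_otsu(ref)
    else:
        thresh = params.relative_level * float(np.median(ref))
    binary = ref < thresh
    binary = ndimage.binary_fill_holes(binary)

    min_area = params.min_area_px
    if min_area is None:
        min_area = _default_min_area(cube.pixel_size_um)

    labels = measure.label(binary, connectivity=1)
    h, w = ref.shape
    regions: list[EggRegion] = []
    for rp in measure.regionprops(labels):
        if rp.area < min_area:
            continue
        r0, c0, r1, c1 = rp.bbox
        if r0 == 0 or c0 == 0 or r1 == h or c1 == w:
            logger.debug("region %d rejected: touches border", rp.label)
            continue
        perim = rp.perimeter
        circ = 1.0 if perim == 0 else min(1.0, 4.0 * np.pi * rp.area / perim**2)
        if circ < params.min_circularity:
            logger.debug("region %d rejected: circularity %.3f", rp.label, circ)
            continue
        mask = labels == rp.label
        regions.append(
            EggRegion(
                label=rp.label,
                mask=mask,
                centroid=tuple(rp.centroid),
                area_px=int(rp.area),
                equivalent_diameter_um=estimate_diameter(rp.area, cube.pixel_size_um),
                circularity=float(circ),
                major_axis_um=float(rp.axis_major_length) * cube.pixel_size_um,
                minor_axis_um=float(rp.axis_minor_length) * cube.pixel_size_um,
            )
        )
    # round to whole pixels first so noise-level centroid jitter cannot
    # scramble eggs that sit on the same row
    regions.sort(key=lambda r: (round(r.centroid[0]), round(r.centroid[1]),
                                r.centroid))
    # renumber in reading order so downstream ids are stable
    return [
        EggRegion(i + 1, r.mask, r.centroid, r.area_px, r.equivalent_diameter_um,
                  r.circularity, r.major_axis_um, r.minor_axis_um)
        for i, r in enumerate(regions)
    ]


def background_mask(cube: HyperspectralCube, regions: list[EggRegion],
                    guard_margin_px: int = 10) -> BackgroundMask:
    """Pixels further than ``guard_margin_px`` (binary dilation) from every egg.

    Raises :class:`CoverageError` when the eggs plus margins swallow the
    whole frame -- the field of view is then too small to estimate the
    incident spectrum.
    """
    h, w, _ = cube.shape
    occupied = np.zeros((h, w), dtype=bool)
    for region in regions:
        if region.mask.shape != (h, w):
            raise ValidationError("region mask shape does not match cube frame")
        occupied |= region.mask
    if occupied.any() and guard_margin_px > 0:
        occupied = ndimage.binary_dilation(
            occupied, structure=disk_footprint(guard_margin_px)
        )
    bg = ~occupied
    if not bg.any():
        raise CoverageError(
            "egg regions plus guard margins cover the entire frame; "
            "image a larger field of view or reduce guard_margin_px"
        )
    return BackgroundMask(bg)


def export_regions(regions: list[EggRegion], frame_shape: tuple[int, int],
                   out_dir: str | Path, stem: str = "regions") -> tuple[Path, Path]:
    """Write a 16-bit label TIFF and a per-region properties CSV."""
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = np.zeros(frame_shape, dtype=np.uint16)
    for r in regions:
        labels[r.mask] = r.label
    tiff_path = out_dir / f"{stem}.tif"
    tifffile.imwrite(tiff_path, labels)
    df = pd.DataFrame(
        [
            {
                "label": r.label,
                "centroid_row": r.centroid[0],
                "centroid_col": r.centroid[1],
                "area_px": r.area_px,
                "equivalent_diameter_um": r.equivalent_diameter_um,
                "circularity": r.circularity,
                "major_axis_um": r.major_axis_um,
                "minor_axis_um": r.minor_axis_um,
            }
            for r in regions
        ]
    )
    csv_path = out_dir / f"{stem}.csv"
    df.to_csv(csv_path, index=False)
    return tiff_path, csv_path
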