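"""Intratumoral region and fat-excluded peritumoral rim construction.

The rim is the band of tissue within ``rim_mm`` (default 12 mm) of the
tumor boundary, obtained by dilating the tumor mask in physical space with
an anisotropic Euclidean distance transform, then removing the tumor
itself, any voxel at or below the fat HU ceiling (-10 HU; peri-hepatic fat
sits in [-100, -10] HU and air lower still), and anything outside the
volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import CTVolume, SegmentationMask

logger = logging.getLogger(__name__)

DEFAULT_RIM_MM = 12.0
DEFAULT_FAT_HU_MAX = -10.0


@dataclass
class RegionPair:
    """Tumor mask plus its fat-excluded peritumoral rim.

    ``rim_empty`` flags the degenerate case where every candidate rim voxel
    was excluded; downstream rim features then become missing.
    """

    tumor: SegmentationMask
    rim: SegmentationMask
    rim_mm: float
    excluded_voxel_count: int
    rim_empty: bool = False


def tumor_distance_mm(tumor: SegmentationMask) -> np.ndarray:
    """Euclidean distance (mm) from each background voxel to the tumor."""
    return ndimage.distance_transform_edt(
        ~tumor.voxels, sampling=tumor.spacing
    )


def extract_peritumoral_rim(volume: CTVolume, tumor: SegmentationMask,
                            rim_mm: float = DEFAULT_RIM_MM,
                            fat_hu_max: float = DEFAULT_FAT_HU_MAX) -> RegionPair:
    """Build the peritumoral rim for one lesion.

    rim = dilation(tumor, rim_mm in physical space) minus tumor, minus
    voxels with HU <= fat_hu_max.  Voxel counts removed by the HU rule are
    reported; an empty rim is flagged, not an exception.
    """
    if rim_mm <= 0:
        raise ValueError("rim_mm must be positive")
    tumor.check_grid(volume)
    if not tumor.voxels.any():
        raise ValueError("empty region: tumor mask contains no voxels")

    dist = tumor_distance_mm(tumor)
    shell = (dist > 0) & (dist <= rim_mm)
    fat = volume.intensities <= fat_hu_max
    rim_voxels = shell & ~fat
    excluded = int(np.count_nonzero(shell & fat))

    rim_empty = not rim_voxels.any()
    if rim_empty:
        logger.warning(
            "peritumoral rim empty after exclusions (excluded %d fat voxels)",
            excluded,
        )
    rim = SegmentationMask(rim_voxels, tumor.spacing, grid=tumor.grid, label="rim")
    return RegionPair(tumor=tumor, rim=rim, rim_mm=float(rim_mm),
                      excluded_voxel_count=excluded, rim_empty=rim_empty)
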