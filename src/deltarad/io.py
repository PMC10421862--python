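"""Reading and writing CT volumes, segmentation masks and tabular data.

Volumes are stored with array axes (x, y, z) so that ``intensities[:, :, k]``
is the k-th axial slice, and ``spacing`` is millimetres per voxel along the
same axes.  Masks must live on the exact grid of their reference volume; no
resampling happens here.  Hounsfield units outside the plausible scanner
range [-1024, 3071] are clipped with a warning rather than rejected.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import SimpleITK as sitk

logger = logging.getLogger(__name__)

HU_MIN = -1024
HU_MAX = 3071

CLINICAL_COLUMNS = [
    "patient_id",
    "os_months",
    "event",
    "response",
    "age",
    "race",
    "baseline_tumor_volume_ml",
]


class GridMismatchError(ValueError):
    """Mask and volume do not share the same voxel grid."""


@dataclass
class CTVolume:
    """A 3D CT intensity grid in Hounsfield units.

    Attributes
    ----------
    intensities : ndarray, shape (nx, ny, nz)
        HU values, finite, within [-1024, 3071].
    spacing : tuple of float
        (sx, sy, sz) voxel size in mm, strictly positive.
    affine : ndarray, shape (4, 4)
        Voxel-index -> world (mm, LPS) map.
    id : str
        Scan identifier.
    timepoint : str
        "pre" or "post".
    """

    intensities: np.ndarray
    spacing: tuple
    affine: np.ndarray = None
    id: str = ""
    timepoint: str = "pre"

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"non-3D payload: got {self.intensities.ndim} dimensions"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        lo, hi = self.intensities.min(), self.intensities.max()
        if lo < HU_MIN or hi > HU_MAX:
            logger.warning(
                "HU values outside [%d, %d] clipped (range was [%.1f, %.1f])",
                HU_MIN, HU_MAX, lo, hi,
            )
            self.intensities = np.clip(self.intensities, HU_MIN, HU_MAX)
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self):
        return self.intensities.shape


@dataclass
class SegmentationMask:
    """Binary region on a CTVolume grid.

    ``label`` is "tumor" or "rim"; a tumor mask must be nonempty.
    """

    voxels: np.ndarray
    spacing: tuple
    grid: str = ""
    label: str = "tumor"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels) > 0
        if self.voxels.ndim != 3:
            raise ValueError("non-3D payload: mask must be a 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.label == "tumor" and not self.voxels.any():
            raise ValueError("empty region: tumor mask contains no voxels")

    @property
    def shape(self):
        return self.voxels.shape

    def check_grid(self, volume: CTVolume):
        """Raise GridMismatchError unless this mask shares ``volume``'s grid."""
        if self.shape != volume.shape:
            raise GridMismatchError(
                f"mask shape {self.shape} != volume shape {volume.shape}"
            )
        if not np.allclose(self.spacing, volume.spacing):
            raise GridMismatchError(
                f"mask spacing {self.spacing} != volume spacing {volume.spacing}"
            )


def _to_sitk(array_xyz: np.ndarray, spacing) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(array_xyz.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    return img


def _from_sitk(img: sitk.Image):
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    return arr.transpose(2, 1, 0), tuple(img.GetSpacing())


def read_volume(path, id: str = None, timepoint: str = "pre") -> CTVolume:
    """Read a CT volume from NIfTI (.nii/.nii.gz) or NRRD.

    Spacing comes from the file header; a file without 3D payload is
    rejected rather than guessed at.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"non-3D payload: image has dimension {img.GetDimension()}")
    arr, spacing = _from_sitk(img)
    origin = np.asarray(img.GetOrigin())
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    affine = np.eye(4)
    affine[:3, :3] = direction @ np.diag(spacing)
    affine[:3, 3] = origin
    if id is None:
        id = os.path.basename(str(path)).split(".")[0]
    return CTVolume(arr.astype(np.float64), spacing, affine, id=id, timepoint=timepoint)


def write_volume(volume: CTVolume, path) -> None:
    sitk.WriteImage(_to_sitk(volume.intensities, volume.spacing), str(path))


def read_mask(path, reference: CTVolume, label: str = "tumor") -> SegmentationMask:
    """Read a mask and bind it to ``reference``'s grid.

    Any voxel value > 0 maps to foreground.  Shape or spacing mismatch with
    the reference raises GridMismatchError; an all-zero tumor mask is an
    error.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"non-3D payload: image has dimension {img.GetDimension()}")
    arr, spacing = _from_sitk(img)
    if arr.shape != reference.shape:
        raise GridMismatchError(
            f"mask shape {arr.shape} != volume shape {reference.shape}"
        )
    if not np.allclose(spacing, reference.spacing):
        raise GridMismatchError(
            f"mask spacing {spacing} != volume spacing {reference.spacing}"
        )
    return SegmentationMask(arr > 0, reference.spacing, grid=reference.id, label=label)


def write_mask(mask: SegmentationMask, path) -> None:
    sitk.WriteImage(_to_sitk(mask.voxels.astype(np.uint8), mask.spacing), str(path))


# ---------------------------------------------------------------------------
# Feature / clinical tables


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a per-(lesion, timepoint) feature table as CSV.

    Columns are emitted in stable (original) order; NaN serializes as an
    empty cell.  Floats are written at full repr precision so read-back is
    exact.
    """
    table.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_clinical_table(path) -> pd.DataFrame:
    """Read the clinical CSV with its fixed column contract.

    Required columns: patient_id, os_months, event, response, age, race,
    baseline_tumor_volume_ml.  os_months must be positive, event in {0, 1},
    response one of {responder, non-responder}.
    """
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    if (df["os_months"] <= 0).any():
        raise ValueError("os_months must be > 0")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 or 1")
    if not df["response"].isin(["responder", "non-responder"]).all():
        raise ValueError("response must be 'responder' or 'non-responder'")
    return df


def write_clinical_table(df: pd.DataFrame, path) -> None:
    df[CLINICAL_COLUMNS].to_csv(path, index=False, float_format="%.17g")
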