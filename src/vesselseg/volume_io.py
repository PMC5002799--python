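"""Reading, writing and projecting 3D scalar volumes and binary masks.

Volumes are held in array (axis0, axis1, axis2) index order; ``spacing`` and
``origin`` are stored in the same axis order as the array.  World coordinates
only matter at the file boundary — the segmentation itself is purely
grid-based.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

SUPPORTED_EXTENSIONS = (".nii", ".nii.gz", ".mha", ".mhd", ".nrrd")


class VolumeFormatError(ValueError):
    """Unsupported or malformed volume file."""


@dataclass
class Volume3D:
    """A 3D scalar image with voxel spacing (length units per voxel)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"expected a nonempty 3D array, got shape {self.data.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class BinaryMask3D:
    """A boolean 3D grid annotating a Volume3D of the same shape."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        return int(np.count_nonzero(self.data))


def _check_extension(path: str) -> None:
    low = str(path).lower()
    if not low.endswith(SUPPORTED_EXTENSIONS):
        raise VolumeFormatError(
            f"unsupported volume format for {path!r}; expected one of {SUPPORTED_EXTENSIONS}"
        )


def read_volume(path: str) -> Volume3D:
    """Read a 3D volume (NIfTI / MetaImage / NRRD); intensities cast to float."""
    _check_extension(path)
    if not os.path.exists(path):
        raise IOError(f"volume file not found: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # SimpleITK raises RuntimeError on bad files
        raise IOError(f"could not read volume {path!r}: {exc}") from exc
    arr = sitk.GetArrayFromImage(img).astype(np.float64)
    if arr.ndim != 3:
        raise VolumeFormatError(f"{path!r} is {arr.ndim}D, expected a 3D volume")
    if not np.all(np.isfinite(arr)):
        raise VolumeFormatError(f"{path!r} contains non-finite intensities")
    # SimpleITK reports spacing/origin in (x, y, z); GetArrayFromImage returns
    # (z, y, x) index order, so reverse to match the array axes.
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    return Volume3D(arr, spacing=spacing, origin=origin)


def read_mask(path: str) -> BinaryMask3D:
    vol = read_volume(path)
    return BinaryMask3D(vol.data > 0.5, spacing=vol.spacing, origin=vol.origin)


def _write(arr: np.ndarray, spacing, origin, path: str) -> None:
    _check_extension(path)
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(reversed(tuple(float(s) for s in spacing))))
    img.SetOrigin(tuple(reversed(tuple(float(o) for o in origin))))
    try:
        sitk.WriteImage(img, str(path))
    except Exception as exc:
        raise IOError(f"could not write {path!r}: {exc}") from exc


def write_volume(volume: Volume3D, path: str) -> None:
    """Write a volume as float32 (bit-exact round trip for float32 data)."""
    _write(np.asarray(volume.data, dtype=np.float32), volume.spacing, volume.origin, path)


def write_mask(mask: BinaryMask3D, path: str) -> None:
    """Write a binary mask as uint8 {0, 1}."""
    if mask.data.size == 0:
        raise ValueError("refusing to write an empty-shape mask")
    _write(mask.data.astype(np.uint8), mask.spacing, mask.origin, path)


def mip_project(volume: Volume3D, axis: int = 0) -> np.ndarray:
    """Maximum intensity projection along ``axis`` (per-pixel max of the rays)."""
    if axis not in (0, 1, 2):
        raise ValueError(f"axis must be 0, 1 or 2, got {axis}")
    return np.asarray(volume.data).max(axis=axis)


def save_mip_png(volume: Volume3D, path: str, axis: int = 0) -> None:
    """Write an 8-bit min–max windowed MIP image (for visual inspection only)."""
    from PIL import Image

    mip = mip_project(volume, axis=axis).astype(np.float64)
    lo, hi = float(mip.min()), float(mip.max())
    scale = 255.0 / (hi - lo) if hi > lo else 0.0
    img8 = ((mip - lo) * scale).astype(np.uint8)
    Image.fromarray(img8).save(path)
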