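"""Image volumes, brain masks and NIfTI I/O.

All imaging data in the package flows through :class:`ImageVolume` (a 3D
scalar grid with voxel spacing in mm) and :class:`BrainMask` (a binary grid
on the same voxel lattice).  Volumes are assumed pre-aligned: registration
is upstream of this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "BrainMask", "load_volume", "load_mask", "save_volume"]


@dataclass
class ImageVolume:
    """A 3D scalar image with per-axis voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image contains non-finite values")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        """A new volume on the same grid with different values."""
        return ImageVolume(data, self.spacing)


@dataclass
class BrainMask:
    """Binary foreground mask on the same grid as its image."""

    data: np.ndarray = field()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D mask, got {self.data.ndim}D")
        if not self.data.any():
            raise ValueError("brain mask is empty")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def voxel_indices(self) -> np.ndarray:
        """(n, 3) integer voxel indices of foreground voxels, C order."""
        return np.argwhere(self.data)

    def intersection(self, other: "BrainMask") -> np.ndarray:
        if self.grid_shape != other.grid_shape:
            raise ValueError("mask grids do not match")
        return self.data & other.data


def load_volume(path: str) -> ImageVolume:
    """Read a NIfTI volume; spacing is taken from the header zooms."""
    img = nib.load(path)
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(data, spacing)


def load_mask(path: str) -> BrainMask:
    img = nib.load(path)
    return BrainMask(np.asanyarray(img.dataobj) > 0)


def save_volume(path: str, data: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> None:
    """Write a volume (scalar, label or mask) as NIfTI with the given spacing."""
    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    nib.save(nib.Nifti1Image(arr, affine), path)
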