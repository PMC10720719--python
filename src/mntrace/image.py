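"""3D scalar volumes with world geometry, plus NIfTI I/O.

A :class:`VolumeImage` is the in-memory unit of the whole pipeline: a 3D
array of signal values (arbitrary units) together with the voxel size and a
4x4 index-to-world affine mapping 0-based voxel indices to RAS+ millimetre
coordinates.  All registration and resampling is expressed in world mm so
images on different grids compose cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeImage", "BrainMask", "load_volume", "save_volume"]


@dataclass
class VolumeImage:
    """A 3D scalar grid with voxel size and index-to-world affine.

    Parameters
    ----------
    voxels:
        3D float array of signal intensities.
    affine:
        4x4 invertible matrix mapping 0-based voxel indices (i, j, k, 1)
        to RAS+ world coordinates in mm.
    """

    voxels: np.ndarray
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.voxels.shape}")
        if self.affine is None:
            self.affine = np.eye(4)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_mm(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the linear part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def index_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to (..., 3) world mm."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Map (..., 3) world mm to fractional voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def world_grid(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape (nx, ny, nz, 3)."""
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"), axis=-1
        )
        return self.index_to_world(idx)

    def center_world(self) -> np.ndarray:
        """World coordinate of the grid centre (rotation centre for registration)."""
        return self.index_to_world((np.asarray(self.shape, float) - 1.0) / 2.0)

    def like(self, voxels: np.ndarray) -> "VolumeImage":
        """A new image on the same grid with different voxel data."""
        return VolumeImage(np.asarray(voxels), self.affine.copy())

    def validate(self) -> None:
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite intensities")


@dataclass
class BrainMask:
    """Binary brain mask on an image's grid."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def as_image(self) -> VolumeImage:
        return VolumeImage(self.data.astype(np.float32), self.affine.copy())


def load_volume(path: str | Path) -> VolumeImage:
    """Read a NIfTI-1 file into a :class:`VolumeImage` (float32 data)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    return VolumeImage(data, np.asarray(img.affine))


def save_volume(img: VolumeImage, path: str | Path, dtype=np.float32) -> None:
    """Write a :class:`VolumeImage` as NIfTI-1, affine in the header."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nii = nib.Nifti1Image(np.asarray(img.voxels, dtype=dtype), img.affine)
    nii.header.set_xyzt_units("mm")
    nib.save(nii, str(path))
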