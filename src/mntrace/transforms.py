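"""Spatial transforms (rigid, affine, dense warp) and pull-back resampling.

Conventions
-----------
* All transforms map world mm -> world mm.
* Resampling is pull-back: the transform argument of :func:`resample` maps
  points of the *target* grid into the *source* image's world frame, and the
  source is interpolated there.  To align a moving image onto a fixed grid,
  pass the moving->fixed registration's *forward* map as estimated by the
  optimisers here (they are already expressed as pull-back maps).
* Chains compose right-to-left and are applied in a single interpolation:
  images are never resampled serially.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .image import VolumeImage

__all__ = [
    "Transform",
    "IdentityTransform",
    "RigidTransform",
    "AffineTransform",
    "WarpTransform",
    "ComposedTransform",
    "resample",
]


class Transform:
    """Base class: a map from world mm points to world mm points."""

    def map_points(self, pts: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def then(self, other: "Transform") -> "ComposedTransform":
        """Return the composition ``other ∘ self`` (self applied first)."""
        return ComposedTransform([other, self])


@dataclass
class IdentityTransform(Transform):
    def map_points(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, dtype=float)

    def inverse(self) -> "IdentityTransform":
        return IdentityTransform()


@dataclass
class RigidTransform(Transform):
    """Rigid body motion: rotate by Euler angles about ``center``, then translate.

    ``map(x) = R (x - c) + c + t`` with R built from extrinsic x-y-z Euler
    angles in degrees.  The rotation matrix is orthonormal with det +1 by
    construction.
    """

    rotation_deg: np.ndarray  # (3,) Euler angles, degrees, extrinsic xyz
    translation_mm: np.ndarray  # (3,)
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation_deg = np.asarray(self.rotation_deg, dtype=float).reshape(3)
        self.translation_mm = np.asarray(self.translation_mm, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)

    @property
    def matrix(self) -> np.ndarray:
        R = Rotation.from_euler("xyz", self.rotation_deg, degrees=True).as_matrix()
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = self.center + self.translation_mm - R @ self.center
        return M

    def map_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        M = self.matrix
        return pts @ M[:3, :3].T + M[:3, 3]

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def rotation_matrix(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @classmethod
    def identity(cls, center=None) -> "RigidTransform":
        return cls(np.zeros(3), np.zeros(3), np.zeros(3) if center is None else center)

    def to_dict(self) -> dict:
        return {
            "kind": "rigid",
            "convention": "euler_xyz_deg_about_center",
            "rotation_deg": self.rotation_deg.tolist(),
            "translation_mm": self.translation_mm.tolist(),
            "center": self.center.tolist(),
        }


@dataclass
class AffineTransform(Transform):
    """General 12-parameter affine as a homogeneous 4x4 matrix."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("affine matrix must be 4x4")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("affine transform is singular")

    def map_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def to_dict(self) -> dict:
        return {"kind": "affine", "matrix": self.matrix.tolist()}


@dataclass
class WarpTransform(Transform):
    """Dense displacement field: ``map(x) = x + u(x)``.

    ``displacement_mm`` holds the world-frame displacement (mm) sampled on a
    grid with affine ``affine``; it is interpolated linearly at query points
    and is zero outside the field of view.  An optional control-point grid
    (the B-spline coefficients the field was built from) is carried along for
    serialisation and diagnostics.
    """

    displacement_mm: np.ndarray  # (nx, ny, nz, 3)
    affine: np.ndarray
    control_points: np.ndarray | None = None
    control_spacing_mm: float | None = None

    def __post_init__(self) -> None:
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=float)
        if self.displacement_mm.ndim != 4 or self.displacement_mm.shape[-1] != 3:
            raise ValueError("displacement field must have shape (nx, ny, nz, 3)")
        self.affine = np.asarray(self.affine, dtype=float)

    def map_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        inv = np.linalg.inv(self.affine)
        idx = pts @ inv[:3, :3].T + inv[:3, 3]
        coords = np.moveaxis(idx, -1, 0)
        disp = np.stack(
            [
                ndimage.map_coordinates(
                    self.displacement_mm[..., d], coords, order=1, mode="constant", cval=0.0
                )
                for d in range(3)
            ],
            axis=-1,
        )
        return pts + disp

    def max_displacement(self) -> float:
        return float(np.abs(self.displacement_mm).max())

    def to_dict(self) -> dict:
        d = {
            "kind": "warp",
            "affine": self.affine.tolist(),
            "shape": list(self.displacement_mm.shape[:3]),
        }
        if self.control_points is not None:
            d["control_points"] = np.asarray(self.control_points).tolist()
            d["control_spacing_mm"] = self.control_spacing_mm
        return d


@dataclass
class ComposedTransform(Transform):
    """Composition; ``transforms`` are applied right-to-left."""

    transforms: list

    def map_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        for t in reversed(self.transforms):
            pts = t.map_points(pts)
        return pts


def resample(
    img: VolumeImage,
    transform: Transform | None,
    target: VolumeImage | None = None,
    interp: str = "linear",
) -> VolumeImage:
    """Pull-back resampling of ``img`` onto ``target``'s grid.

    ``transform`` maps target-grid world points into ``img``'s world frame
    (identity if None).  ``interp`` is "linear" for intensities or "nearest"
    for label volumes; nearest-neighbour never invents label values.
    Out-of-field voxels are set to 0.
    """
    if interp == "linear":
        order = 1
    elif interp == "nearest":
        order = 0
    elif interp == "cubic":
        order = 3
    else:
        raise ValueError(f"unknown interpolation mode: {interp!r}")
    if target is None:
        target = img
    if transform is None:
        transform = IdentityTransform()
    if (
        isinstance(transform, IdentityTransform)
        and target.shape == img.shape
        and np.allclose(target.affine, img.affine)
    ):
        return VolumeImage(np.asarray(img.voxels).copy(), target.affine.copy())
    pts = target.world_grid().reshape(-1, 3)
    src_pts = transform.map_points(pts)
    idx = img.world_to_index(src_pts)
    coords = idx.T
    out = ndimage.map_coordinates(
        np.asarray(img.voxels, dtype=np.float32 if order else img.voxels.dtype),
        coords,
        order=order,
        mode="constant",
        cval=0.0,
    )
    return VolumeImage(out.reshape(target.shape), target.affine.copy())
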