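"""Volume grids, binary masks and NIfTI I/O.

World-coordinate convention used throughout the package: RAS with
``x`` = left->right, ``y`` = posterior->anterior, ``z`` = inferior->superior.
Array axis ``i`` maps to world axis ``i``; the "coronal plane" has unit
normal ``(0, 1, 0)`` (the anterior-posterior axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

CORONAL_NORMAL = np.array([0.0, 1.0, 0.0])


@dataclass
class VolumeGrid:
    """A 3D scalar image with voxel spacing, origin and axis directions in mm.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Scalar image values.
    spacing : ndarray, shape (3,)
        Voxel edge length per axis in mm; strictly positive.
    origin : ndarray, shape (3,)
        World coordinate (mm) of the center of voxel (0, 0, 0).
    direction : ndarray, shape (3, 3)
        Orthonormal matrix whose columns are the world directions of the
        array axes. Identity for axis-aligned RAS grids.
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = None  # type: ignore[assignment]
    direction: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be 3 positive floats")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.direction is None:
            self.direction = np.eye(3)
        self.direction = np.asarray(self.direction, dtype=float)
        if not np.allclose(self.direction @ self.direction.T, np.eye(3), atol=1e-6):
            raise ValueError("direction must be orthonormal within 1e-6")

    # ------------------------------------------------------------------ #
    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (voxel centers)."""
        aff = np.eye(4)
        aff[:3, :3] = self.direction @ np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        pts = idx @ (self.direction @ np.diag(self.spacing)).T + self.origin
        return pts if pts.shape[0] > 1 else pts[0]

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        m = np.linalg.inv(self.direction @ np.diag(self.spacing))
        idx = (pts - self.origin) @ m.T
        return idx if idx.shape[0] > 1 else idx[0]

    def same_grid(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )

    def with_voxels(self, voxels: np.ndarray) -> "VolumeGrid":
        """Same geometry, new values."""
        if voxels.shape != self.shape:
            raise ValueError("voxel array shape must match the grid")
        return VolumeGrid(voxels, self.spacing.copy(), self.origin.copy(), self.direction.copy())

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    # ------------------------------------------------------------------ #
    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.voxels, dtype=np.float32), self.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))


class BinaryMask(VolumeGrid):
    """A {0,1} labelling on a VolumeGrid."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.voxels)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be in {0, 1}")
        self.voxels = self.voxels.astype(np.uint8)

    @property
    def volume_mm3(self) -> float:
        return float(self.voxels.sum()) * self.voxel_volume

    def with_voxels(self, voxels: np.ndarray) -> "BinaryMask":
        if voxels.shape != self.shape:
            raise ValueError("voxel array shape must match the grid")
        return BinaryMask(voxels, self.spacing.copy(), self.origin.copy(), self.direction.copy())

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.voxels, dtype=np.uint8), self.affine)


def _from_nifti(img: nib.Nifti1Image, cls):
    data = np.asarray(img.dataobj)
    aff = img.affine
    lin = aff[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    direction = lin / spacing
    return cls(data, spacing, aff[:3, 3], direction)


def load_volume(path) -> VolumeGrid:
    return _from_nifti(nib.load(str(path)), VolumeGrid)


def load_mask(path) -> BinaryMask:
    img = nib.load(str(path))
    data = (np.asarray(img.dataobj) > 0.5).astype(np.uint8)
    aff = img.affine
    lin = aff[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    return BinaryMask(data, spacing, aff[:3, 3], lin / spacing)
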