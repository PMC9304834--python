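"""Voxel grid plumbing shared by all volumetric stages.

A :class:`VoxelGrid` couples an array shape with a voxel-to-millimetre affine
(RAS+ convention) and a boolean analysis mask. Coordinates are world
millimetres everywhere in the public API; voxelization happens only here.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VoxelGrid", "mni_grid"]


@dataclass
class VoxelGrid:
    shape: tuple[int, int, int]
    affine: np.ndarray  # 4x4 voxel -> mm
    mask: np.ndarray = field(default=None)  # bool, same shape

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if self.mask is None:
            self.mask = np.ones(self.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.shape:
            raise ValueError("mask shape mismatch")
        if not self.mask.any():
            raise ValueError("mask is empty")
        self._inv = np.linalg.inv(self.affine)

    # -- coordinate transforms ------------------------------------------------
    def mm_to_voxel(self, pts_mm: np.ndarray) -> np.ndarray:
        """Map mm coordinates to continuous voxel coordinates."""
        pts = np.atleast_2d(np.asarray(pts_mm, dtype=float))
        out = pts @ self._inv[:3, :3].T + self._inv[:3, 3]
        return out if np.asarray(pts_mm).ndim == 2 else out[0]

    def voxel_to_mm(self, idx: np.ndarray) -> np.ndarray:
        """Map (continuous or integer) voxel coordinates to mm."""
        v = np.atleast_2d(np.asarray(idx, dtype=float))
        out = v @ self.affine[:3, :3].T + self.affine[:3, 3]
        return out if np.asarray(idx).ndim == 2 else out[0]

    def nearest_voxel(self, pt_mm) -> tuple[int, int, int] | None:
        """Integer voxel containing a mm point, or None outside the array."""
        v = np.rint(self.mm_to_voxel(pt_mm)).astype(int)
        if np.any(v < 0) or np.any(v >= np.asarray(self.shape)):
            return None
        return tuple(v)

    def in_mask(self, pt_mm) -> bool:
        v = self.nearest_voxel(pt_mm)
        return v is not None and bool(self.mask[v])

    @property
    def spacing(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_centers_mm(self, indices: np.ndarray | None = None) -> np.ndarray:
        """mm centers of the given N x 3 integer indices (default: mask voxels)."""
        if indices is None:
            indices = np.argwhere(self.mask)
        return self.voxel_to_mm(np.asarray(indices, dtype=float))

    # -- I/O -------------------------------------------------------------------
    def to_nifti(self, values: np.ndarray, dtype=np.float32) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(values, dtype=dtype), self.affine)

    @classmethod
    def from_nifti(cls, img: "nib.Nifti1Image | str", mask_threshold: float = 0.0) -> "VoxelGrid":
        if isinstance(img, str):
            img = nib.load(img)
        data = np.asanyarray(img.dataobj)
        if data.ndim > 3:
            data = data[..., 0]
        return cls(shape=data.shape, affine=img.affine, mask=data > mask_threshold)


def mni_grid(spacing_mm: float = 2.0, shape: tuple[int, int, int] | None = None,
             ellipsoid_mask: bool = True) -> VoxelGrid:
    """Default MNI-like bounding-box grid with an inscribed ellipsoidal brain mask.

    The box spans roughly [-90, 90] x [-126, 90] x [-72, 108] mm, the usual
    2 mm template extent, scaled to the requested spacing.
    """
    if shape is None:
        shape = tuple(int(round(e / spacing_mm)) + 1 for e in (180, 216, 180))
    affine = np.diag([spacing_mm, spacing_mm, spacing_mm, 1.0])
    affine[:3, 3] = (-90.0, -126.0, -72.0)
    grid = VoxelGrid(shape=shape, affine=affine, mask=np.ones(shape, bool))
    if ellipsoid_mask:
        idx = np.indices(shape).reshape(3, -1).T
        mm = grid.voxel_to_mm(idx.astype(float))
        center = np.array([0.0, -18.0, 18.0])
        radii = np.array([80.0, 100.0, 85.0])
        inside = (((mm - center) / radii) ** 2).sum(axis=1) <= 1.0
        grid.mask = inside.reshape(shape)
    return grid
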