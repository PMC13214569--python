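"""Shared volumetric data containers.

All volumes are 3D scalar (or integer label) arrays with a 4x4 voxel-to-world
affine in RAS millimetres.  Voxel indices are 0-based and refer to voxel
centers; world coordinates are obtained by applying the affine to the index
vector.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np


def affine_voxel_size(affine: np.ndarray) -> np.ndarray:
    """Column norms of the 3x3 block: the voxel spacing in mm."""
    return np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)


@dataclass
class ImageVolume:
    """A 3D scalar image with geometry and an optional validity mask.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Scalar intensities in arbitrary units.
    affine : ndarray, shape (4, 4)
        Voxel-to-world map (mm, RAS).
    mask : ndarray of bool, optional
        Valid voxels; same grid shape as ``voxels``.
    """

    voxels: np.ndarray
    affine: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel sizes must be positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.voxels.shape:
                raise ValueError("mask shape must match voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        return affine_voxel_size(self.affine)

    def world_coords(self) -> np.ndarray:
        """(3, nx, ny, nz) array of world coordinates of voxel centers."""
        idx = np.indices(self.shape, dtype=float)
        return apply_affine(self.affine, idx)

    @classmethod
    def from_nifti(cls, path, reorient: bool = True) -> "ImageVolume":
        img = nib.load(str(path))
        if reorient:
            img = nib.as_closest_canonical(img)
        data = np.asarray(img.dataobj, dtype=np.float64)
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        return cls(voxels=data, affine=np.asarray(img.affine))

    def to_nifti(self, path) -> None:
        nib.save(nib.Nifti1Image(np.asarray(self.voxels), self.affine), str(path))


def apply_affine(affine: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Apply a 4x4 affine to coordinates of shape (3, ...)."""
    A = np.asarray(affine)
    out = np.tensordot(A[:3, :3], coords, axes=(1, 0))
    return out + A[:3, 3].reshape(3, 1, 1, 1) if coords.ndim == 4 else (
        out + A[:3, 3].reshape((3,) + (1,) * (coords.ndim - 1))
    )


@dataclass
class CoarseSegmentation:
    """Whole-brain labels at ~1 mm following a fixed semantic protocol.

    ``protocol`` maps each nonzero label id to its structure name; label 0 is
    background by convention.
    """

    labels: np.ndarray
    affine: np.ndarray
    protocol: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.protocol)
        if missing:
            raise ValueError(f"labels missing from protocol: {sorted(missing)}")

    @property
    def voxel_size(self) -> np.ndarray:
        return affine_voxel_size(self.affine)

    def name_to_id(self) -> dict[str, int]:
        return {v: k for k, v in self.protocol.items()}

    @classmethod
    def from_nifti(cls, path, protocol: dict[int, str]) -> "CoarseSegmentation":
        img = nib.as_closest_canonical(nib.load(str(path)))
        data = np.asarray(img.dataobj)
        return cls(labels=np.rint(data).astype(np.int32), affine=np.asarray(img.affine),
                   protocol=protocol)

    def to_nifti(self, path) -> None:
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), self.affine), str(path))


def resample_to_grid(values: np.ndarray, src_affine: np.ndarray,
                     dst_shape: tuple[int, int, int], dst_affine: np.ndarray,
                     order: int = 1, cval: float = 0.0) -> np.ndarray:
    """Resample ``values`` onto a destination grid by interpolation in voxel space."""
    from scipy.ndimage import map_coordinates

    M = np.linalg.inv(src_affine) @ dst_affine
    idx = np.indices(dst_shape, dtype=float)
    src = np.tensordot(M[:3, :3], idx, axes=(1, 0)) + M[:3, 3].reshape(3, 1, 1, 1)
    return map_coordinates(np.asarray(values, dtype=float), src, order=order,
                           mode="constant", cval=cval)
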