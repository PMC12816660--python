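"""Voxel-grid images: the shared carrier for masks, statistical maps and densities.

A :class:`VoxelImage` is a plain 3D array plus a voxel-to-world affine, thin
enough to build from any source and to round-trip through NIfTI-1 via
nibabel. Binary masks are stored as uint8, statistical maps as float32.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VoxelImage", "dice_coefficient", "overlap_fractions"]


@dataclass
class VoxelImage:
    """A 3D scalar or label volume with a voxel-to-world affine.

    Parameters
    ----------
    data : ndarray, shape (i, j, k)
        Scalar, binary or integer-label volume.
    affine : ndarray, shape (4, 4)
        Invertible voxel-to-world (mm) transform.
    space_tag : str
        Free-text label of the coordinate frame (e.g. ``"synthetic-2mm"``).
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    space_tag: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def same_grid(self, other: "VoxelImage", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=atol)

    def is_binary(self) -> bool:
        return bool(np.isin(self.data, (0, 1)).all())

    def world_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        """Map world-mm points (N, 3) to continuous voxel coordinates."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    # -- NIfTI round-trip ---------------------------------------------------

    def to_nifti(self) -> nib.Nifti1Image:
        data = self.data
        if self.is_binary():
            data = data.astype(np.uint8)
        elif np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float32)
        img = nib.Nifti1Image(data, self.affine)
        if self.space_tag:
            img.header["descrip"] = self.space_tag.encode()[:79]
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path, space_tag: str = "") -> "VoxelImage":
        img = nib.load(str(path))
        tag = space_tag or img.header["descrip"].tobytes().split(b"\x00")[0].decode(errors="ignore")
        return cls(np.asanyarray(img.dataobj), np.asarray(img.affine), tag)

    @classmethod
    def zeros_like(cls, other: "VoxelImage", dtype=float) -> "VoxelImage":
        return cls(np.zeros(other.shape, dtype=dtype), other.affine.copy(), other.space_tag)

    def with_data(self, data: np.ndarray) -> "VoxelImage":
        return VoxelImage(data, self.affine.copy(), self.space_tag)


def dice_coefficient(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|); defined as 0.0 when both masks are empty."""
    a = np.asarray(mask_a) > 0
    b = np.asarray(mask_b) > 0
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def overlap_fractions(mask_a: np.ndarray, mask_b: np.ndarray) -> tuple[float, float, float]:
    """(Dice, fraction of A inside B, fraction of B inside A)."""
    a = np.asarray(mask_a) > 0
    b = np.asarray(mask_b) > 0
    inter = float(np.logical_and(a, b).sum())
    fa = inter / a.sum() if a.sum() else 0.0
    fb = inter / b.sum() if b.sum() else 0.0
    return dice_coefficient(a, b), float(fa), float(fb)
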