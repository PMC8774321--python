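"""Volumetric containers and NIfTI-1 input/output.

All downstream geometry is computed in physical units: voxel spacing is
carried in millimetres and every surface area / volume the package reports
is in mm^2 / mm^3.  Image orientation (the rotational part of the affine)
is irrelevant to sphericity scores and is preserved on write but otherwise
ignored.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import VolumeIOError

__all__ = [
    "VoxelGrid",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "voxel_volume",
]


def _validate_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError(f"spacing must have 3 components, got {len(spacing)}")
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValueError(f"spacing components must be strictly positive, got {spacing}")
    return spacing


@dataclass(frozen=True)
class VoxelGrid:
    """A 3-D scalar field (PET SUV or CT intensity) with anisotropic spacing.

    Parameters
    ----------
    values:
        Rank-3 array of voxel values.
    spacing:
        Millimetres per voxel along each array axis; all strictly positive.
    origin:
        Physical position of voxel (0, 0, 0) in mm.  Informational only.
    affine:
        Optional full 4x4 voxel-to-world affine kept for lossless re-export.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    affine: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise ValueError(f"expected 3-D volume, got {values.ndim}-D array")
        if min(values.shape) < 1:
            raise ValueError(f"every dimension must be >= 1, got shape {values.shape}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", _validate_spacing(self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class BinaryMask:
    """A boolean field sharing a :class:`VoxelGrid`'s geometry."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    affine: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise ValueError(f"expected 3-D mask, got {values.ndim}-D array")
        object.__setattr__(self, "values", values.astype(bool))
        object.__setattr__(self, "spacing", _validate_spacing(self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def count(self) -> int:
        """Number of selected voxels."""
        return int(np.count_nonzero(self.values))

    def same_geometry(self, other) -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


def voxel_volume(grid: VoxelGrid | BinaryMask) -> float:
    """Physical voxel volume in mm^3 (product of the spacing triple)."""
    return grid.voxel_volume


def read_volume(path: str | os.PathLike, clip_negative: bool = False) -> VoxelGrid:
    """Read a NIfTI-1 volume.

    Spacing is taken from the header zooms.  ``clip_negative=True`` clips
    values below zero to zero at load time; use it for PET images so that
    reconstruction noise cannot contaminate the strictly-positive SUV mean.
    """
    if not os.path.exists(path):
        raise VolumeIOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeIOError(f"could not read {path} as NIfTI: {exc}") from exc
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeIOError(f"expected 3-D volume, got {data.ndim}-D image in {path}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise VolumeIOError(f"non-positive voxel spacing {zooms} in {path}")
    if clip_negative:
        data = np.clip(data, 0.0, None)
    affine = np.asarray(img.affine, dtype=np.float64)
    origin = tuple(float(x) for x in affine[:3, 3])
    return VoxelGrid(values=data, spacing=tuple(float(z) for z in zooms),
                     origin=origin, affine=affine)


def read_mask(path: str | os.PathLike) -> BinaryMask:
    """Read a NIfTI-1 mask; any non-zero voxel counts as selected."""
    grid = read_volume(path)
    return BinaryMask(values=grid.values > 0, spacing=grid.spacing,
                      origin=grid.origin, affine=grid.affine)


def _default_affine(spacing, origin) -> np.ndarray:
    affine = np.diag(list(spacing) + [1.0])
    affine[:3, 3] = origin
    return affine


def write_volume(grid: VoxelGrid | BinaryMask, path: str | os.PathLike) -> None:
    """Write a grid (float32) or mask (uint8 with values {0,1}) as NIfTI-1.

    Round-trip with :func:`read_volume` preserves spacing exactly and values
    to float32 precision.
    """
    if isinstance(grid, BinaryMask):
        data = grid.values.astype(np.uint8)
    else:
        data = grid.values.astype(np.float32)
    affine = grid.affine if grid.affine is not None else _default_affine(grid.spacing, grid.origin)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(grid.spacing)
    parent = os.path.dirname(os.path.abspath(str(path)))
    if not os.path.isdir(parent):
        raise VolumeIOError(f"parent directory does not exist: {parent}")
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise VolumeIOError(f"could not write {path}: {exc}") from exc
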