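"""Amyloid VOI extraction from PET and a brain mask from CT.

The amyloid volume of interest (VOI) is the set of PET voxels at or above
``k`` times the SUV mean, where the SUV mean is the arithmetic mean of the
strictly positive voxels of the image.  ``k = 6`` is the operating point at
which the score separates amyloid-positive from amyloid-negative scans best
on clinical images; it is exposed as a parameter throughout.

The CT brain mask here is a deliberately simple intensity-window stub
(soft-tissue Hounsfield window, largest connected component, hole filling).
Users with a proper parenchyma segmentation should supply their own mask
file instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import EmptyMaskError, ShapeFeatureError
from .grid import BinaryMask, VoxelGrid

__all__ = [
    "SUVStats",
    "compute_suv_mean",
    "threshold_voi",
    "filter_components",
    "brain_mask_from_ct",
]

# 26-neighbourhood: the VOI is treated as a solid, so diagonal contacts connect
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class SUVStats:
    """Non-zero SUV mean of a PET grid and the derived threshold k * mean."""

    suv_mean_nonzero: float
    k: float
    source_shape: tuple[int, int, int]

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError(f"threshold multiple k must be > 0, got {self.k}")
        if self.suv_mean_nonzero < 0:
            raise ValueError("SUV mean cannot be negative")

    @property
    def threshold(self) -> float:
        return self.k * self.suv_mean_nonzero


def compute_suv_mean(pet: VoxelGrid, k: float = 6.0) -> SUVStats:
    """Mean of the strictly positive PET voxels, with threshold multiple ``k``.

    Zeros (and any negative values) are excluded from the mean.  Raises
    :class:`EmptyMaskError` when the grid has no positive voxel.
    """
    positive = pet.values[pet.values > 0]
    if positive.size == 0:
        raise EmptyMaskError("no positive voxels: cannot compute the non-zero SUV mean")
    return SUVStats(suv_mean_nonzero=float(positive.mean()), k=float(k),
                    source_shape=pet.shape)


def threshold_voi(pet: VoxelGrid, stats: SUVStats) -> BinaryMask:
    """Voxels with value >= ``stats.threshold`` (inclusive comparison).

    The result may be empty; callers decide whether that is an error.
    """
    if stats.source_shape != pet.shape:
        raise ShapeFeatureError(
            f"SUV stats were computed on shape {stats.source_shape}, "
            f"but grid has shape {pet.shape}"
        )
    return BinaryMask(values=pet.values >= stats.threshold, spacing=pet.spacing,
                      origin=pet.origin, affine=pet.affine)


def filter_components(mask: BinaryMask, min_voxels: int = 0) -> BinaryMask:
    """Drop 26-connected components with fewer than ``min_voxels`` voxels.

    ``min_voxels = 0`` (and 1) is the identity.  Never increases the voxel
    count and is idempotent.
    """
    if min_voxels < 0:
        raise ValueError("min_voxels must be >= 0")
    if min_voxels <= 1 or not mask.values.any():
        return mask
    labels, n = ndimage.label(mask.values, structure=_STRUCT_26)
    if n == 0:
        return mask
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts >= min_voxels)
    keep = keep[keep != 0]  # label 0 is background
    kept = np.isin(labels, keep)
    return BinaryMask(values=kept, spacing=mask.spacing, origin=mask.origin,
                      affine=mask.affine)


def brain_mask_from_ct(ct: VoxelGrid, low: float = 0.0, high: float = 80.0) -> BinaryMask:
    """Brain-parenchyma mask from CT by a soft-tissue intensity window.

    Voxels with ``low <= value <= high`` are selected, the largest
    26-connected component is kept, and internal holes are filled in 3-D.
    The window defaults to the 0-80 HU soft-tissue range, which excludes
    both air (about -1000 HU) and bone (well above 100 HU).
    """
    window = (ct.values >= low) & (ct.values <= high)
    if not window.any():
        raise EmptyMaskError(
            f"no brain-like tissue found in window [{low}, {high}]"
        )
    labels, n = ndimage.label(window, structure=_STRUCT_26)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    largest = counts.argmax()
    brain = ndimage.binary_fill_holes(labels == largest)
    return BinaryMask(values=brain, spacing=ct.spacing, origin=ct.origin,
                      affine=ct.affine)
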