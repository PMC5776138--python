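"""Brain-volume morphometry from autofluorescence scans.

The autofluorescent brain contour is segmented by a global intensity
threshold (fixed value or Otsu), optionally cleaned to the largest
26-connected component, and the brain (or any box-ROI-restricted
structure) volume is the true-voxel count times the voxel volume.  This is
a transparent, parameter-explicit reimplementation of what commercial
volumetric renderers do behind closed settings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .voldata import INTENSITY_MAX, BoxROI, ChannelVolume, VoxelGeometry

__all__ = ["BrainMask", "segment_brain", "mask_volume", "roi_mask_volume"]

_CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(eq=False)
class BrainMask:
    """Binary segmentation of the brain with its provenance parameters."""

    mask: np.ndarray
    threshold: float
    largest_component: bool

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("BrainMask must be 3-D")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def segment_brain(
    volume: ChannelVolume,
    threshold: Union[float, int, str] = "otsu",
    largest_component_only: bool = False,
) -> BrainMask:
    """Threshold-segment a (typically autofluorescence) volume.

    With an explicit threshold the mask is ``intensity >= threshold``;
    ``threshold="otsu"`` picks the cut from the full-volume histogram and
    keeps intensities strictly above it (the Otsu convention).  A constant
    (e.g. all-zero) volume yields an empty mask rather than an error.  With
    ``largest_component_only`` the largest 26-connected component is kept.
    """
    arr = volume.intensities
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold method {threshold!r}")
        if int(arr.min()) == int(arr.max()):
            # degenerate: no foreground/background separation exists
            return BrainMask(
                mask=np.zeros(arr.shape, dtype=bool),
                threshold=float(arr.max()),
                largest_component=largest_component_only,
            )
        thr = float(threshold_otsu(arr))
        mask = arr > thr
    else:
        thr = float(threshold)
        if not 0 <= thr <= INTENSITY_MAX:
            raise ValueError(f"threshold {thr} outside [0, {INTENSITY_MAX}]")
        mask = arr >= thr
    if largest_component_only and mask.any():
        labels, n = ndimage.label(mask, structure=_CONNECTIVITY_26)
        if n > 1:
            sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
            mask = labels == (int(np.argmax(sizes)) + 1)
    return BrainMask(mask=mask, threshold=thr, largest_component=largest_component_only)


def mask_volume(mask: BrainMask, geometry: VoxelGeometry) -> float:
    """Volume of the mask in um^3: true-voxel count x voxel volume."""
    return mask.n_voxels * geometry.voxel_volume_um3


def roi_mask_volume(mask: BrainMask, roi: BoxROI, geometry: VoxelGeometry) -> float:
    """Volume of the mask restricted to a box ROI, in um^3."""
    roi.validate(mask.mask.shape)  # type: ignore[arg-type]
    return int(mask.mask[roi.slices()].sum()) * geometry.voxel_volume_um3
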