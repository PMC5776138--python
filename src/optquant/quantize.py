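"""16-bin intensity quantizer and pixel-to-volume conversion.

The 16-bit intensity range is divided into 16 equal bins of width 4,096
(the FIJI "16 colors" view of a 16-bit image).  Bin 0 — the black bin —
holds intensities below 4,096 and is excluded from volume quantification;
the remaining 15 "non-black" bins, labeled by their lower edges (4,096,
8,192, ..., 61,440), carry the signal.  The top bin additionally absorbs
65,535 since 16 x 4,096 exceeds the representable maximum by one.

Summed bin counts convert to EdU-positive volume through the isotropic
voxel volume (``pixel_size_um ** 3``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Union

import numpy as np

from .voldata import INTENSITY_MAX, VoxelGeometry

__all__ = [
    "N_BINS",
    "BIN_WIDTH",
    "BinCounts",
    "bin_of",
    "bin_lower_edge",
    "nonblack_bins",
    "count_bins",
    "voxel_volume",
    "pixels_to_volume",
]

N_BINS = 16
BIN_WIDTH = 4096


def _validate_domain(arr: np.ndarray) -> None:
    if arr.size == 0:
        return
    lo, hi = int(arr.min()), int(arr.max())
    if lo < 0 or hi > INTENSITY_MAX:
        bad = lo if lo < 0 else hi
        raise ValueError(f"intensity {bad} outside [0, {INTENSITY_MAX}]")


def bin_of(intensity: Union[int, np.ndarray]) -> Union[int, np.ndarray]:
    """Bin index of an intensity: floor(intensity / 4096), clamped to 15.

    Accepts a scalar or an array; out-of-domain values raise.
    """
    arr = np.asarray(intensity)
    _validate_domain(arr)
    idx = np.minimum(arr.astype(np.int64) // BIN_WIDTH, N_BINS - 1)
    if np.isscalar(intensity) or arr.ndim == 0:
        return int(idx)
    return idx


def bin_lower_edge(index: int) -> int:
    """Lower intensity edge of a bin (bins are labeled by this value)."""
    if not 0 <= index < N_BINS:
        raise ValueError(f"bin index {index} outside 0..{N_BINS - 1}")
    return index * BIN_WIDTH


def nonblack_bins() -> List[int]:
    """The 15 non-black bin indices, 1..15, in ascending order."""
    return list(range(1, N_BINS))


@dataclass(frozen=True)
class BinCounts:
    """Per-bin pixel counts from the 16-bin quantizer."""

    counts: np.ndarray  # shape (16,), non-negative integers
    n_pixels: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (N_BINS,):
            raise ValueError(f"counts must have shape ({N_BINS},), got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("bin counts must be non-negative")
        if int(counts.sum()) != int(self.n_pixels):
            raise ValueError(
                f"counts sum {int(counts.sum())} != n_pixels {int(self.n_pixels)}"
            )
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "n_pixels", int(self.n_pixels))

    def total(self, bins_used: Sequence[int] | None = None) -> int:
        """Summed pixel count over ``bins_used`` (default: all 15 non-black)."""
        if bins_used is None:
            bins_used = nonblack_bins()
        return int(self.counts[list(bins_used)].sum())

    def __add__(self, other: "BinCounts") -> "BinCounts":
        return BinCounts(self.counts + other.counts, self.n_pixels + other.n_pixels)


def count_bins(region: Union[Iterable[int], np.ndarray]) -> BinCounts:
    """Histogram a region of intensities into the 16 fixed bins."""
    arr = np.asarray(list(region) if not isinstance(region, np.ndarray) else region)
    arr = arr.reshape(-1)
    if arr.size and not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise ValueError("intensities must be integers")
        arr = arr.astype(np.int64)
    _validate_domain(arr)
    idx = np.minimum(arr.astype(np.int64) // BIN_WIDTH, N_BINS - 1)
    counts = np.bincount(idx, minlength=N_BINS)
    return BinCounts(counts=counts, n_pixels=int(arr.size))


def voxel_volume(geometry: VoxelGeometry) -> float:
    """Volume of one isotropic voxel in um^3 (pixel edge length cubed)."""
    return geometry.voxel_volume_um3


def pixels_to_volume(count: int, geometry: VoxelGeometry) -> float:
    """Convert a pixel (voxel) count to volume in um^3."""
    if count < 0:
        raise ValueError(f"count must be >= 0, got {count}")
    return float(count) * voxel_volume(geometry)
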