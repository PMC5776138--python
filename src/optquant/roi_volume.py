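"""Structure and Slice Analysis: EdU-positive volume within ROIs.

Structure Analysis bins every voxel of a box ROI across its full A-P depth
into the 16 fixed intensity bins and sums the counts over the 15 non-black
bins (default) before converting to um^3.  Slice Analysis instead samples
every Nth A-P section (default every 5th) of a neurogenic niche, counts
only pixels inside that section's hand-drawn mask, and by default restricts
to the first three non-black bins (lower edges 4,096 / 8,192 / 12,288) —
the low-intensity regime that favors niche stem-cell labeling over bright
immune-cell infiltrate.

Reported slice volumes are of the sampled voxels only (a 1-in-N sample);
an optional ``extrapolate`` flag multiplies by the stride for whole-niche
estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .quantize import BinCounts, N_BINS, count_bins, nonblack_bins, pixels_to_volume
from .voldata import BoxROI, BrainSample, NicheROI

__all__ = ["VolumeResult", "structure_volume", "slice_volume", "results_to_frame"]

DEFAULT_SLICE_BINS: Tuple[int, int, int] = (1, 2, 3)


@dataclass(frozen=True)
class VolumeResult:
    """EdU-positive volume for one sample in one ROI."""

    sample_id: str
    group: str
    roi: str
    analysis: str  # "structure" | "slice"
    bins_used: Tuple[int, ...]
    pixel_count: int
    volume_um3: float
    bin_counts: BinCounts


def _check_bins(bins_used: Optional[Sequence[int]], default: Sequence[int]) -> Tuple[int, ...]:
    bins = tuple(sorted({int(b) for b in (default if bins_used is None else bins_used)}))
    if not bins:
        raise ValueError("bins_used must be a non-empty subset of the non-black bins")
    if any(b < 1 or b >= N_BINS for b in bins):
        raise ValueError(f"bins_used must lie within 1..{N_BINS - 1}, got {bins}")
    return bins


def structure_volume(
    sample: BrainSample,
    channel: str,
    roi: BoxROI,
    bins_used: Optional[Sequence[int]] = None,
    roi_name: str = "roi",
) -> VolumeResult:
    """Structure Analysis over the full z-depth of a box ROI.

    Default ``bins_used`` is all 15 non-black bins.
    """
    bins = _check_bins(bins_used, nonblack_bins())
    volume = sample.channel(channel)
    roi.validate(volume.shape)
    counts = count_bins(volume.intensities[roi.slices()])
    pixel_count = counts.total(bins)
    return VolumeResult(
        sample_id=sample.sample_id,
        group=sample.group,
        roi=roi_name,
        analysis="structure",
        bins_used=bins,
        pixel_count=pixel_count,
        volume_um3=pixels_to_volume(pixel_count, sample.geometry),
        bin_counts=counts,
    )


def slice_volume(
    sample: BrainSample,
    channel: str,
    niche: NicheROI,
    bins_used: Optional[Sequence[int]] = None,
    roi_name: str = "niche",
    extrapolate: bool = False,
) -> VolumeResult:
    """Slice Analysis over every ``stride``-th section of a niche ROI.

    Sampling starts at the first section of the niche's A-P interval.  Each
    sampled section must carry a mask; only pixels inside the mask are
    binned.  Default ``bins_used`` is the first three non-black bins.
    ``extrapolate=True`` scales the sampled count by the stride to estimate
    the whole-niche volume.
    """
    bins = _check_bins(bins_used, DEFAULT_SLICE_BINS)
    volume = sample.channel(channel)
    niche.validate(volume.shape)
    counts = BinCounts(np.zeros(N_BINS, dtype=np.int64), 0)
    for ap_index in niche.sampled_indices():
        if ap_index not in niche.masks:
            raise ValueError(f"sampled slice {ap_index} has no mask")
        mask = niche.masks[ap_index]
        counts = counts + count_bins(volume.intensities[ap_index][mask])
    pixel_count = counts.total(bins)
    if extrapolate:
        pixel_count *= niche.stride
    return VolumeResult(
        sample_id=sample.sample_id,
        group=sample.group,
        roi=roi_name,
        analysis="slice",
        bins_used=bins,
        pixel_count=pixel_count,
        volume_um3=pixels_to_volume(pixel_count, sample.geometry),
        bin_counts=counts,
    )


def results_to_frame(
    results: Sequence[VolumeResult], per_bin: bool = False
) -> pd.DataFrame:
    """Tabulate VolumeResults (CSV schema:
    ``sample_id,group,roi,analysis,bins_used,pixel_count,volume_um3``),
    optionally with the 16 per-bin counts as extra columns."""
    rows = []
    for r in results:
        row = {
            "sample_id": r.sample_id,
            "group": r.group,
            "roi": r.roi,
            "analysis": r.analysis,
            "bins_used": "+".join(str(b) for b in r.bins_used),
            "pixel_count": r.pixel_count,
            "volume_um3": r.volume_um3,
        }
        if per_bin:
            for i in range(N_BINS):
                row[f"bin_{i}"] = int(r.bin_counts.counts[i])
        rows.append(row)
    return pd.DataFrame(rows)
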