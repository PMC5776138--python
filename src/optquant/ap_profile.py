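"""Histogram Analysis: the anterior-posterior EdU intensity profile.

The volume is maximum-projected through the horizontal plane, a threshold
mask keeps non-black pixels only (intensity > 0), and the projection is cut
along the A-P axis into fixed-width segments (default 20 um).  Each
segment's mean intensity over its masked pixels proxies the local EdU
signal; per-segment means are then averaged across age-matched specimens
(anterior-end alignment, truncation to the shortest profile) and can be
expressed as percent change from a control group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .voldata import BrainSample, VoxelGeometry, max_project_horizontal

__all__ = [
    "SegmentInterval",
    "APProfile",
    "GroupProfile",
    "PercentChange",
    "nonblack_mask",
    "segment_boundaries",
    "sample_profile",
    "group_profile",
    "percent_change",
]


def nonblack_mask(image: np.ndarray) -> np.ndarray:
    """Boolean mask that is true exactly where intensity > 0."""
    arr = np.asarray(image)
    if arr.size and (int(arr.min()) < 0 or int(arr.max()) > 65535):
        raise ValueError("intensities outside [0, 65535]")
    return arr > 0


@dataclass(frozen=True)
class SegmentInterval:
    """One A-P segment: half-open pixel interval plus its span in um."""

    index: int
    start_px: int
    stop_px: int
    start_um: float
    stop_um: float
    partial: bool  # trailing segment whose tissue span is < segment_um


def segment_boundaries(
    n_ap_pixels: int,
    geometry: VoxelGeometry,
    segment_um: float = 20.0,
) -> List[SegmentInterval]:
    """Cut ``n_ap_pixels`` A-P pixels into fixed-width segments.

    The pixel whose anterior edge sits at ``i * pixel_size_um`` belongs to
    segment ``floor(i * pixel_size_um / segment_um)``.  Intervals are
    contiguous, cover every pixel, and the trailing partial segment is
    retained with ``partial=True``.
    """
    if n_ap_pixels < 1:
        raise ValueError(f"n_ap_pixels must be >= 1, got {n_ap_pixels}")
    if not segment_um > 0:
        raise ValueError(f"segment_um must be > 0, got {segment_um}")
    px = geometry.pixel_size_um
    seg_of = np.floor(np.arange(n_ap_pixels) * px / segment_um).astype(int)
    intervals: List[SegmentInterval] = []
    for seg_index in range(seg_of[-1] + 1):
        members = np.nonzero(seg_of == seg_index)[0]
        if members.size == 0:  # cannot happen for segment_um >= px, kept for safety
            continue
        start, stop = int(members[0]), int(members[-1]) + 1
        covered_um = min(n_ap_pixels * px, (seg_index + 1) * segment_um)
        partial = covered_um - seg_index * segment_um < segment_um - 1e-9
        intervals.append(
            SegmentInterval(
                index=len(intervals),
                start_px=start,
                stop_px=stop,
                start_um=start * px,
                stop_um=stop * px,
                partial=partial,
            )
        )
    return intervals


@dataclass
class APProfile:
    """Per-segment mean EdU intensity along the A-P axis of one specimen."""

    segment_um: float
    intervals: List[SegmentInterval]
    mean_intensity: np.ndarray
    n_nonblack: np.ndarray
    sample_id: Optional[str] = None
    group: Optional[str] = None

    def __len__(self) -> int:
        return len(self.intervals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "group": self.group,
                "segment_index": [iv.index for iv in self.intervals],
                "ap_start_um": [iv.start_um for iv in self.intervals],
                "ap_stop_um": [iv.stop_um for iv in self.intervals],
                "mean_intensity": self.mean_intensity,
                "n_nonblack": self.n_nonblack,
            }
        )


def sample_profile(
    sample: BrainSample,
    channel: str = "edu",
    segment_um: float = 20.0,
    include_zero_pixels: bool = False,
) -> APProfile:
    """A-P intensity profile of one specimen.

    The channel is horizontally max-projected and masked to non-black
    pixels; each segment's mean is taken over masked pixels within its A-P
    columns.  Segments without any non-black pixel report mean 0 so that
    profiles stay plottable and comparable.  ``include_zero_pixels`` is a
    documented toggle that averages over every pixel of the segment
    instead (mask-then-mean is the default reading of the workflow).
    """
    volume = sample.channel(channel)
    projection = max_project_horizontal(volume)
    mask = nonblack_mask(projection)
    intervals = segment_boundaries(projection.shape[0], sample.geometry, segment_um)
    means = np.zeros(len(intervals))
    counts = np.zeros(len(intervals), dtype=np.int64)
    for i, iv in enumerate(intervals):
        block = projection[iv.start_px : iv.stop_px]
        block_mask = mask[iv.start_px : iv.stop_px]
        counts[i] = int(block_mask.sum())
        if include_zero_pixels:
            means[i] = float(block.mean())
        elif counts[i] > 0:
            means[i] = float(block[block_mask].mean())
    return APProfile(
        segment_um=float(segment_um),
        intervals=intervals,
        mean_intensity=means,
        n_nonblack=counts,
        sample_id=sample.sample_id,
        group=sample.group,
    )


@dataclass
class GroupProfile:
    """Per-segment mean (of per-sample means) and SEM for one group."""

    group: str
    segment_um: float
    intervals: List[SegmentInterval]
    mean: np.ndarray
    sem: np.ndarray
    n: int

    def __len__(self) -> int:
        return len(self.mean)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "segment_index": np.arange(len(self.mean)),
                "mean": self.mean,
                "sem": self.sem,
                "n": self.n,
            }
        )


def group_profile(profiles: Sequence[APProfile], group: Optional[str] = None) -> GroupProfile:
    """Aggregate per-sample profiles into a group mean +/- SEM profile.

    Profiles are aligned from the anterior end and truncated to the
    shortest profile's segment count (age-matched specimens yield nearly
    equal counts; no registration is attempted).
    """
    if not profiles:
        raise ValueError("group_profile needs at least one profile")
    widths = {p.segment_um for p in profiles}
    if len(widths) > 1:
        raise ValueError(f"profiles have mixed segment widths: {sorted(widths)}")
    length = min(len(p) for p in profiles)
    stacked = np.vstack([p.mean_intensity[:length] for p in profiles])
    n = stacked.shape[0]
    mean = stacked.mean(axis=0)
    sem = (
        stacked.std(axis=0, ddof=1) / np.sqrt(n)
        if n > 1
        else np.zeros(length)
    )
    label = group if group is not None else (profiles[0].group or "group")
    return GroupProfile(
        group=label,
        segment_um=profiles[0].segment_um,
        intervals=profiles[0].intervals[:length],
        mean=mean,
        sem=sem,
        n=n,
    )


@dataclass
class PercentChange:
    """Per-segment percent change of a treatment group from control.

    Segments where the control mean is 0 are flagged undefined and carry
    NaN rather than a number.
    """

    treatment: str
    control: str
    segment_um: float
    percent: np.ndarray
    defined: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "treatment": self.treatment,
                "control": self.control,
                "segment_index": np.arange(len(self.percent)),
                "percent_change": self.percent,
                "defined": self.defined,
            }
        )


def percent_change(treatment: GroupProfile, control: GroupProfile) -> PercentChange:
    """100 x (treatment - control) / control per segment, with a 0-guard."""
    if treatment.segment_um != control.segment_um:
        raise ValueError("segment widths differ between treatment and control")
    length = min(len(treatment), len(control))
    t = treatment.mean[:length]
    c = control.mean[:length]
    defined = c > 0
    percent = np.full(length, np.nan)
    percent[defined] = 100.0 * (t[defined] - c[defined]) / c[defined]
    return PercentChange(
        treatment=treatment.group,
        control=control.group,
        segment_um=treatment.segment_um,
        percent=percent,
        defined=defined,
    )


def profiles_to_frame(profiles: Sequence[APProfile]) -> pd.DataFrame:
    """Long-format table of per-sample profiles (CSV-ready)."""
    return pd.concat([p.to_frame() for p in profiles], ignore_index=True)
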