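"""Figure export for A-P profiles and percent-change curves."""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .ap_profile import GroupProfile, PercentChange

__all__ = ["plot_group_profiles", "plot_percent_change"]


def plot_group_profiles(
    profiles: Sequence[GroupProfile],
    path: Optional[str] = None,
    ax=None,
):
    """Mean +/- SEM EdU intensity along the A-P axis, one curve per group."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    for gp in profiles:
        x = [0.5 * (iv.start_um + iv.stop_um) for iv in gp.intervals]
        ax.plot(x, gp.mean, label=f"{gp.group} (n={gp.n})")
        ax.fill_between(x, gp.mean - gp.sem, gp.mean + gp.sem, alpha=0.25)
    ax.set_xlabel("A-P position (µm)")
    ax.set_ylabel("mean EdU intensity (non-black pixels)")
    ax.legend(frameon=False)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_percent_change(pc: PercentChange, path: Optional[str] = None, ax=None):
    """Per-segment percent change from control; undefined segments are gaps."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    x = list(range(len(pc.percent)))
    ax.axhline(0.0, color="k", lw=0.8)
    ax.plot(x, pc.percent, label=f"{pc.treatment} vs {pc.control}")
    ax.set_xlabel("A-P segment index")
    ax.set_ylabel("% change from control")
    ax.legend(frameon=False)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
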