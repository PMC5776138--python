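"""Replicate studies validating the pipeline on phantom cohorts.

These routines are what the package's own quality checks run: oracle
equivalence of the ROI volumetry, recovery of the injury pattern on the
default phantom schedule (structure-level burst at 1-dpl, niche-level
burst at 3-dpl ipsilaterally, flat tectal/cerebellar niches), and the
calibration of the statistical layer (null type-I error, Tukey p-values
against an independent computation).
"""

from __future__ import annotations

from typing import Dict, Mapping, Optional

import numpy as np
from scipy import stats

from .groupstats import compare_groups
from .phantom import (
    PhantomSpec,
    default_spec,
    generate_sample,
    hemisphere_box,
    niche_roi,
)
from .quantize import nonblack_bins
from .roi_volume import slice_volume, structure_volume
from .voldata import BoxROI, BrainSample, ChannelVolume, NicheROI, VoxelGeometry

__all__ = [
    "DEFAULT_N_PER_GROUP",
    "structure_oracle_check",
    "injury_power_study",
    "anova_null_type1",
    "profile_peak_recovery",
]

#: Cohort sizes mirroring the published group sizes (control, 1, 3, 7 dpl).
DEFAULT_N_PER_GROUP: Mapping[str, int] = {"control": 5, "1dpl": 4, "3dpl": 4, "7dpl": 5}


def structure_oracle_check(
    n_rois: int = 50,
    roi_edge: int = 32,
    seed: int = 0,
    pixel_size_um: float = 5.0,
) -> Dict[str, float]:
    """Compare structure/slice volumetry against brute-force counting.

    On randomized full-range ROIs, Structure Analysis with all 15
    non-black bins must equal the count of voxels >= 4096 times the voxel
    volume, and Slice Analysis at stride 1 with full-slice masks must
    equal Structure Analysis.  Returns the maximum absolute discrepancies
    in um^3 over all ROIs.
    """
    rng = np.random.default_rng(seed)
    geometry = VoxelGeometry(pixel_size_um)
    max_diff_oracle = 0.0
    max_diff_slice = 0.0
    for _ in range(n_rois):
        arr = rng.integers(0, 65536, size=(roi_edge,) * 3).astype(np.uint16)
        sample = BrainSample("r", "control", {"edu": ChannelVolume(arr)}, geometry)
        box = BoxROI(ap=(0, roi_edge), dv=(0, roi_edge), lr=(0, roi_edge))
        res = structure_volume(sample, "edu", box, bins_used=nonblack_bins())
        oracle = int((arr >= 4096).sum()) * geometry.voxel_volume_um3
        max_diff_oracle = max(max_diff_oracle, abs(res.volume_um3 - oracle))

        full = NicheROI(
            ap=(0, roi_edge),
            stride=1,
            masks={i: np.ones((roi_edge, roi_edge), bool) for i in range(roi_edge)},
        )
        res_slice = slice_volume(sample, "edu", full, bins_used=nonblack_bins())
        max_diff_slice = max(max_diff_slice, abs(res_slice.volume_um3 - res.volume_um3))
    return {
        "max_abs_diff_vs_threshold_oracle_um3": max_diff_oracle,
        "max_abs_diff_slice_stride1_vs_structure_um3": max_diff_slice,
        "n": n_rois,
    }


def injury_power_study(
    n_replicates: int = 50,
    seed: int = 0,
    spec: Optional[PhantomSpec] = None,
    n_per_group: Optional[Mapping[str, int]] = None,
    alpha: float = 0.05,
) -> Dict[str, float]:
    """Rates of recovering the injury pattern over seeded phantom cohorts.

    Per replicate a cohort is generated with the default injury schedule
    and analysed end-to-end: Structure Analysis (all 15 bins) on the
    lesioned-hemisphere box, and Slice Analysis (first 3 non-black bins,
    stride 5) on the ipsilateral pallial, tectal and cerebellar niches,
    each followed by one-way ANOVA + Tukey.  Returned rates are fractions
    of replicates in which the named pair was significant (for the
    tectal/cerebellar niches: in which *any* dpl-vs-control pair was).
    """
    spec = spec if spec is not None else default_spec()
    npg = dict(n_per_group if n_per_group is not None else DEFAULT_N_PER_GROUP)
    box = hemisphere_box(spec, "left")
    rois = {
        name: niche_roi(spec, name)
        for name in ("pallial_ipsi", "tectal", "cerebellar")
    }
    master = np.random.default_rng(seed)
    rep_seeds = master.integers(0, 2**31 - 1, n_replicates)

    hits = {"structure_1dpl": 0, "slice_ipsi_3dpl": 0, "tectal_any": 0, "cerebellar_any": 0}
    for rep_seed in rep_seeds:
        rng = np.random.default_rng(int(rep_seed))
        data: Dict[str, Dict[str, list]] = {
            m: {g: [] for g in npg} for m in ("structure", "ipsi", "tectal", "cerebellar")
        }
        for group, n in npg.items():
            for s in rng.integers(0, 2**31 - 1, n):
                sample, _ = generate_sample(spec, group, int(s))
                data["structure"][group].append(
                    structure_volume(sample, "edu", box).volume_um3
                )
                data["ipsi"][group].append(
                    slice_volume(sample, "edu", rois["pallial_ipsi"]).volume_um3
                )
                data["tectal"][group].append(
                    slice_volume(sample, "edu", rois["tectal"]).volume_um3
                )
                data["cerebellar"][group].append(
                    slice_volume(sample, "edu", rois["cerebellar"]).volume_um3
                )
        cmp_structure = compare_groups(data["structure"], alpha=alpha)
        cmp_ipsi = compare_groups(data["ipsi"], alpha=alpha)
        if cmp_structure.pair("control", "1dpl").significant:
            hits["structure_1dpl"] += 1
        if cmp_ipsi.pair("control", "3dpl").significant:
            hits["slice_ipsi_3dpl"] += 1
        for key, measure in (("tectal_any", "tectal"), ("cerebellar_any", "cerebellar")):
            cmp_n = compare_groups(data[measure], alpha=alpha)
            if any(
                cmp_n.pair("control", g).significant for g in npg if g != "control"
            ):
                hits[key] += 1

    return {
        "power_structure_1dpl_vs_control": hits["structure_1dpl"] / n_replicates,
        "power_slice_ipsi_3dpl_vs_control": hits["slice_ipsi_3dpl"] / n_replicates,
        "fp_rate_tectal_niche": hits["tectal_any"] / n_replicates,
        "fp_rate_cerebellar_niche": hits["cerebellar_any"] / n_replicates,
        "n": n_replicates,
    }


def anova_null_type1(
    n_cohorts: int = 2000,
    n_groups: int = 4,
    n_per_group: int = 5,
    alpha: float = 0.05,
    seed: int = 0,
) -> Dict[str, float]:
    """Empirical type-I error of the omnibus ANOVA under the null.

    Simulates Gaussian cohorts with identical group means and measures the
    fraction rejected at ``alpha``.  Runs the same one-way F test the
    group-comparison layer uses, vectorised over all cohorts.
    """
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((n_groups, n_per_group, n_cohorts))
    _, p = stats.f_oneway(*draws, axis=0)
    return {"type1_error": float(np.mean(p < alpha)), "n": n_cohorts}


def profile_peak_recovery(seed: int = 0) -> Dict[str, float]:
    """Histogram Analysis recovery on a single-niche phantom.

    Builds a phantom whose only EdU source is one anterior midline niche,
    computes the A-P profile, and reports whether the profile's peak
    segment lies inside the constructed niche span, plus the relative
    error of the linearity check (doubling all non-zero intensities must
    double every segment mean).
    """
    from .ap_profile import sample_profile
    from .phantom import NicheSpec

    niche = NicheSpec(
        name="anterior",
        ap_span_um=(60.0, 210.0),
        kind="midline_band",
        hemisphere=None,
        focus_rate_per_um3=4e-4,
        focus_peak=20000.0,
    )
    spec = PhantomSpec(
        niches=(niche,),
        parenchyma_amplitude={g: 0.0 for g in ("control", "1dpl", "3dpl", "7dpl")},
        noise_sd=300.0,
    )
    sample, _ = generate_sample(spec, "control", seed)
    profile = sample_profile(sample, "edu")
    peak = int(np.argmax(profile.mean_intensity))
    iv = profile.intervals[peak]
    peak_center = 0.5 * (iv.start_um + iv.stop_um)
    in_span = niche.ap_span_um[0] <= peak_center < niche.ap_span_um[1]

    arr = sample.channel("edu").intensities.astype(np.int64)
    doubled = BrainSample(
        "x2", "control",
        {"edu": ChannelVolume(np.minimum(arr * 2, 65535).astype(np.uint16))},
        sample.geometry,
    )
    # keep to the unclipped regime for the exact-linearity comparison
    assert int(arr.max()) * 2 <= 65535, "phantom intensities exceed linear headroom"
    profile2 = sample_profile(doubled, "edu")
    nz = profile.mean_intensity > 0
    rel_err = float(
        np.max(np.abs(profile2.mean_intensity[nz] / profile.mean_intensity[nz] - 2.0))
    )
    return {
        "peak_in_niche_span": float(in_span),
        "peak_center_um": peak_center,
        "linearity_max_rel_err": rel_err,
        "n": int(len(profile)),
    }
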