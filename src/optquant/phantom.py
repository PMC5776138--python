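"""Synthetic OPT-brain phantom generator with ground truth.

Emulates reconstructed (post-tomography) adult zebrafish brain scans at
desk scale: an autofluorescent ellipsoidal brain shell, midline ventricular
proliferation niches along the A-P axis carrying punctate EdU foci
(Poisson counts, hard-edged spheres), and a lesion-condition-dependent
diffuse parenchymal component confined to the lesioned (left) forebrain
hemisphere — the immune-cell infiltrate that Structure Analysis picks up
but niche-restricted Slice Analysis largely avoids.  Signal is Gaussian
blurred (standing in for the OPT point-spread and reconstruction
smoothing), additive Gaussian noise is applied, and the result is clipped
and quantized to 16 bits.

The default injury schedule over groups (control, 1dpl, 3dpl, 7dpl):

* parenchymal amplitude peaks at 1-dpl, decays through 3-dpl, and is near
  baseline by 7-dpl;
* the lesioned-hemisphere pallial niche focus rate peaks at 3-dpl, the
  contralateral one at 1-dpl;
* tectal and cerebellar niches are unchanged by the lesion.

Ground truth (focus counts, focus-voxel counts, parenchymal voxel counts,
brain-mask size) is recorded before blur and noise.  Identical spec +
seed produce bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .voldata import (
    BoxROI,
    BrainSample,
    ChannelVolume,
    CohortManifest,
    ManifestRecord,
    NicheROI,
    VoxelGeometry,
    save_box_roi,
    save_niche_roi,
    write_channel,
)

__all__ = [
    "GROUPS",
    "NicheSpec",
    "PhantomSpec",
    "GroundTruth",
    "default_spec",
    "generate_sample",
    "generate_cohort",
    "brain_mask",
    "niche_region",
    "hemisphere_box",
    "niche_box",
    "niche_roi",
]

GROUPS: Tuple[str, ...] = ("control", "1dpl", "3dpl", "7dpl")

# geometry of the niche caricatures, in micrometres
_BAND_LR_OFFSET = (4.0, 40.0)   # midline band: |lr - midline| within this range
_BAND_DV_SPAN = (-60.0, -10.0)  # relative to the D-V centre; negative = dorsal
_SHELL_DEPTH = 0.30             # tectal shell: normalized ellipsoid coordinate > 1 - depth
_CEREBELLAR_DV_SPAN = (-60.0, 10.0)
_NICHE_EXCLUSION_DILATION = 3   # voxels kept clear of parenchymal signal around niches
_NONBLACK_EDGE = 4096           # ground-truth "signal voxel" threshold


@dataclass(frozen=True, eq=False)
class NicheSpec:
    """One proliferation niche: geometry plus EdU focus statistics."""

    name: str
    ap_span_um: Tuple[float, float]
    kind: str  # "midline_band" | "tectal_shell" | "cerebellar_band"
    hemisphere: Optional[str] = None  # "left" | "right" | None (both)
    focus_rate_per_um3: float = 2e-4
    focus_radius_um: float = 6.0
    focus_peak: float = 30000.0
    group_rate_multiplier: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("midline_band", "tectal_shell", "cerebellar_band"):
            raise ValueError(f"unknown niche kind {self.kind!r}")
        if self.hemisphere not in (None, "left", "right"):
            raise ValueError(f"hemisphere must be left/right/None, got {self.hemisphere!r}")
        if self.focus_rate_per_um3 < 0 or self.focus_radius_um < 0 or self.focus_peak < 0:
            raise ValueError("focus rate, radius and peak must be >= 0")

    def rate_for(self, group: str) -> float:
        return self.focus_rate_per_um3 * float(self.group_rate_multiplier.get(group, 1.0))


@dataclass(frozen=True, eq=False)
class PhantomSpec:
    """Full description of the phantom study conditions.

    Frozen and hashed by identity: reuse one spec object across a cohort
    so the cached geometry (brain and niche masks) is shared.
    """

    shape: Tuple[int, int, int] = (120, 48, 48)
    pixel_size_um: float = 5.0
    brain_semiaxes_um: Tuple[float, float, float] = (290.0, 105.0, 105.0)
    niches: Tuple[NicheSpec, ...] = ()
    parenchyma_amplitude: Mapping[str, float] = field(default_factory=dict)
    parenchyma_ap_span_um: Tuple[float, float] = (60.0, 210.0)
    parenchyma_lesioned_hemisphere_only: bool = True
    parenchyma_smoothness_um: float = 10.0
    autofluorescence_level: float = 18000.0
    blur_sigma_um: float = 5.0
    noise_sd: float = 800.0
    groups: Tuple[str, ...] = GROUPS

    def __post_init__(self) -> None:
        if min(self.shape) < 8:
            raise ValueError(f"all grid extents must be >= 8, got {self.shape}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.blur_sigma_um < 0 or self.noise_sd < 0 or self.parenchyma_smoothness_um < 0:
            raise ValueError("sigmas and noise sd must be >= 0")
        if any(a < 0 for a in self.parenchyma_amplitude.values()):
            raise ValueError("parenchymal amplitudes must be >= 0")

    @property
    def geometry(self) -> VoxelGeometry:
        return VoxelGeometry(self.pixel_size_um)


def default_spec() -> PhantomSpec:
    """The canonical desk-scale phantom with the default injury schedule."""
    niches = (
        NicheSpec(
            name="pallial_ipsi",
            ap_span_um=(60.0, 210.0),
            kind="midline_band",
            hemisphere="left",
            group_rate_multiplier={"control": 1.0, "1dpl": 1.6, "3dpl": 2.5, "7dpl": 1.2},
        ),
        NicheSpec(
            name="pallial_contra",
            ap_span_um=(60.0, 210.0),
            kind="midline_band",
            hemisphere="right",
            group_rate_multiplier={"control": 1.0, "1dpl": 1.8, "3dpl": 1.2, "7dpl": 1.0},
        ),
        NicheSpec(
            name="tectal",
            ap_span_um=(250.0, 420.0),
            kind="tectal_shell",
            focus_rate_per_um3=1.5e-4,
        ),
        NicheSpec(
            name="cerebellar",
            ap_span_um=(440.0, 540.0),
            kind="cerebellar_band",
        ),
    )
    return PhantomSpec(
        niches=niches,
        parenchyma_amplitude={"control": 0.0, "1dpl": 12000.0, "3dpl": 6000.0, "7dpl": 1500.0},
    )


@dataclass
class GroundTruth:
    """Pre-blur/noise truth recorded alongside each generated sample."""

    sample_id: str
    group: str
    niche_focus_counts: Dict[str, int]
    niche_focus_voxels: Dict[str, int]
    parenchyma_voxels: Dict[str, int]  # per hemisphere ("left"/"right")
    brain_voxels: int

    def to_row(self) -> Dict[str, object]:
        row: Dict[str, object] = {
            "sample_id": self.sample_id,
            "group": self.group,
            "brain_voxels": self.brain_voxels,
        }
        for name, c in self.niche_focus_counts.items():
            row[f"foci_{name}"] = c
        for name, c in self.niche_focus_voxels.items():
            row[f"focus_voxels_{name}"] = c
        for hemi, c in self.parenchyma_voxels.items():
            row[f"parenchyma_voxels_{hemi}"] = c
        return row


# ---------------------------------------------------------------------------
# cached geometry (keyed by spec identity — reuse the spec object)


def _axis_centers_um(n: int, px: float) -> np.ndarray:
    return (np.arange(n) + 0.5) * px


@lru_cache(maxsize=32)
def _ellipsoid_field(spec: PhantomSpec) -> np.ndarray:
    """Normalized ellipsoid coordinate e = sum((x_i - c_i)^2 / a_i^2)."""
    px = spec.pixel_size_um
    centers = [_axis_centers_um(n, px) for n in spec.shape]
    mids = [n * px / 2.0 for n in spec.shape]
    ap = (centers[0] - mids[0]) / spec.brain_semiaxes_um[0]
    dv = (centers[1] - mids[1]) / spec.brain_semiaxes_um[1]
    lr = (centers[2] - mids[2]) / spec.brain_semiaxes_um[2]
    return (
        ap[:, None, None] ** 2 + dv[None, :, None] ** 2 + lr[None, None, :] ** 2
    ).astype(np.float32)


@lru_cache(maxsize=32)
def brain_mask(spec: PhantomSpec) -> np.ndarray:
    """Boolean mask of the ellipsoidal brain interior."""
    return _ellipsoid_field(spec) <= 1.0


@lru_cache(maxsize=256)
def niche_region(spec: PhantomSpec, niche: NicheSpec) -> np.ndarray:
    """Boolean 3-D mask of one niche's voxels."""
    px = spec.pixel_size_um
    nap, ndv, nlr = spec.shape
    ap_c = _axis_centers_um(nap, px)
    dv_c = _axis_centers_um(ndv, px)
    lr_c = _axis_centers_um(nlr, px)
    dv_mid = ndv * px / 2.0
    lr_mid = nlr * px / 2.0

    in_ap = (ap_c >= niche.ap_span_um[0]) & (ap_c < niche.ap_span_um[1])
    region = brain_mask(spec) & in_ap[:, None, None]

    if niche.kind == "midline_band":
        offset = lr_c - lr_mid
        if niche.hemisphere == "left":
            in_lr = (offset >= -_BAND_LR_OFFSET[1]) & (offset <= -_BAND_LR_OFFSET[0])
        elif niche.hemisphere == "right":
            in_lr = (offset >= _BAND_LR_OFFSET[0]) & (offset <= _BAND_LR_OFFSET[1])
        else:
            in_lr = np.abs(offset) <= _BAND_LR_OFFSET[1]
        in_dv = (dv_c - dv_mid >= _BAND_DV_SPAN[0]) & (dv_c - dv_mid <= _BAND_DV_SPAN[1])
        region = region & in_dv[None, :, None] & in_lr[None, None, :]
    elif niche.kind == "tectal_shell":
        e = _ellipsoid_field(spec)
        dorsal = (dv_c < dv_mid)[None, :, None]
        region = region & (e >= 1.0 - _SHELL_DEPTH) & dorsal
    else:  # cerebellar_band
        in_dv = (dv_c - dv_mid >= _CEREBELLAR_DV_SPAN[0]) & (
            dv_c - dv_mid <= _CEREBELLAR_DV_SPAN[1]
        )
        region = region & in_dv[None, :, None]
    return region


@lru_cache(maxsize=32)
def _parenchyma_mask(spec: PhantomSpec) -> np.ndarray:
    """Brain voxels eligible for diffuse parenchymal signal.

    Confined to the forebrain A-P span (and the lesioned left hemisphere
    when so flagged), excluding a dilated neighbourhood of every niche so
    that niche-restricted Slice Analysis sees almost none of it.
    """
    px = spec.pixel_size_um
    nap, _, nlr = spec.shape
    ap_c = _axis_centers_um(nap, px)
    in_ap = (ap_c >= spec.parenchyma_ap_span_um[0]) & (ap_c < spec.parenchyma_ap_span_um[1])
    mask = brain_mask(spec) & in_ap[:, None, None]
    if spec.parenchyma_lesioned_hemisphere_only:
        left = np.zeros(nlr, dtype=bool)
        left[: nlr // 2] = True
        mask = mask & left[None, None, :]
    if spec.niches:
        union = np.zeros(spec.shape, dtype=bool)
        for niche in spec.niches:
            union |= niche_region(spec, niche)
        union = ndimage.binary_dilation(union, iterations=_NICHE_EXCLUSION_DILATION)
        mask = mask & ~union
    return mask


@lru_cache(maxsize=64)
def _sphere_offsets(radius_vox_scaled: int) -> np.ndarray:
    """Integer offsets within a sphere; radius passed scaled by 1000."""
    r = radius_vox_scaled / 1000.0
    reach = int(np.floor(r))
    rng_ = np.arange(-reach, reach + 1)
    di, dj, dk = np.meshgrid(rng_, rng_, rng_, indexing="ij")
    inside = di**2 + dj**2 + dk**2 <= r**2
    return np.stack([di[inside], dj[inside], dk[inside]], axis=1)


# ---------------------------------------------------------------------------
# generation


def generate_sample(
    spec: PhantomSpec,
    group: str,
    seed: int,
    sample_id: Optional[str] = None,
) -> Tuple[BrainSample, GroundTruth]:
    """Generate one phantom specimen and its ground truth.

    The EdU channel is the sum of hard-edged niche foci and the
    group-scaled diffuse parenchymal field, blurred, noised, clipped and
    quantized; the autofluorescence channel is the brain interior at the
    base level plus noise.  The random stream is consumed identically for
    every group (the parenchymal field is drawn even at amplitude 0), so
    same-seed samples from different groups differ only in their signal.
    """
    if group not in spec.groups:
        raise ValueError(f"unknown group {group!r}; declared groups: {list(spec.groups)}")
    rng = np.random.default_rng(seed)
    px = spec.pixel_size_um
    voxel_um3 = px**3
    shape = spec.shape
    brain = brain_mask(spec)

    # autofluorescence: brain interior at base level + noise
    auto = np.where(brain, np.float32(spec.autofluorescence_level), np.float32(0.0))
    auto = auto + rng.standard_normal(shape, dtype=np.float32) * np.float32(spec.noise_sd)
    auto_q = np.rint(np.clip(auto, 0, 65535)).astype(np.uint16)

    # EdU niche foci
    signal = np.zeros(shape, dtype=np.float32)
    focus_counts: Dict[str, int] = {}
    focus_voxels: Dict[str, int] = {}
    for niche in spec.niches:
        region = niche_region(spec, niche)
        flat = np.flatnonzero(region)
        if flat.size == 0:
            raise ValueError(f"niche {niche.name!r} is empty after discretization")
        lam = niche.rate_for(group) * flat.size * voxel_um3
        n_foci = int(rng.poisson(lam))
        focus_counts[niche.name] = n_foci
        paint = np.zeros(shape, dtype=bool)
        if n_foci:
            centers_flat = flat[rng.integers(0, flat.size, n_foci)]
            centers = np.stack(np.unravel_index(centers_flat, shape), axis=1)
            offsets = _sphere_offsets(int(round(niche.focus_radius_um / px * 1000)))
            pts = centers[:, None, :] + offsets[None, :, :]
            pts = pts.reshape(-1, 3)
            ok = (
                (pts[:, 0] >= 0) & (pts[:, 0] < shape[0])
                & (pts[:, 1] >= 0) & (pts[:, 1] < shape[1])
                & (pts[:, 2] >= 0) & (pts[:, 2] < shape[2])
            )
            pts = pts[ok]
            paint[pts[:, 0], pts[:, 1], pts[:, 2]] = True
            signal = np.maximum(signal, np.where(paint, np.float32(niche.focus_peak), 0))
        focus_voxels[niche.name] = int(paint.sum())

    # diffuse parenchymal component (drawn for every group; amplitude scales it)
    field = rng.random(shape, dtype=np.float32)
    if spec.parenchyma_smoothness_um > 0:
        field = ndimage.gaussian_filter(field, spec.parenchyma_smoothness_um / px)
    span = float(field.max() - field.min())
    if span > 0:
        field = (field - field.min()) / span
    amplitude = float(spec.parenchyma_amplitude.get(group, 0.0))
    pmask = _parenchyma_mask(spec)
    parenchyma = np.where(pmask, field * np.float32(amplitude), np.float32(0.0))

    nlr = shape[2]
    strong = parenchyma >= _NONBLACK_EDGE
    parenchyma_voxels = {
        "left": int(strong[:, :, : nlr // 2].sum()),
        "right": int(strong[:, :, nlr // 2 :].sum()),
    }

    edu = signal + parenchyma
    if spec.blur_sigma_um > 0:
        edu = ndimage.gaussian_filter(edu, spec.blur_sigma_um / px)
    edu = edu + rng.standard_normal(shape, dtype=np.float32) * np.float32(spec.noise_sd)
    edu_q = np.rint(np.clip(edu, 0, 65535)).astype(np.uint16)

    sid = sample_id if sample_id is not None else f"{group}_{seed}"
    sample = BrainSample(
        sample_id=sid,
        group=group,
        channels={
            "edu": ChannelVolume(edu_q),
            "autofluorescence": ChannelVolume(auto_q),
        },
        geometry=spec.geometry,
    )
    truth = GroundTruth(
        sample_id=sid,
        group=group,
        niche_focus_counts=focus_counts,
        niche_focus_voxels=focus_voxels,
        parenchyma_voxels=parenchyma_voxels,
        brain_voxels=int(brain.sum()),
    )
    return sample, truth


def generate_cohort(
    spec: PhantomSpec,
    n_per_group: Mapping[str, int],
    seed: int,
    out_dir: Optional[Path] = None,
) -> Tuple[List[BrainSample], CohortManifest, pd.DataFrame]:
    """Generate a cohort with deterministic per-sample seeds.

    Per-sample seeds are drawn once from the cohort seed and recorded in
    the manifest, so any specimen can be regenerated in isolation.  With
    ``out_dir`` the TIFF stacks, ``manifest.csv``, ``ground_truth.csv``
    and the default analysis ROIs are written to disk.
    """
    for g, n in n_per_group.items():
        if g not in spec.groups:
            raise ValueError(f"unknown group {g!r}")
        if n < 1:
            raise ValueError(f"n for group {g!r} must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    order = [(g, i) for g in n_per_group for i in range(n_per_group[g])]
    sample_seeds = rng.integers(0, 2**31 - 1, len(order))

    samples: List[BrainSample] = []
    truths: List[GroundTruth] = []
    ids = set()
    for (g, i), s in zip(order, sample_seeds):
        sid = f"{g}_{i + 1:02d}"
        if sid in ids:
            raise ValueError(f"duplicate sample id {sid!r}")
        ids.add(sid)
        sample, truth = generate_sample(spec, g, int(s), sample_id=sid)
        samples.append(sample)
        truths.append(truth)
    truth_frame = pd.DataFrame([t.to_row() for t in truths])

    records: List[ManifestRecord] = []
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sample, s in zip(samples, sample_seeds):
            paths: Dict[str, Path] = {}
            for name, chan in sample.channels.items():
                p = out_dir / f"{sample.sample_id}_{name}.tif"
                write_channel(chan, p)
                paths[name] = p
            records.append(
                ManifestRecord(sample.sample_id, sample.group, spec.pixel_size_um, paths)
            )
        manifest = CohortManifest(records)
        frame = manifest.to_frame()
        frame["seed"] = list(sample_seeds)
        frame.to_csv(out_dir / "manifest.csv", index=False)
        truth_frame.to_csv(out_dir / "ground_truth.csv", index=False)
        roi_dir = out_dir / "rois"
        roi_dir.mkdir(exist_ok=True)
        save_box_roi(hemisphere_box(spec, "left"), roi_dir / "lesioned_hemisphere.json")
        save_box_roi(hemisphere_box(spec, "right"), roi_dir / "unlesioned_hemisphere.json")
        for niche in spec.niches:
            save_niche_roi(niche_roi(spec, niche.name), roi_dir / f"{niche.name}.json")
    else:
        for sample, s in zip(samples, sample_seeds):
            records.append(
                ManifestRecord(sample.sample_id, sample.group, spec.pixel_size_um, {})
            )
        manifest = CohortManifest(records)

    return samples, manifest, truth_frame


# ---------------------------------------------------------------------------
# analysis ROIs derived from the phantom geometry


def _span_to_indices(span_um: Tuple[float, float], n: int, px: float) -> Tuple[int, int]:
    centers = _axis_centers_um(n, px)
    hit = np.nonzero((centers >= span_um[0]) & (centers < span_um[1]))[0]
    if hit.size == 0:
        raise ValueError(f"span {span_um} um contains no voxel centers")
    return int(hit[0]), int(hit[-1]) + 1


def hemisphere_box(
    spec: PhantomSpec,
    side: str = "left",
    ap_span_um: Optional[Tuple[float, float]] = None,
) -> BoxROI:
    """Box ROI covering one telencephalic hemisphere across the forebrain
    A-P span (the Structure Analysis target)."""
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    span = ap_span_um if ap_span_um is not None else spec.parenchyma_ap_span_um
    ap = _span_to_indices(span, spec.shape[0], spec.pixel_size_um)
    nlr = spec.shape[2]
    lr = (0, nlr // 2) if side == "left" else (nlr // 2, nlr)
    return BoxROI(ap=ap, dv=(0, spec.shape[1]), lr=lr)


def _find_niche(spec: PhantomSpec, name: str) -> NicheSpec:
    for niche in spec.niches:
        if niche.name == name:
            return niche
    raise KeyError(f"no niche named {name!r}; available: {[n.name for n in spec.niches]}")


def niche_box(spec: PhantomSpec, name: str) -> BoxROI:
    """Bounding box of a niche's voxels."""
    region = niche_region(spec, _find_niche(spec, name))
    idx = np.nonzero(region)
    return BoxROI(
        ap=(int(idx[0].min()), int(idx[0].max()) + 1),
        dv=(int(idx[1].min()), int(idx[1].max()) + 1),
        lr=(int(idx[2].min()), int(idx[2].max()) + 1),
    )


def niche_roi(spec: PhantomSpec, name: str, stride: int = 5) -> NicheROI:
    """Per-slice niche masks for Slice Analysis, sampled every ``stride``."""
    region = niche_region(spec, _find_niche(spec, name))
    ap_idx = np.nonzero(region.any(axis=(1, 2)))[0]
    ap = (int(ap_idx[0]), int(ap_idx[-1]) + 1)
    masks = {int(i): region[i] for i in range(ap[0], ap[1], stride)}
    return NicheROI(ap=ap, stride=stride, masks=masks)
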