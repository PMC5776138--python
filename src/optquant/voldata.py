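"""Domain containers and I/O for reconstructed OPT brain volumes.

A specimen is stored as one multi-page grayscale TIFF per fluorescence
channel.  Stack pages are 1-pixel virtual cross-sections ordered
anterior->posterior; within a page, rows run dorsal->ventral and columns
left->right.  Intensities are 16-bit, 0 (black) to 65535 (white).  Voxels
are isotropic: the edge length is the scan pixel size in micrometres, so
one voxel has volume ``pixel_size_um ** 3``.

All coordinates are 0-based and all intervals are half-open ``[start, stop)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "INTENSITY_MAX",
    "VoxelGeometry",
    "ChannelVolume",
    "BrainSample",
    "BoxROI",
    "NicheROI",
    "ManifestRecord",
    "CohortManifest",
    "read_channel",
    "write_channel",
    "load_manifest",
    "max_project_horizontal",
    "load_box_roi",
    "save_box_roi",
    "load_niche_roi",
    "save_niche_roi",
]

#: Largest representable 16-bit intensity ("white").
INTENSITY_MAX = 65535


@dataclass(frozen=True)
class VoxelGeometry:
    """Isotropic voxel geometry of a reconstructed scan.

    Parameters
    ----------
    pixel_size_um : float
        Edge length of one voxel in micrometres.  Typical OPT scans of
        adult zebrafish brain reconstruct at ~4.5-5 um, i.e. voxels of
        ~91-125 um^3.
    """

    pixel_size_um: float

    def __post_init__(self) -> None:
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")

    @property
    def voxel_volume_um3(self) -> float:
        """Volume of one voxel in cubic micrometres."""
        return float(self.pixel_size_um) ** 3


@dataclass(eq=False)
class ChannelVolume:
    """A 3-D 16-bit intensity grid for one fluorescence channel.

    Axis order is (anterior->posterior, dorsal->ventral, left->right).
    """

    intensities: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got {arr.ndim} dimensions")
        if min(arr.shape) < 1:
            raise ValueError(f"all extents must be >= 1, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            raise TypeError(f"intensities must be integral, got dtype {arr.dtype}")
        if arr.size and (int(arr.min()) < 0 or int(arr.max()) > INTENSITY_MAX):
            raise ValueError(
                f"intensities outside [0, {INTENSITY_MAX}]: "
                f"min={int(arr.min())}, max={int(arr.max())}"
            )
        self.intensities = arr.astype(np.uint16, copy=False)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]


def max_project_horizontal(volume: ChannelVolume) -> np.ndarray:
    """Maximum-intensity projection through the horizontal plane.

    Collapses the dorsal-ventral axis, returning a 2-D (A-P, L-R) image in
    which each position holds the maximum intensity along D-V.  This is the
    projection the A-P intensity profile (Histogram Analysis) starts from.
    """
    return volume.intensities.max(axis=1)


@dataclass(eq=False)
class BrainSample:
    """One specimen: named channel volumes sharing a grid and geometry."""

    sample_id: str
    group: str
    channels: Dict[str, ChannelVolume]
    geometry: VoxelGeometry

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("a BrainSample needs at least one channel")
        shapes = {name: ch.shape for name, ch in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channels have mismatched extents: {shapes}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> ChannelVolume:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"sample {self.sample_id!r} has no channel {name!r}; "
                f"available: {sorted(self.channels)}"
            ) from None


def _check_interval(name: str, iv: Tuple[int, int]) -> Tuple[int, int]:
    a, b = int(iv[0]), int(iv[1])
    if not 0 <= a < b:
        raise ValueError(f"{name} interval must satisfy 0 <= start < stop, got [{a}, {b})")
    return a, b


@dataclass(frozen=True)
class BoxROI:
    """Axis-aligned box ROI as half-open index intervals on (A-P, D-V, L-R)."""

    ap: Tuple[int, int]
    dv: Tuple[int, int]
    lr: Tuple[int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ap", _check_interval("ap", self.ap))
        object.__setattr__(self, "dv", _check_interval("dv", self.dv))
        object.__setattr__(self, "lr", _check_interval("lr", self.lr))

    def validate(self, shape: Tuple[int, int, int]) -> None:
        for name, (a, b), extent in zip(
            ("ap", "dv", "lr"), (self.ap, self.dv, self.lr), shape
        ):
            if b > extent:
                raise ValueError(
                    f"ROI {name} interval [{a}, {b}) exceeds axis extent {extent}"
                )

    def slices(self) -> Tuple[slice, slice, slice]:
        return (slice(*self.ap), slice(*self.dv), slice(*self.lr))

    @property
    def n_voxels(self) -> int:
        return (
            (self.ap[1] - self.ap[0])
            * (self.dv[1] - self.dv[0])
            * (self.lr[1] - self.lr[0])
        )


@dataclass(eq=False)
class NicheROI:
    """Per-slice niche masks sampled every ``stride`` sections along A-P.

    ``masks`` maps an A-P slice index to a 2-D boolean mask over (D-V, L-R).
    Only the sampled slices (``ap[0], ap[0]+stride, ...``) need masks.
    """

    ap: Tuple[int, int]
    stride: int
    masks: Dict[int, np.ndarray]

    def __post_init__(self) -> None:
        self.ap = _check_interval("ap", self.ap)
        self.stride = int(self.stride)
        if self.stride < 1:
            raise ValueError(f"stride must be >= 1, got {self.stride}")
        clean: Dict[int, np.ndarray] = {}
        for k, m in self.masks.items():
            k = int(k)
            if not self.ap[0] <= k < self.ap[1]:
                raise ValueError(f"mask key {k} outside ap interval {list(self.ap)}")
            m = np.asarray(m)
            if m.ndim != 2:
                raise ValueError(f"mask for slice {k} must be 2-D, got {m.ndim}-D")
            clean[k] = m.astype(bool)
        self.masks = clean

    def sampled_indices(self) -> List[int]:
        return list(range(self.ap[0], self.ap[1], self.stride))

    def validate(self, shape: Tuple[int, int, int]) -> None:
        if self.ap[1] > shape[0]:
            raise ValueError(f"ap interval {list(self.ap)} exceeds extent {shape[0]}")
        for k, m in self.masks.items():
            if m.shape != shape[1:]:
                raise ValueError(
                    f"mask for slice {k} has shape {m.shape}, expected {shape[1:]}"
                )


# ---------------------------------------------------------------------------
# TIFF stack I/O


def read_channel(path) -> ChannelVolume:
    """Read a multi-page grayscale TIFF stack as a ChannelVolume.

    Page order is taken as anterior->posterior.  8-bit pages are rescaled to
    16-bit by multiplying by 257, so 255 maps exactly to 65535.  RGB or
    multi-sample pages and inconsistent page shapes are rejected with the
    offending page index.
    """
    path = Path(path)
    pages_data: List[np.ndarray] = []
    first_shape: Optional[Tuple[int, int]] = None
    with tifffile.TiffFile(path) as tf:
        for i, page in enumerate(tf.pages):
            arr = page.asarray()
            if arr.ndim != 2:
                raise ValueError(
                    f"{path}: page {i} is not single-sample grayscale "
                    f"(shape {arr.shape})"
                )
            if arr.dtype not in (np.dtype(np.uint8), np.dtype(np.uint16)):
                raise ValueError(
                    f"{path}: page {i} has unsupported dtype {arr.dtype}; "
                    "expected 8- or 16-bit grayscale"
                )
            if first_shape is None:
                first_shape = arr.shape
            elif arr.shape != first_shape:
                raise ValueError(
                    f"{path}: page {i} shape {arr.shape} differs from "
                    f"page 0 shape {first_shape}"
                )
            pages_data.append(arr)
    if not pages_data:
        raise ValueError(f"{path}: TIFF contains no pages")
    stack = np.stack(pages_data)
    if stack.dtype == np.uint8:
        stack = stack.astype(np.uint16) * 257
    return ChannelVolume(stack)


def write_channel(volume: ChannelVolume, path) -> None:
    """Write a ChannelVolume as a multi-page 16-bit grayscale TIFF.

    ``read_channel`` inverts this bit-exactly.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    tifffile.imwrite(path, volume.intensities, photometric="minisblack")


# ---------------------------------------------------------------------------
# Cohort manifest

_REQUIRED_COLUMNS = ("sample_id", "group", "pixel_size_um")
_CHANNEL_COLUMNS = {
    "edu_path": "edu",
    "autofluorescence_path": "autofluorescence",
    "marker_path": "marker",
}


@dataclass
class ManifestRecord:
    sample_id: str
    group: str
    pixel_size_um: float
    channel_paths: Dict[str, Path]


@dataclass
class CohortManifest:
    """Validated cohort table: one record per specimen."""

    records: List[ManifestRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ManifestRecord]:
        return iter(self.records)

    @property
    def groups(self) -> List[str]:
        seen: List[str] = []
        for r in self.records:
            if r.group not in seen:
                seen.append(r.group)
        return seen

    def load_sample(self, record: ManifestRecord) -> BrainSample:
        channels = {name: read_channel(p) for name, p in record.channel_paths.items()}
        return BrainSample(
            sample_id=record.sample_id,
            group=record.group,
            channels=channels,
            geometry=VoxelGeometry(record.pixel_size_um),
        )

    def iter_samples(self) -> Iterator[BrainSample]:
        for record in self.records:
            yield self.load_sample(record)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "sample_id": r.sample_id,
                "group": r.group,
                "pixel_size_um": r.pixel_size_um,
            }
            for col, name in _CHANNEL_COLUMNS.items():
                if name in r.channel_paths:
                    row[col] = str(r.channel_paths[name])
            rows.append(row)
        return pd.DataFrame(rows)


def load_manifest(
    path,
    groups: Optional[Sequence[str]] = None,
    check_paths: bool = True,
) -> CohortManifest:
    """Load and validate a cohort manifest CSV.

    The dialect is a header row
    ``sample_id,group,pixel_size_um,edu_path,autofluorescence_path[,marker_path]``
    with channel paths resolved relative to the manifest's directory.  When
    ``groups`` is given, any record with a label outside it is rejected.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest is missing columns {missing}")
    channel_cols = [c for c in _CHANNEL_COLUMNS if c in df.columns]
    if not channel_cols:
        raise ValueError(
            f"{path}: manifest has no channel path columns "
            f"(expected one of {sorted(_CHANNEL_COLUMNS)})"
        )
    dupes = df["sample_id"][df["sample_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate sample_id values: {dupes}")

    base = path.parent
    records: List[ManifestRecord] = []
    for _, row in df.iterrows():
        group = str(row["group"])
        if groups is not None and group not in groups:
            raise ValueError(
                f"{path}: sample {row['sample_id']!r} has unknown group "
                f"{group!r}; declared groups: {list(groups)}"
            )
        channel_paths: Dict[str, Path] = {}
        for col in channel_cols:
            value = row[col]
            if pd.isna(value) or str(value) == "":
                continue
            p = Path(str(value))
            if not p.is_absolute():
                p = base / p
            if check_paths and not p.exists():
                raise FileNotFoundError(
                    f"{path}: sample {row['sample_id']!r}: {col} not found: {p}"
                )
            channel_paths[_CHANNEL_COLUMNS[col]] = p
        records.append(
            ManifestRecord(
                sample_id=str(row["sample_id"]),
                group=group,
                pixel_size_um=float(row["pixel_size_um"]),
                channel_paths=channel_paths,
            )
        )
    return CohortManifest(records)


# ---------------------------------------------------------------------------
# ROI JSON I/O


def load_box_roi(path) -> BoxROI:
    """Read a box ROI from JSON: ``{"ap":[a,b],"dv":[c,d],"lr":[e,f]}``."""
    with open(path) as fh:
        data = json.load(fh)
    return BoxROI(ap=tuple(data["ap"]), dv=tuple(data["dv"]), lr=tuple(data["lr"]))


def save_box_roi(roi: BoxROI, path) -> None:
    with open(path, "w") as fh:
        json.dump({"ap": list(roi.ap), "dv": list(roi.dv), "lr": list(roi.lr)}, fh)


def load_niche_roi(path) -> NicheROI:
    """Read a niche ROI from JSON.

    Format: ``{"ap":[a,b],"stride":5,"masks":{"<ap_index>":"<mask tiff>"}}``
    with mask paths resolved relative to the JSON file; masks are 2-D TIFFs
    where any nonzero pixel is inside the niche.
    """
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh)
    masks: Dict[int, np.ndarray] = {}
    for key, mask_path in data["masks"].items():
        p = Path(mask_path)
        if not p.is_absolute():
            p = path.parent / p
        masks[int(key)] = tifffile.imread(p) > 0
    return NicheROI(ap=tuple(data["ap"]), stride=int(data.get("stride", 5)), masks=masks)


def save_niche_roi(roi: NicheROI, path, mask_dir: Optional[Path] = None) -> None:
    """Write a niche ROI as JSON plus one 8-bit binary TIFF per mask."""
    path = Path(path)
    mask_dir = Path(mask_dir) if mask_dir is not None else path.parent
    mask_dir.mkdir(parents=True, exist_ok=True)
    entries: Dict[str, str] = {}
    for k, m in sorted(roi.masks.items()):
        mask_path = mask_dir / f"{path.stem}_mask_{k:04d}.tif"
        tifffile.imwrite(mask_path, m.astype(np.uint8) * 255, photometric="minisblack")
        try:
            rel = mask_path.relative_to(path.parent)
        except ValueError:
            rel = mask_path
        entries[str(k)] = str(rel)
    with open(path, "w") as fh:
        json.dump({"ap": list(roi.ap), "stride": roi.stride, "masks": entries}, fh)
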