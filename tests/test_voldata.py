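"""Volume containers, TIFF stack I/O, manifests, ROIs and projection."""

import numpy as np
import pytest
import tifffile
from hypothesis import given
from hypothesis import strategies as st

from optquant.voldata import (
    BoxROI,
    BrainSample,
    ChannelVolume,
    NicheROI,
    VoxelGeometry,
    load_box_roi,
    load_manifest,
    load_niche_roi,
    max_project_horizontal,
    read_channel,
    save_box_roi,
    save_niche_roi,
    write_channel,
)


class TestVoxelGeometry:
    def test_voxel_volume_is_pixel_size_cubed(self):
        assert VoxelGeometry(5.0).voxel_volume_um3 == 125.0
        assert VoxelGeometry(4.5).voxel_volume_um3 == pytest.approx(91.125)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_rejects_nonpositive_pixel_size(self, bad):
        with pytest.raises(ValueError):
            VoxelGeometry(bad)


class TestChannelVolume:
    def test_rejects_out_of_domain_and_wrong_rank(self):
        with pytest.raises(ValueError):
            ChannelVolume(np.full((2, 2, 2), 70000, dtype=np.int64))
        with pytest.raises(ValueError):
            ChannelVolume(np.zeros((2, 2), dtype=np.uint16))
        with pytest.raises(ValueError):
            ChannelVolume(np.zeros((0, 2, 2), dtype=np.uint16))

    def test_brain_sample_requires_matching_extents(self):
        a = ChannelVolume(np.zeros((2, 3, 4), dtype=np.uint16))
        b = ChannelVolume(np.zeros((2, 3, 5), dtype=np.uint16))
        with pytest.raises(ValueError):
            BrainSample("s", "control", {"edu": a, "autofluorescence": b}, VoxelGeometry(5))


class TestTiffRoundTrip:
    def test_shape_passthrough(self, tmp_path, rng):
        arr = rng.integers(0, 65536, (10, 64, 64)).astype(np.uint16)
        path = tmp_path / "v.tif"
        write_channel(ChannelVolume(arr), path)
        assert read_channel(path).shape == (10, 64, 64)

    def test_round_trip_is_bit_exact(self, tmp_path, rng):
        arr = rng.integers(0, 65536, (5, 16, 17)).astype(np.uint16)
        path = tmp_path / "v.tif"
        write_channel(ChannelVolume(arr), path)
        np.testing.assert_array_equal(read_channel(path).intensities, arr)

    def test_8bit_rescaled_by_257(self, tmp_path):
        arr8 = np.array([[[0, 1], [128, 255]]], dtype=np.uint8)
        path = tmp_path / "v8.tif"
        tifffile.imwrite(path, arr8[0])
        vol = read_channel(path)
        np.testing.assert_array_equal(vol.intensities, arr8.astype(np.uint16) * 257)
        assert vol.intensities.max() == 65535  # 255 * 257

    def test_rejects_rgb_pages(self, tmp_path):
        rgb = np.zeros((4, 4, 3), dtype=np.uint8)
        path = tmp_path / "rgb.tif"
        tifffile.imwrite(path, rgb, photometric="rgb")
        with pytest.raises(ValueError, match="page 0"):
            read_channel(path)

    def test_rejects_inconsistent_page_shapes(self, tmp_path):
        path = tmp_path / "mixed.tif"
        with tifffile.TiffWriter(path) as tw:
            tw.write(np.zeros((4, 4), dtype=np.uint16))
            tw.write(np.zeros((5, 4), dtype=np.uint16))
        with pytest.raises(ValueError, match="page 1"):
            read_channel(path)


class TestMaxProjection:
    def test_single_voxel_projects_to_its_column(self):
        arr = np.zeros((6, 9, 8), dtype=np.uint16)
        arr[3, 7, 5] = 900
        img = max_project_horizontal(ChannelVolume(arr))
        assert img[3, 5] == 900
        assert img.sum() == 900

    def test_random_volume_matches_loop_oracle(self, rng):
        arr = rng.integers(0, 65536, (4, 5, 6)).astype(np.uint16)
        img = max_project_horizontal(ChannelVolume(arr))
        for i in range(4):
            for k in range(6):
                assert img[i, k] == max(arr[i, j, k] for j in range(5))

    def test_idempotent_under_dv_duplication(self, rng):
        arr = rng.integers(0, 65536, (3, 4, 5)).astype(np.uint16)
        doubled = np.concatenate([arr, arr], axis=1)
        np.testing.assert_array_equal(
            max_project_horizontal(ChannelVolume(arr)),
            max_project_horizontal(ChannelVolume(doubled)),
        )

    @given(st.integers(min_value=1, max_value=1000))
    def test_commutes_with_monotone_remap(self, offset):
        rng = np.random.default_rng(7)
        arr = rng.integers(0, 60000, (3, 4, 5)).astype(np.uint16)

        def f(x):
            return np.minimum(x.astype(np.int64) + offset, 65535).astype(np.uint16)

        left = max_project_horizontal(ChannelVolume(f(arr)))
        right = f(max_project_horizontal(ChannelVolume(arr)))
        np.testing.assert_array_equal(left, right)


class TestROIs:
    def test_box_roi_validation(self):
        roi = BoxROI(ap=(0, 5), dv=(1, 3), lr=(0, 4))
        roi.validate((5, 3, 4))
        with pytest.raises(ValueError):
            roi.validate((4, 3, 4))
        with pytest.raises(ValueError):
            BoxROI(ap=(3, 3), dv=(0, 1), lr=(0, 1))

    def test_niche_roi_validation(self):
        mask = np.ones((3, 4), bool)
        niche = NicheROI(ap=(2, 10), stride=5, masks={2: mask, 7: mask})
        assert niche.sampled_indices() == [2, 7]
        with pytest.raises(ValueError):
            NicheROI(ap=(2, 10), stride=0, masks={})
        with pytest.raises(ValueError):
            NicheROI(ap=(2, 10), stride=5, masks={11: mask})
        with pytest.raises(ValueError):
            niche.validate((12, 9, 9))  # mask shape mismatch

    def test_box_roi_json_round_trip(self, tmp_path):
        roi = BoxROI(ap=(1, 9), dv=(0, 4), lr=(2, 6))
        path = tmp_path / "roi.json"
        save_box_roi(roi, path)
        assert load_box_roi(path) == roi

    def test_niche_roi_json_round_trip(self, tmp_path, rng):
        masks = {i: rng.random((6, 7)) > 0.5 for i in (0, 5)}
        niche = NicheROI(ap=(0, 8), stride=5, masks=masks)
        path = tmp_path / "niche.json"
        save_niche_roi(niche, path)
        loaded = load_niche_roi(path)
        assert loaded.ap == niche.ap and loaded.stride == 5
        for k in masks:
            np.testing.assert_array_equal(loaded.masks[k], masks[k])


class TestManifest:
    def _write(self, tmp_path, rows, header=None):
        header = header or "sample_id,group,pixel_size_um,edu_path,autofluorescence_path"
        path = tmp_path / "manifest.csv"
        path.write_text("\n".join([header] + rows) + "\n")
        return path

    def _touch_channels(self, tmp_path, names):
        for n in names:
            arr = np.zeros((2, 3, 3), dtype=np.uint16)
            write_channel(ChannelVolume(arr), tmp_path / n)

    def test_valid_manifest_loads_records(self, tmp_path):
        self._touch_channels(tmp_path, ["a_e.tif", "a_af.tif", "b_e.tif", "b_af.tif"])
        path = self._write(
            tmp_path,
            ["a,control,5.0,a_e.tif,a_af.tif", "b,1dpl,5.0,b_e.tif,b_af.tif"],
        )
        manifest = load_manifest(path)
        assert len(manifest) == 2
        assert manifest.groups == ["control", "1dpl"]
        sample = manifest.load_sample(manifest.records[0])
        assert sample.shape == (2, 3, 3) and sample.group == "control"

    def test_duplicate_sample_id_rejected(self, tmp_path):
        self._touch_channels(tmp_path, ["a_e.tif", "a_af.tif"])
        path = self._write(
            tmp_path,
            ["a,control,5.0,a_e.tif,a_af.tif", "a,1dpl,5.0,a_e.tif,a_af.tif"],
        )
        with pytest.raises(ValueError, match="'a'"):
            load_manifest(path)

    def test_missing_column_rejected(self, tmp_path):
        path = self._write(
            tmp_path, ["a,control,x.tif"], header="sample_id,group,edu_path"
        )
        with pytest.raises(ValueError, match="pixel_size_um"):
            load_manifest(path)

    def test_unknown_group_rejected_when_declared(self, tmp_path):
        self._touch_channels(tmp_path, ["a_e.tif", "a_af.tif"])
        path = self._write(tmp_path, ["a,5dpl,5.0,a_e.tif,a_af.tif"])
        with pytest.raises(ValueError, match="5dpl"):
            load_manifest(path, groups=["control", "1dpl"])

    def test_grouped_records(self, tmp_path):
        rows = []
        names = []
        for g in ("control", "1dpl", "3dpl", "7dpl"):
            for i in range(5):
                sid = f"{g}_{i}"
                names += [f"{sid}_e.tif", f"{sid}_af.tif"]
                rows.append(f"{sid},{g},5.0,{sid}_e.tif,{sid}_af.tif")
        self._touch_channels(tmp_path, names)
        manifest = load_manifest(self._write(tmp_path, rows))
        assert len(manifest) == 20
        assert len(manifest.groups) == 4
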