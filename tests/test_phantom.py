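"""Phantom generator: determinism, Poisson statistics, ground truth."""

import numpy as np
import pytest

from optquant.phantom import (
    NicheSpec,
    PhantomSpec,
    brain_mask,
    generate_cohort,
    generate_sample,
    hemisphere_box,
    niche_box,
    niche_region,
    niche_roi,
)
from optquant.quantize import nonblack_bins
from optquant.roi_volume import slice_volume, structure_volume
from optquant.voldata import BoxROI


def small_spec(**overrides):
    """Tiny single-niche phantom for fast statistical checks."""
    kwargs = dict(
        shape=(40, 24, 24),
        brain_semiaxes_um=(95.0, 55.0, 55.0),
        niches=(
            NicheSpec(
                name="niche",
                ap_span_um=(30.0, 120.0),
                kind="midline_band",
                hemisphere=None,
                focus_rate_per_um3=3e-4,
            ),
        ),
        parenchyma_amplitude={g: 0.0 for g in ("control", "1dpl", "3dpl", "7dpl")},
        parenchyma_ap_span_um=(30.0, 120.0),
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


class TestDeterminism:
    def test_same_spec_and_seed_bit_identical(self, default_phantom_spec):
        s1, t1 = generate_sample(default_phantom_spec, "3dpl", 77)
        s2, t2 = generate_sample(default_phantom_spec, "3dpl", 77)
        for name in s1.channels:
            np.testing.assert_array_equal(
                s1.channels[name].intensities, s2.channels[name].intensities
            )
        assert t1.niche_focus_counts == t2.niche_focus_counts

    def test_different_seeds_differ(self, default_phantom_spec):
        s1, _ = generate_sample(default_phantom_spec, "control", 1)
        s2, _ = generate_sample(default_phantom_spec, "control", 2)
        assert (s1.channel("edu").intensities != s2.channel("edu").intensities).any()


class TestSignalStatistics:
    def test_no_signal_matches_noise_model(self):
        spec = small_spec(
            niches=(
                NicheSpec(
                    name="niche",
                    ap_span_um=(30.0, 120.0),
                    kind="midline_band",
                    focus_rate_per_um3=0.0,
                ),
            )
        )
        sample, truth = generate_sample(spec, "control", 5)
        assert all(v == 0 for v in truth.niche_focus_counts.values())
        edu = sample.channel("edu").intensities.astype(float)
        # clipped N(0, sd): mean sd/sqrt(2*pi), measured over many voxels
        expected = spec.noise_sd / np.sqrt(2 * np.pi)
        tol = 3 * spec.noise_sd / np.sqrt(edu.size)
        assert abs(edu.mean() - expected) < max(tol, 0.01 * expected + tol)

    def test_poisson_focus_count_recovery(self):
        spec = small_spec()
        niche = spec.niches[0]
        region_voxels = int(niche_region(spec, niche).sum())
        lam = niche.focus_rate_per_um3 * region_voxels * spec.pixel_size_um**3
        n_rep = 200
        counts = [
            generate_sample(spec, "control", seed)[1].niche_focus_counts["niche"]
            for seed in range(n_rep)
        ]
        assert abs(np.mean(counts) - lam) < 3 * np.sqrt(lam) / np.sqrt(n_rep)

    def test_empty_niche_named_in_error(self):
        spec = small_spec(
            niches=(
                NicheSpec(name="ghost", ap_span_um=(300.0, 310.0), kind="midline_band"),
            )
        )
        with pytest.raises(ValueError, match="ghost"):
            generate_sample(spec, "control", 0)

    def test_unknown_group_rejected(self, default_phantom_spec):
        with pytest.raises(ValueError, match="14dpl"):
            generate_sample(default_phantom_spec, "14dpl", 0)


class TestGroundTruthRecovery:
    def test_exact_recovery_without_blur_or_noise(self, quiet_phantom_spec):
        # the whole-grid box captures focus spheres protruding past the
        # niche's bounding box; with one niche and no blur/noise the
        # structure volume equals the true focus-voxel volume exactly
        sample, truth = generate_sample(quiet_phantom_spec, "control", 11)
        nap, ndv, nlr = quiet_phantom_spec.shape
        box = BoxROI((0, nap), (0, ndv), (0, nlr))
        res = structure_volume(sample, "edu", box, bins_used=nonblack_bins())
        assert res.volume_um3 == truth.niche_focus_voxels["anterior"] * 125.0

    def test_recovery_with_default_blur_bounded(self, default_phantom_spec):
        sample, truth = generate_sample(default_phantom_spec, "control", 13)
        inner = niche_box(default_phantom_spec, "cerebellar")
        shape = default_phantom_spec.shape
        box = BoxROI(
            *(
                (max(a - 3, 0), min(b + 3, n))
                for (a, b), n in zip((inner.ap, inner.dv, inner.lr), shape)
            )
        )
        res = structure_volume(sample, "edu", box, bins_used=nonblack_bins())
        true_vol = truth.niche_focus_voxels["cerebellar"] * 125.0
        # blur trades focus-core voxels for a halo: same order of magnitude
        assert 0.5 * true_vol <= res.volume_um3 <= 5.0 * true_vol

    def test_structure_vs_slice_dichotomy(self):
        """Parenchymal infiltrate inflates hemisphere Structure Analysis but
        barely moves niche-restricted Slice Analysis."""
        base = dict(
            shape=(60, 32, 32),
            brain_semiaxes_um=(140.0, 75.0, 75.0),
            niches=(
                NicheSpec(
                    name="pallial",
                    ap_span_um=(40.0, 160.0),
                    kind="midline_band",
                    hemisphere="left",
                ),
            ),
            parenchyma_ap_span_um=(40.0, 160.0),
        )
        quiet = PhantomSpec(
            **base, parenchyma_amplitude={"control": 0.0, "1dpl": 0.0}
        )
        loud = PhantomSpec(
            **base, parenchyma_amplitude={"control": 0.0, "1dpl": 12000.0}
        )
        s_ctrl, _ = generate_sample(quiet, "1dpl", 21)
        s_les, _ = generate_sample(loud, "1dpl", 21)  # same seed: same foci
        box = hemisphere_box(loud, "left")
        roi = niche_roi(loud, "pallial")
        structure_ctrl = structure_volume(s_ctrl, "edu", box).volume_um3
        structure_les = structure_volume(s_les, "edu", box).volume_um3
        slice_ctrl = slice_volume(s_ctrl, "edu", roi).volume_um3
        slice_les = slice_volume(s_les, "edu", roi).volume_um3
        assert structure_les > 1.5 * structure_ctrl
        assert abs(slice_les - slice_ctrl) <= 0.2 * slice_ctrl


class TestCohort:
    def test_cohort_counts_and_reproducibility(self, default_phantom_spec):
        npg = {"control": 2, "1dpl": 1, "3dpl": 1, "7dpl": 2}
        samples1, manifest1, truth1 = generate_cohort(default_phantom_spec, npg, seed=31)
        samples2, _, _ = generate_cohort(default_phantom_spec, npg, seed=31)
        assert len(samples1) == 6 and len(manifest1) == 6
        groups = [s.group for s in samples1]
        assert groups.count("control") == 2 and groups.count("7dpl") == 2
        np.testing.assert_array_equal(
            samples1[0].channel("edu").intensities,
            samples2[0].channel("edu").intensities,
        )
        assert set(truth1["sample_id"]) == {s.sample_id for s in samples1}

    def test_cohort_on_disk(self, tiny_cohort_dir):
        from optquant.voldata import load_manifest

        manifest = load_manifest(tiny_cohort_dir / "manifest.csv")
        assert len(manifest) == 8
        sample = manifest.load_sample(manifest.records[0])
        assert set(sample.channels) == {"edu", "autofluorescence"}
        assert (tiny_cohort_dir / "ground_truth.csv").exists()
        assert (tiny_cohort_dir / "rois" / "pallial_ipsi.json").exists()

    def test_invalid_counts(self, default_phantom_spec):
        with pytest.raises(ValueError):
            generate_cohort(default_phantom_spec, {"control": 0}, seed=1)
        with pytest.raises(ValueError):
            generate_cohort(default_phantom_spec, {"nope": 2}, seed=1)


class TestGeometryHelpers:
    def test_brain_mask_inside_grid(self, default_phantom_spec):
        mask = brain_mask(default_phantom_spec)
        assert mask.any()
        assert not mask[0].any() and not mask[-1].any()  # poles clear of edges

    def test_niche_boxes_and_rois_consistent(self, default_phantom_spec):
        for niche in default_phantom_spec.niches:
            region = niche_region(default_phantom_spec, niche)
            box = niche_box(default_phantom_spec, niche.name)
            assert region[box.slices()].sum() == region.sum()
            roi = niche_roi(default_phantom_spec, niche.name)
            assert roi.sampled_indices()[0] == box.ap[0]
            for k, m in roi.masks.items():
                np.testing.assert_array_equal(m, region[k])

    def test_hemisphere_boxes_partition_lr(self, default_phantom_spec):
        left = hemisphere_box(default_phantom_spec, "left")
        right = hemisphere_box(default_phantom_spec, "right")
        assert left.lr[1] == right.lr[0]
        assert left.ap == right.ap
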