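"""Segmentation, puncta counting, local MFI and the outlier rule."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

import ivcyto as iv
from ivcyto.cytometry import (
    PunctaParams,
    SegmentationParams,
    classify_damage,
    detect_puncta,
    dose_damage_association,
    exclude_outliers,
    measure_local_mfi,
    segment_nuclei,
)
from ivcyto.model import LabelVolume, ValidationError, VoxelGrid
from ivcyto.synth import _add_gaussian_spot, _paint_sphere

VS = (1.0, 0.5, 0.5)


def _damage_grid(img, vs=VS):
    zeros = np.zeros_like(img)
    return VoxelGrid(np.stack([zeros, zeros, img, zeros]), vs, ("vehicle", "payload", "damage", "macrophage"))


def _sphere_labels(shape, spheres, vs=VS):
    labels = np.zeros(shape, dtype=np.int32)
    for lab, (centre, r) in enumerate(spheres, start=1):
        _paint_sphere(labels, centre, r, vs, value=lab)
    return LabelVolume(labels)


class TestSegmentNuclei:
    def test_all_zero_volume_yields_no_labels(self):
        grid = _damage_grid(np.zeros((16, 32, 32)))
        assert segment_nuclei(grid).n_labels == 0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            SegmentationParams(min_volume=100.0, max_volume=50.0)

    def test_two_touching_spheres_split_by_watershed(self):
        # centres 1.6 radii apart -> overlapping masks, two seeds
        img = np.zeros((20, 48, 48))
        r = 4.0
        c1, c2 = (10.0, 12.0, 12.0), (10.0, 12.0, 12.0 + 1.6 * r)
        _paint_sphere(img, c1, r, VS, value=50.0)
        _paint_sphere(img, c2, r, VS, value=50.0)
        params = SegmentationParams(
            threshold_method="fixed", fixed_threshold=10.0, watershed_min_distance=5.0
        )
        labels = segment_nuclei(_damage_grid(img), params)
        assert labels.n_labels == 2

    def test_labels_are_contiguous_and_volume_filtered(self, default_tissue, default_analysis):
        grid, _ = default_tissue
        nuclei, _, _ = default_analysis
        ids = np.unique(nuclei.labels)
        assert ids[0] == 0
        assert np.array_equal(ids[1:], np.arange(1, nuclei.n_labels + 1))
        voxel_vol = float(np.prod(grid.voxel_size))
        params = SegmentationParams()
        for lab in range(1, nuclei.n_labels + 1):
            vol = (nuclei.labels == lab).sum() * voxel_vol
            assert params.min_volume <= vol <= params.max_volume

    def test_ground_truth_recovery_without_merges(self, default_tissue, default_analysis):
        from conftest import match_to_ground_truth

        grid, gt = default_tissue
        nuclei, _, _ = default_analysis
        matched, idx = match_to_ground_truth(nuclei, gt, grid.voxel_size)
        assert matched.mean() >= 0.95
        # 1-to-1: no two truth cells share a segmented label (no merges)
        assert len(set(idx[matched])) == matched.sum()


class TestDetectPuncta:
    def test_uniform_nucleus_has_zero_puncta(self):
        img = np.zeros((16, 32, 32))
        _paint_sphere(img, (8.0, 8.0, 8.0), 4.0, VS, value=50.0)
        nuclei = _sphere_labels(img.shape, [((8.0, 8.0, 8.0), 4.0)])
        assert detect_puncta(_damage_grid(img), nuclei)[0] == 0

    def test_five_planted_spots_are_counted(self):
        img = np.zeros((20, 40, 40))
        centre = (10.0, 10.0, 10.0)
        _paint_sphere(img, centre, 4.0, VS, value=50.0)
        spots = [(10, 10, 10), (10, 12.5, 10), (8, 10, 11.5), (12, 8.5, 9), (10, 10, 7.5)]
        for s in spots:
            _add_gaussian_spot(img, s, 0.6, 150.0, VS)
        nuclei = _sphere_labels(img.shape, [(centre, 4.0)])
        assert detect_puncta(_damage_grid(img), nuclei)[0] == 5

    def test_spots_outside_the_mask_are_ignored(self):
        img = np.zeros((20, 40, 40))
        centre = (10.0, 10.0, 10.0)
        _paint_sphere(img, centre, 4.0, VS, value=50.0)
        inside = [(10, 10, 10), (10, 12.5, 10), (8, 10, 11.5)]
        outside = [(10, 10, 17.0), (10, 17.0, 10)]
        for s in inside + outside:
            _add_gaussian_spot(img, s, 0.6, 150.0, VS)
        nuclei = _sphere_labels(img.shape, [(centre, 4.0)])
        assert detect_puncta(_damage_grid(img), nuclei)[0] == 3

    def test_count_invariant_to_uniform_intensity_scaling(self):
        img = np.zeros((20, 40, 40))
        centre = (10.0, 10.0, 10.0)
        _paint_sphere(img, centre, 4.0, VS, value=50.0)
        for s in [(10, 10, 10), (10, 12.5, 10), (8, 10, 11.5)]:
            _add_gaussian_spot(img, s, 0.6, 150.0, VS)
        nuclei = _sphere_labels(img.shape, [(centre, 4.0)])
        for c in (0.01, 1.0, 250.0):
            assert detect_puncta(_damage_grid(c * img), nuclei)[0] == 3

    def test_end_to_end_count_recovery(self, default_tissue, default_analysis):
        from conftest import match_to_ground_truth

        grid, gt = default_tissue
        nuclei, counts, _ = default_analysis
        matched, idx = match_to_ground_truth(nuclei, gt, grid.voxel_size)
        r = np.corrcoef(counts[idx[matched]], gt.true_puncta_counts[matched])[0, 1]
        assert r >= 0.9


class TestMeasureLocalMfi:
    def test_constant_image_gives_constant_mfi_any_radius(self):
        img = np.full((16, 32, 32), 7.25)
        nuclei = _sphere_labels(img.shape, [((8.0, 8.0, 8.0), 3.0)])
        grid = VoxelGrid(
            np.stack([img, img, img, np.zeros_like(img)]), VS,
            ("vehicle", "payload", "damage", "macrophage"),
        )
        for radius in (0.0, 2.0, 5.0):
            assert measure_local_mfi(grid, nuclei, radius, "payload")[0] == pytest.approx(7.25)

    def test_brute_force_enumeration_oracle_on_toy_volume(self):
        rng = np.random.default_rng(3)
        img = rng.random((8, 8, 8))
        vs = (1.0, 1.0, 1.0)
        labels = np.zeros((8, 8, 8), dtype=np.int32)
        labels[3:5, 3:5, 3:5] = 1
        grid = VoxelGrid(
            np.stack([img, img, img, np.zeros_like(img)]), vs,
            ("vehicle", "payload", "damage", "macrophage"),
        )
        radius = 2.0
        got = measure_local_mfi(grid, LabelVolume(labels), radius, "payload")[0]
        # oracle: voxel within radius of ANY nucleus voxel, by direct loops
        nucleus = np.argwhere(labels == 1)
        sel = []
        for z in range(8):
            for y in range(8):
                for x in range(8):
                    d = np.min(np.linalg.norm(nucleus - (z, y, x), axis=1))
                    if d <= radius:
                        sel.append(img[z, y, x])
        assert got == pytest.approx(np.mean(sel), abs=1e-9)

    def test_radius_zero_measures_nucleus_mask_only(self):
        img = np.zeros((8, 8, 8))
        labels = np.zeros((8, 8, 8), dtype=np.int32)
        labels[4, 4, 4] = 1
        img[4, 4, 4] = 5.0
        img[4, 4, 5] = 100.0
        grid = VoxelGrid(
            np.stack([img, img, img, np.zeros_like(img)]), (1, 1, 1),
            ("vehicle", "payload", "damage", "macrophage"),
        )
        assert measure_local_mfi(grid, LabelVolume(labels), 0.0, "payload")[0] == 5.0

    def test_mfi_non_increasing_with_radius_for_central_hotspot(self):
        img = np.zeros((16, 32, 32))
        centre = (8.0, 8.0, 8.0)
        _paint_sphere(img, centre, 3.0, VS, value=10.0)
        nuclei = _sphere_labels(img.shape, [(centre, 3.0)])
        grid = _damage_grid(img)
        grid = VoxelGrid(
            np.stack([img, img, img, np.zeros_like(img)]), VS,
            ("vehicle", "payload", "damage", "macrophage"),
        )
        mfis = [measure_local_mfi(grid, nuclei, r, "payload")[0] for r in (0, 1, 2, 4, 8)]
        assert all(a >= b for a, b in zip(mfis, mfis[1:]))


class TestClassifyAndOutliers:
    def test_threshold_boundary(self):
        classes, frac = classify_damage([4, 5], threshold=5)
        assert list(classes) == ["low", "high"]
        assert frac == 0.5

    def test_all_zero_counts_give_zero_high_fraction(self):
        _, frac = classify_damage([0] * 10)
        assert frac == 0.0

    def test_identical_values_exclude_nothing(self):
        assert exclude_outliers([3.0] * 8).all()

    def test_two_sd_rule_matches_normal_tail_mass(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(100_000)
        excluded = 1.0 - exclude_outliers(x).mean()
        assert excluded == pytest.approx(2 * stats.norm.cdf(-2.0), abs=0.002)

    def test_hand_recomputed_mask_on_seven_values(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 100.0])
        mean, sd = x.mean(), x.std(ddof=1)
        expected = np.abs(x - mean) <= 2 * sd
        assert np.array_equal(exclude_outliers(x), expected)
        assert not expected[-1]  # the gross outlier goes


def _cells(payload, vehicle, counts):
    return pd.DataFrame(
        {"puncta_count": counts, "payload_mfi": payload, "vehicle_mfi": vehicle}
    )


class TestDoseDamageAssociation:
    def test_identical_mfis_give_unit_ratio_nonsignificant(self):
        df = _cells([5.0] * 40, [5.0] * 40, [1, 8] * 20)
        res = dose_damage_association(df)
        assert res["payload"]["ratio_high_low"] == pytest.approx(1.0)
        assert not (res["payload"]["anova_p"] < 0.05)

    def test_constructed_fourfold_ratio(self):
        counts = [1] * 20 + [8] * 20
        payload = [2.0] * 20 + [8.0] * 20
        res = dose_damage_association(_cells(payload, payload, counts))
        assert res["payload"]["ratio_high_low"] == pytest.approx(4.0)

    def test_empty_class_is_flagged(self):
        df = _cells([1.0] * 10, [1.0] * 10, [0] * 10)
        res = dose_damage_association(df)
        assert res["payload"]["flag"] is not None
        assert np.isnan(res["payload"]["ratio_high_low"])

    def test_synthetic_cohort_with_and_without_damage_link(self):
        """A dosed cohort (slope 4) shows a larger high-damage fraction
        than an undosed one (slope 0), n=500 cells pooled."""
        frac = {}
        for slope in (4.0, 0.0):
            highs = []
            for seed in (50, 51, 52):
                _, gt = iv.generate_tissue(
                    iv.SynthConfig(
                        seed=seed, damage_link_slope=slope, n_cells=170,
                        volume_shape=(48, 224, 224),
                    )
                )
                highs.append(gt.true_puncta_counts >= 5)
            frac[slope] = np.concatenate(highs).mean()
        assert frac[4.0] > frac[0.0]
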