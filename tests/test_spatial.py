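"""Co-localization, CV heterogeneity and proximity statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ivcyto.model import ValidationError, VoxelGrid
from ivcyto.spatial import (
    manders_coloc,
    neighbour_damage_contrast,
    pearson_coloc,
    proximity_profile,
    spatial_cv,
)


def _grid(a, b=None, vs=(1.0, 1.0, 1.0)):
    b = a if b is None else b
    zeros = np.zeros_like(a)
    return VoxelGrid(
        np.stack([a, b, zeros, zeros]).astype(float), vs,
        ("vehicle", "payload", "damage", "macrophage"),
    )


class TestPearson:
    def test_channel_against_itself_is_one(self):
        a = np.random.default_rng(0).random((4, 4, 4))
        assert pearson_coloc(_grid(a, a), "vehicle", "payload").pearson_rho == pytest.approx(1.0)

    def test_negated_channel_is_minus_one(self):
        a = np.random.default_rng(1).random((4, 4, 4))
        res = pearson_coloc(_grid(a, 10.0 - a), "vehicle", "payload")
        assert res.pearson_rho == pytest.approx(-1.0)

    def test_textbook_covariance_formula_oracle(self):
        rng = np.random.default_rng(5)
        a, b = rng.random((4, 5, 5)), rng.random((4, 5, 5))
        mask = rng.random((4, 5, 5)) < 0.5
        got = pearson_coloc(_grid(a, b), "vehicle", "payload", mask).pearson_rho
        av, bv = a[mask], b[mask]
        cov = np.mean((av - av.mean()) * (bv - bv.mean()))
        expected = cov / (av.std() * bv.std())
        assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_is_flagged_not_crashed(self):
        a = np.ones((3, 3, 3))
        res = pearson_coloc(_grid(a, a), "vehicle", "payload")
        assert res.flag is not None and np.isnan(res.pearson_rho)

    @given(st.floats(min_value=0.1, max_value=50.0), st.floats(min_value=-5.0, max_value=5.0))
    def test_affine_gain_invariance(self, gain, shift):
        rng = np.random.default_rng(7)
        a, b = rng.random((3, 4, 4)), rng.random((3, 4, 4))
        base = pearson_coloc(_grid(a, b), "vehicle", "payload").pearson_rho
        scaled = pearson_coloc(_grid(gain * a + shift, b), "vehicle", "payload").pearson_rho
        assert scaled == pytest.approx(base, abs=1e-9)


class TestManders:
    def test_identical_channels_give_unity(self):
        a = np.random.default_rng(2).random((4, 4, 4))
        res = manders_coloc(_grid(a, a), "vehicle", "payload", thresholds=(0.3, 0.3))
        assert res.manders_m1 == pytest.approx(1.0)
        assert res.manders_m2 == pytest.approx(1.0)

    def test_disjoint_supports_give_zero(self):
        a = np.zeros((2, 4, 4))
        b = np.zeros((2, 4, 4))
        a[0] = 5.0
        b[1] = 5.0
        res = manders_coloc(_grid(a, b), "vehicle", "payload", thresholds=(1.0, 1.0))
        assert res.manders_m1 == 0.0 and res.manders_m2 == 0.0

    def test_hand_summation_on_toy_arrays(self):
        a = np.arange(25, dtype=float).reshape(1, 5, 5)
        b = a[:, ::-1, :].copy()
        ta, tb = 10.0, 12.0
        res = manders_coloc(_grid(a, b), "vehicle", "payload", thresholds=(ta, tb))
        m1_num = m1_den = m2_num = m2_den = 0.0
        for i in range(25):
            ai, bi = a.flat[i], b.flat[i]
            if ai > ta:
                m1_den += ai
                if bi > tb:
                    m1_num += ai
            if bi > tb:
                m2_den += bi
                if ai > ta:
                    m2_num += bi
        assert res.manders_m1 == pytest.approx(m1_num / m1_den, abs=1e-12)
        assert res.manders_m2 == pytest.approx(m2_num / m2_den, abs=1e-12)

    def test_background_percentile_default_thresholds_recorded(self):
        rng = np.random.default_rng(8)
        a, b = rng.random((4, 6, 6)), rng.random((4, 6, 6))
        mask = np.zeros((4, 6, 6), dtype=bool)
        mask[1:3, 2:4, 2:4] = True
        res = manders_coloc(_grid(a, b), "vehicle", "payload", mask)
        assert res.threshold_a == pytest.approx(np.percentile(a[~mask], 95))
        assert res.threshold_b == pytest.approx(np.percentile(b[~mask], 95))


class TestSpatialCV:
    def test_uniform_image_has_zero_cv(self):
        res = spatial_cv(_grid(np.full((4, 8, 8), 3.0)), "vehicle", roi_size=4.0)
        assert res.cv == 0.0

    def test_two_roi_hand_calculation(self):
        img = np.zeros((2, 2, 4))
        img[:, :, :2] = 1.0
        img[:, :, 2:] = 3.0
        res = spatial_cv(_grid(img), "vehicle", roi_size=2.0)
        # ROI MFIs {1, 3}: sd = sqrt(2), mean = 2 -> cv = sqrt(2)/2
        assert res.n_rois == 2
        assert res.cv == pytest.approx(np.sqrt(2.0) / 2.0, abs=1e-12)

    @given(st.floats(min_value=0.05, max_value=100.0))
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(9)
        img = rng.random((4, 8, 8)) + 0.5
        base = spatial_cv(_grid(img), "vehicle", roi_size=2.0).cv
        scaled = spatial_cv(_grid(c * img), "vehicle", roi_size=2.0).cv
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_too_few_rois_rejected(self):
        with pytest.raises(ValidationError):
            spatial_cv(_grid(np.ones((2, 2, 2))), "vehicle", roi_size=10.0)


class TestProximityProfile:
    def test_uniform_channel_gives_flat_profile_and_unit_fold(self):
        img = np.full((6, 10, 10), 2.0)
        mac = np.zeros((6, 10, 10), dtype=bool)
        mac[3, 5, 5] = True
        res = proximity_profile(_grid(img), "vehicle", mac, (0, 2, 4, 8))
        assert np.allclose(res.mean_intensity, 2.0)
        assert res.fold_vs_far == pytest.approx(1.0)

    def test_brute_force_distance_oracle_on_toy_volume(self):
        rng = np.random.default_rng(10)
        img = rng.random((8, 8, 8))
        mac = np.zeros((8, 8, 8), dtype=bool)
        mac[2, 2, 2] = True
        mac[6, 5, 4] = True
        vs = (2.0, 1.0, 1.0)
        edges = (0.0, 3.0, 6.0, 12.0)
        res = proximity_profile(_grid(img, vs=vs), "vehicle", mac, edges)
        mac_pos = np.argwhere(mac) * np.array(vs)
        for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
            vals = []
            for z in range(8):
                for y in range(8):
                    for x in range(8):
                        if mac[z, y, x]:
                            continue
                        p = np.array([z, y, x]) * np.array(vs)
                        d = np.min(np.linalg.norm(mac_pos - p, axis=1))
                        if lo <= d < hi:
                            vals.append(img[z, y, x])
            if vals:
                assert res.mean_intensity[i] == pytest.approx(np.mean(vals), abs=1e-9)

    def test_monotone_kernel_profile_non_increasing(self, noisefree_tissue):
        grid, _ = noisefree_tissue
        mac = grid.channel("macrophage") > 0
        res = proximity_profile(grid, "payload", mac, (0, 5, 10, 15, 20, 25, 30, 45))
        means = res.mean_intensity[np.isfinite(res.mean_intensity)]
        assert np.all(np.diff(means) <= 1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            proximity_profile(
                _grid(np.ones((3, 3, 3))), "vehicle", np.zeros((3, 3, 3), bool), (0, 1, 2)
            )


class TestNeighbourDamageContrast:
    def test_identical_cells_have_zero_contrast(self):
        df = pd.DataFrame(
            {
                "puncta_count": [3] * 20,
                "dist_to_macrophage_um": list(range(1, 21)),
            }
        )
        res = neighbour_damage_contrast(df, near_cut=10.5)
        assert res["difference"] == pytest.approx(0.0)
        assert res["ratio_near_far"] == pytest.approx(1.0)

    def test_constructed_double_puncta_near_cells(self):
        df = pd.DataFrame(
            {
                "puncta_count": [8] * 10 + [4] * 10,
                "dist_to_macrophage_um": [5.0] * 10 + [40.0] * 10,
            }
        )
        res = neighbour_damage_contrast(df)
        assert res["ratio_near_far"] == pytest.approx(2.0)

    def test_synthetic_cohort_shows_elevated_damage_near_depots(self, cohort):
        cells, _ = cohort
        finite = cells[np.isfinite(cells["dist_to_macrophage_um"])]
        res = neighbour_damage_contrast(finite)
        assert res["near_mean"] > res["far_mean"]
        assert res["n_samples"] >= 2
        assert res["paired_p"] < 0.05
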