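"""fMRI design construction, voxelwise GLM, thresholding and overlap."""

import numpy as np
import pandas as pd
import pytest

from wandertap import glm, synth


class TestHrf:
    def test_zero_at_origin(self):
        assert glm.double_gamma_hrf(0.0) == 0.0

    def test_single_peak_then_undershoot(self):
        t = np.arange(0, 32, 0.1)
        h = glm.double_gamma_hrf(t)
        body = h[np.abs(h) > 1e-4]
        signs = np.sign(body)
        assert (np.diff(signs) != 0).sum() == 1  # exactly one sign change
        assert h.max() == pytest.approx(1.0)
        assert h.min() < 0

    def test_impulse_convolution_identity(self):
        dt = 0.05
        t = np.arange(0, 32, dt)
        h = glm.double_gamma_hrf(t)
        u = np.zeros(t.size)
        u[0] = 1.0
        conv = np.convolve(u, h)[:t.size]
        np.testing.assert_allclose(conv, h)

    def test_invalid_shape_rejected(self):
        with pytest.raises(ValueError):
            glm.double_gamma_hrf(1.0, peak=10.0, undershoot=5.0)


class TestEventRegressor:
    def test_empty_onsets_zero_column(self):
        np.testing.assert_allclose(glm.events_to_regressor([], [], 1.8, 40), 0.0)

    def test_superposition(self):
        both = glm.events_to_regressor([10.0, 40.0], 0.0, 1.8, 50)
        a = glm.events_to_regressor([10.0], 0.0, 1.8, 50)
        b = glm.events_to_regressor([40.0], 0.0, 1.8, 50)
        np.testing.assert_allclose(both, a + b, atol=1e-9)

    def test_amplitude_linearity(self):
        one = glm.events_to_regressor([10.0], 0.0, 1.8, 50, amplitudes=[1.0])
        two = glm.events_to_regressor([10.0], 0.0, 1.8, 50, amplitudes=[2.0])
        np.testing.assert_allclose(two, 2 * one, atol=1e-12)

    def test_onset_beyond_scan_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="beyond the scan"):
            col = glm.events_to_regressor([10.0, 500.0], 0.0, 1.8, 50)
        np.testing.assert_allclose(col, glm.events_to_regressor([10.0], 0.0, 1.8, 50))


class TestPreprobeBoxcars:
    def test_all_on_task_gives_zero_off_column(self):
        off, on = glm.preprobe_boxcars([30.0, 90.0], [False, False], 1.8, 80)
        np.testing.assert_allclose(off, 0.0)
        assert on.max() > 0

    def test_interval_duration_10s(self):
        off, _ = glm.preprobe_boxcars([60.0], [True], 1.8, 60)
        ref = glm.events_to_regressor([50.0], [10.0], 1.8, 60)
        np.testing.assert_allclose(off, ref)

    def test_18s_variant_differs_only_in_duration(self):
        off18, _ = glm.preprobe_boxcars([60.0], [True], 1.8, 60, interval=18.0)
        ref = glm.events_to_regressor([42.0], [18.0], 1.8, 60)
        np.testing.assert_allclose(off18, ref)

    def test_truncated_at_block_start(self):
        off, _ = glm.preprobe_boxcars([12.0], [True], 1.8, 60, block_starts=[8.0])
        ref = glm.events_to_regressor([8.0], [4.0], 1.8, 60)
        np.testing.assert_allclose(off, ref)


class TestMarkerRegressor:
    def test_constant_series_constant_column(self):
        col = glm.marker_regressor([10.0, 20.0, 30.0], [2.5, 2.5, 2.5], 1.8, 30)
        np.testing.assert_allclose(col, 2.5)

    def test_nearest_rule_steps_at_midpoint(self):
        col = glm.marker_regressor([0.0, 18.0], [1.0, 5.0], 1.8, 11)
        vt = 1.8 * np.arange(11)
        expected = np.where(vt <= 9.0, 1.0, 5.0)  # exact midpoint ties to the earlier anchor
        np.testing.assert_allclose(col, expected)

    def test_volumes_before_first_anchor_hold_first_value(self):
        col = glm.marker_regressor([18.0, 36.0], [4.0, 8.0], 1.8, 12)
        assert col[0] == 4.0

    def test_convolve_mode_equals_event_regressor(self):
        anchors = [9.0, 27.0]
        vals = [1.5, 0.5]
        a = glm.marker_regressor(anchors, vals, 1.8, 30, mode="convolve")
        b = glm.events_to_regressor(anchors, 0.0, 1.8, 30, amplitudes=vals)
        np.testing.assert_allclose(a, b)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            glm.marker_regressor([], [], 1.8, 10)


class TestDctBasis:
    def test_orthonormal(self):
        D = glm.dct_basis(200, 1.8)
        np.testing.assert_allclose(D.T @ D, np.eye(D.shape[1]), atol=1e-12)

    def test_lowest_column_monotone_half_cosine(self):
        D = glm.dct_basis(200, 1.8)
        assert np.all(np.diff(D[:, 0]) < 0)

    def test_linear_drift_removed(self):
        D = glm.dct_basis(300, 1.8)
        drift = np.linspace(0, 1, 300)
        drift -= drift.mean()
        resid = drift - D @ (D.T @ drift)
        assert resid.var() / drift.var() < 0.01


class TestFitGlm:
    def test_contrast_difference_linearity(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(60), rng.standard_normal(60), rng.standard_normal(60)])
        beta = rng.standard_normal((4, 4, 4, 3))
        Y = synth.simulate_bold(X, beta, 0.0, rng)
        diff = glm.fit_glm(Y, X, [0, 1, -1])
        np.testing.assert_allclose(diff["beta"][..., 1] - diff["beta"][..., 2],
                                   beta[..., 1] - beta[..., 2], atol=1e-10)

    def test_rank_deficiency_warns_with_columns(self):
        X = pd.DataFrame({"a": np.ones(20), "b": np.ones(20)})
        Y = np.zeros((2, 2, 2, 20))
        with pytest.warns(UserWarning, match="rank deficient"):
            glm.fit_glm(Y, X, [1, 0])

    def test_design_row_mismatch_rejected(self):
        with pytest.raises(ValueError):
            glm.fit_glm(np.zeros((2, 2, 2, 10)), np.ones((12, 1)), [1])


class TestThresholdMap:
    def test_all_zero_map_empty(self):
        out = glm.threshold_map(np.zeros((8, 8, 8)))
        assert out["mask"].sum() == 0

    def test_single_cuboid_exact_size(self):
        z = np.zeros((10, 10, 10))
        z[2:5, 3:6, 4:6] = 5.0
        out = glm.threshold_map(z)
        assert out["cluster_sizes"] == {1: 18}

    def test_corner_touching_cuboids_one_component(self):
        z = np.zeros((10, 10, 10))
        z[2:4, 2:4, 2:4] = 5.0
        z[4:6, 4:6, 4:6] = 5.0  # touches only at the corner voxel diagonal
        out = glm.threshold_map(z)
        assert len(out["cluster_sizes"]) == 1  # 26-connectivity joins them

    def test_min_cluster_removes_small_components(self):
        z = np.zeros((10, 10, 10))
        z[1, 1, 1] = 5.0
        z[5:8, 5:8, 5:8] = 5.0
        out = glm.threshold_map(z, min_cluster=5)
        assert out["mask"].sum() == 27

    def test_nonfinite_rejected(self):
        z = np.zeros((4, 4, 4))
        z[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            glm.threshold_map(z)


class TestAtlasOverlap:
    def _parcels(self, shape=(10, 10, 10)):
        a = np.zeros(shape, bool)
        b = np.zeros(shape, bool)
        a[:, :, :5] = True
        b[:, :, 5:] = True
        return {"A": a, "B": b}

    def test_single_network_100_percent(self):
        m = np.zeros((10, 10, 10), bool)
        m[2:4, 2:4, 1:3] = True
        out = glm.atlas_overlap(m, self._parcels())
        assert out["A"] == 100.0 and out["B"] == 0.0

    def test_half_half(self):
        m = np.zeros((10, 10, 10), bool)
        m[5, 5, 3:7] = True
        out = glm.atlas_overlap(m, self._parcels())
        assert out["A"] == out["B"] == 50.0

    def test_wm_only_map_empty_after_exclusion(self):
        m = np.zeros((10, 10, 10), bool)
        m[0, 0, 0] = True
        wm = np.zeros((10, 10, 10), bool)
        wm[0, 0, 0] = True
        out = glm.atlas_overlap(m, self._parcels(), wm_mask=wm)
        assert (out == 0).all()

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(0)
        m = rng.random((10, 10, 10)) > 0.7
        out = glm.atlas_overlap(m, self._parcels())
        assert out.sum() == pytest.approx(100.0, abs=0.1)

    def test_uncovered_voxel_fails_loudly(self):
        parcels = self._parcels()
        parcels["B"][:, :, 9] = False  # puncture the cover
        m = np.zeros((10, 10, 10), bool)
        m[3, 3, 9] = True
        with pytest.raises(ValueError, match="no parcel"):
            glm.atlas_overlap(m, parcels)


class TestDice:
    def test_identical_maps(self):
        m = np.zeros((4, 4, 4), bool)
        m[1:3, 1:3, 1:3] = True
        assert glm.dice(m, m) == 1.0

    def test_disjoint_maps(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, 0] = True
        b[3, 3, 3] = True
        assert glm.dice(a, b) == 0.0

    def test_hand_counted_example(self):
        a = np.zeros(64, bool)
        b = np.zeros(64, bool)
        a[:4] = True
        b[1:7] = True  # |A|=4, |B|=6, |A&B|=3
        assert glm.dice(a.reshape(4, 4, 4), b.reshape(4, 4, 4)) == pytest.approx(0.6)

    def test_both_empty_defined_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert glm.dice(np.zeros((3, 3, 3), bool), np.zeros((3, 3, 3), bool)) == 0.0


class TestResampling:
    def test_identity_grid_preserves_labels(self):
        rng = np.random.default_rng(0)
        lab = rng.integers(0, 5, (8, 8, 8))
        aff = np.diag([2.0, 2.0, 2.0, 1.0])
        out = glm.resample_labels_nearest(lab, aff, (8, 8, 8), aff)
        np.testing.assert_array_equal(out, lab)

    def test_downsampling_preserves_label_values(self):
        lab = np.zeros((8, 8, 8), int)
        lab[4:, :, :] = 7
        src_aff = np.diag([1.0, 1.0, 1.0, 1.0])
        dst_aff = np.diag([2.0, 2.0, 2.0, 1.0])
        out = glm.resample_labels_nearest(lab, src_aff, (4, 4, 4), dst_aff)
        assert set(np.unique(out)) <= {0, 7}
        assert out[3, 0, 0] == 7 and out[0, 0, 0] == 0


class TestFullPipelineRecovery:
    def test_planted_marker_coupled_region_recovered(self):
        """BOLD with a BV-coupled cuboid yields a thresholded contrast map
        with Dice > 0.5 against the truth region at moderate noise."""
        rng = np.random.default_rng(7)
        n_vol, tr = 200, 1.8
        anchors = np.arange(18.0, n_vol * tr - 10, 0.75)
        bv = rng.standard_normal(anchors.size).cumsum() * 0.1
        bv = (bv - bv.mean()) / bv.std()
        col = glm.marker_regressor(anchors, bv, tr, n_vol)
        X = pd.DataFrame({"intercept": np.ones(n_vol), "bv": col})
        beta = np.zeros((12, 12, 12, 2))
        truth_region = np.zeros((12, 12, 12), bool)
        truth_region[3:7, 3:7, 3:7] = True
        beta[truth_region, 1] = 1.0
        Y = synth.simulate_bold(X.to_numpy(), beta, 1.0, rng)
        res = glm.fit_glm(Y, X, [0, 1])
        th = glm.threshold_map(res["z"], 2.3, min_cluster=4)
        assert glm.dice(th["mask"], truth_region) > 0.5
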