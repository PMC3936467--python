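import numpy as np
import pytest
from scipy import stats

from amygconn.errors import (DesignError, EstimationError, ResolutionError,
                             SampleSizeError, ValidationError)
from amygconn.grid import VolumeGrid
from amygconn.inference import (ClusterInferenceSpec, bonferroni_adjust,
                                cluster_report, covariate_association,
                                estimate_smoothness, group_contrast_map,
                                kmin_from_sizes, label_clusters,
                                mc_cluster_size_threshold, one_sample_map,
                                simulate_max_cluster_sizes,
                                stat_threshold_from_p, threshold_stat_map)
from amygconn.preprocess import smooth_gaussian


class TestOneSampleMap:
    def test_hand_computed_t(self):
        maps = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1, 1)
        sm = one_sample_map(maps, np.ones((1, 1, 1), dtype=bool))
        assert sm.df == 2
        assert sm.values[0, 0, 0] == pytest.approx(2.0 / (1.0 / np.sqrt(3)), abs=1e-3)
        assert sm.values[0, 0, 0] == pytest.approx(3.464, abs=1e-3)

    def test_constant_voxel_removed_from_mask(self):
        maps = np.full((4, 2, 1, 1), 5.0)
        maps[:, 1] = np.random.default_rng(0).standard_normal((4, 1, 1))
        sm = one_sample_map(maps, np.ones((2, 1, 1), dtype=bool))
        assert not sm.mask[0, 0, 0] and sm.mask[1, 0, 0]

    def test_null_calibration_at_p05(self, rng):
        maps = rng.standard_normal((22, 20, 20, 10))
        mask = np.ones((20, 20, 10), dtype=bool)
        sm = one_sample_map(maps, mask)
        thr = stat_threshold_from_p(0.05, sm.df, "t")
        frac = (np.abs(sm.values[sm.mask]) >= thr).mean()
        se = np.sqrt(0.05 * 0.95 / mask.sum())
        assert abs(frac - 0.05) < 4 * se

    def test_single_subject_rejected(self):
        with pytest.raises(SampleSizeError):
            one_sample_map(np.zeros((1, 2, 2, 2)), np.ones((2, 2, 2), dtype=bool))


class TestGroupContrast:
    def test_f_equals_squared_two_sample_t(self, rng):
        maps = rng.standard_normal((12, 4, 4, 2))
        labels = np.array(["a"] * 5 + ["b"] * 7)
        sm = group_contrast_map(maps, labels)
        t, _ = stats.ttest_ind(maps[labels == "b"], maps[labels == "a"], axis=0)
        np.testing.assert_allclose(sm.values, t * t, atol=1e-8)
        assert sm.df == (1, 10)

    def test_null_suprathreshold_fraction_matches_voxel_p(self, rng):
        maps = rng.standard_normal((45, 20, 20, 20))
        labels = np.array(["a"] * 24 + ["b"] * 21)
        rng.shuffle(labels)
        sm = group_contrast_map(maps, labels)
        thr = stat_threshold_from_p(0.005, sm.df, "F")
        frac = (sm.values[sm.mask] >= thr).mean()
        assert abs(frac - 0.005) < 0.0035

    def test_group_collinear_covariate_rejected(self, rng):
        maps = rng.standard_normal((8, 2, 2, 2))
        labels = np.array(["a"] * 4 + ["b"] * 4)
        g = (labels == "b").astype(float)
        with pytest.raises(DesignError):
            group_contrast_map(maps, labels, covariates=g)

    def test_constant_covariate_rejected(self, rng):
        maps = rng.standard_normal((8, 2, 2, 2))
        labels = np.array(["a"] * 4 + ["b"] * 4)
        with pytest.raises(DesignError):
            group_contrast_map(maps, labels, covariates=np.ones(8))

    def test_orthogonal_covariate_changes_f_only_through_df(self, rng):
        n = 10
        labels = np.array(["a"] * 5 + ["b"] * 5)
        g = (labels == "b").astype(float)
        cov = rng.standard_normal(n)
        base = np.column_stack([np.ones(n), g])
        q, _ = np.linalg.qr(base)
        cov -= q @ (q.T @ cov)                       # orthogonal to 1, group
        maps = rng.standard_normal((n, 3, 3, 3))
        flat = maps.reshape(n, -1)
        flat -= np.outer(cov / (cov @ cov), cov @ flat)  # y orthogonal to cov
        maps = flat.reshape(n, 3, 3, 3)
        f0 = group_contrast_map(maps, labels)
        f1 = group_contrast_map(maps, labels, covariates=cov)
        # identical fit, one fewer residual df: F scales by dfd ratio
        np.testing.assert_allclose(f1.values, f0.values * (n - 3) / (n - 2),
                                   atol=1e-8)

    def test_three_groups_rejected(self, rng):
        maps = rng.standard_normal((6, 2, 2, 2))
        with pytest.raises(DesignError):
            group_contrast_map(maps, np.array(["a", "a", "b", "b", "c", "c"]))


class TestStatThreshold:
    def test_normal_limit_at_p05(self):
        assert stat_threshold_from_p(0.05, np.inf, "t") == pytest.approx(1.960, abs=1e-3)

    def test_t_quantile_reproduces_display_threshold(self):
        # two-tailed p = 0.001 at 21 df, the conventional display threshold
        assert stat_threshold_from_p(0.001, 21, "t") == pytest.approx(3.82, abs=0.01)

    def test_monotone_in_p(self):
        assert (stat_threshold_from_p(0.001, 21, "t")
                > stat_threshold_from_p(0.01, 21, "t"))

    def test_f_threshold_squares_t(self):
        t = stat_threshold_from_p(0.005, 40, "t")
        f = stat_threshold_from_p(0.005, (1, 40), "F")
        assert f == pytest.approx(t * t, rel=1e-10)


from oracles import flood_fill_components as _flood_fill_oracle  # noqa: E402


class TestLabelClusters:
    def test_corner_touch_depends_on_neighborhood_rule(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True
        assert len(label_clusters(mask, neighborhood=26)) == 1
        assert len(label_clusters(mask, neighborhood=6)) == 2

    @pytest.mark.parametrize("neighborhood", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, neighborhood, rng):
        for _ in range(20):
            mask = rng.random((12, 12, 12)) < 0.15
            ours = {frozenset(map(tuple, cl.voxels))
                    for cl in label_clusters(mask, neighborhood=neighborhood)}
            assert ours == _flood_fill_oracle(mask, neighborhood)

    def test_empty_mask_gives_empty_set(self):
        assert label_clusters(np.zeros((3, 3, 3), dtype=bool)) == []

    def test_peak_and_sorting(self, rng):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[0:2, 0, 0] = True          # size 2
        mask[4:6, 4:6, 4] = True        # size 4
        vals = np.zeros((6, 6, 6))
        vals[0, 0, 0], vals[1, 0, 0] = 3.0, -7.0
        vals[4:6, 4:6, 4] = 1.0
        clusters = label_clusters(mask, stat_values=vals)
        assert [c.size for c in clusters] == [4, 2]
        assert clusters[1].peak_stat == -7.0       # largest |value| is the peak
        assert clusters[1].peak_ijk == (1, 0, 0)

    def test_peak_mm_uses_report_convention(self):
        grid = VolumeGrid(dims=(5, 5, 5), voxel_size=(2.0, 2.0, 2.0))
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[4, 2, 0] = True
        cl = label_clusters(mask, stat_values=np.ones((5, 5, 5)), grid=grid)[0]
        np.testing.assert_allclose(cl.peak_mm, (-4.0, 0.0, 4.0))


class TestMonteCarloClusterThreshold:
    MASK = np.ones((20, 20, 20), dtype=bool)

    def test_negligible_voxel_p_gives_kmin_one(self, rng):
        spec = ClusterInferenceSpec(voxel_p=1e-10, n_iterations=100, fwhm_mm=6.0)
        assert mc_cluster_size_threshold(self.MASK, spec, rng) == 1

    def test_kmin_monotone_in_alpha_on_shared_draws(self, rng):
        spec = ClusterInferenceSpec(n_iterations=200, fwhm_mm=6.0)
        sizes = simulate_max_cluster_sizes(self.MASK, spec, rng)
        assert kmin_from_sizes(sizes, 0.01) >= kmin_from_sizes(sizes, 0.05)

    def test_alpha_finer_than_resolution_rejected(self, rng):
        spec = ClusterInferenceSpec(cluster_alpha=0.001, n_iterations=100)
        with pytest.raises(ResolutionError):
            mc_cluster_size_threshold(self.MASK, spec, rng)


class TestEstimateSmoothness:
    VOX = (3.25, 3.25, 3.0)
    MASK = np.ones((24, 24, 18), dtype=bool)

    def test_white_noise_estimate_is_sub_voxel(self, rng):
        # varD ~ 2 var for white noise, so the estimate clamps at (or
        # fluctuates just above) zero - well under one voxel
        fwhm = estimate_smoothness(rng.standard_normal((24, 24, 18)),
                                   self.MASK, self.VOX)
        assert np.all(fwhm < 2.5)

    def test_recovers_known_kernel_within_ten_percent(self, rng):
        vols = np.stack([
            smooth_gaussian(rng.standard_normal((24, 24, 18)), 6.0, self.VOX)
            for _ in range(4)])
        fwhm = estimate_smoothness(vols, self.MASK, self.VOX)
        np.testing.assert_allclose(fwhm, 6.0, rtol=0.10)

    def test_scale_invariant(self, rng):
        vol = smooth_gaussian(rng.standard_normal((24, 24, 18)), 6.0, self.VOX)
        a = estimate_smoothness(vol, self.MASK, self.VOX)
        b = estimate_smoothness(vol * 10.0, self.MASK, self.VOX)
        np.testing.assert_allclose(a, b, rtol=1e-10)

    def test_tiny_mask_rejected(self, rng):
        mask = np.zeros((24, 24, 18), dtype=bool)
        mask[0, 0, :5] = True
        with pytest.raises(EstimationError):
            estimate_smoothness(rng.standard_normal((24, 24, 18)), mask, self.VOX)


class TestClusterReport:
    GRID = VolumeGrid(dims=(10, 10, 10), voxel_size=(3.0, 3.0, 3.0))

    def _stat_map_with_blob(self, size_x):
        vals = np.zeros((10, 10, 10))
        vals[:size_x, :5, :5] = 10.0
        from amygconn.inference import StatMap
        sm = StatMap("F", vals, (1, 40), np.ones((10, 10, 10), dtype=bool),
                     sign=np.ones((10, 10, 10)))
        return sm

    def test_no_suprathreshold_voxels_gives_empty_table(self):
        sm = self._stat_map_with_blob(0)
        clusters = threshold_stat_map(sm, 5.0, grid=self.GRID)
        table = cluster_report(sm, clusters, k_min=55)
        assert len(table) == 0
        assert list(table.columns) == ["contrast", "size_voxels", "peak_stat",
                                       "x_mm", "y_mm", "z_mm"]

    def test_cluster_above_kmin_reported(self):
        sm = self._stat_map_with_blob(4)   # 100 voxels
        clusters = threshold_stat_map(sm, 5.0, grid=self.GRID)
        assert len(cluster_report(sm, clusters, k_min=55)) == 1

    def test_cluster_below_kmin_suppressed(self):
        sm = self._stat_map_with_blob(2)   # 50 voxels
        clusters = threshold_stat_map(sm, 5.0, grid=self.GRID)
        assert len(cluster_report(sm, clusters, k_min=55)) == 0


class TestCovariateAssociation:
    def test_identical_series_correlate_perfectly(self):
        y = np.array([0.1, 0.4, 0.2, 0.9, 0.5])
        r, df, p = covariate_association(y, y)
        assert r == pytest.approx(1.0)
        assert df == 3 and p == pytest.approx(0.0, abs=1e-12)

    def test_four_point_hand_computation(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0.0, 1.0, 0.0, 1.0])
        # brute-force covariance formula
        expected = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        r, df, p = covariate_association(y, x)
        assert r == pytest.approx(expected, abs=1e-12)
        assert df == 2

    def test_binary_covariate_uses_two_sample_t(self, rng):
        y = rng.standard_normal(20)
        x = np.repeat([0.0, 1.0], 10)
        t, df, p = covariate_association(y, x)
        t_ref, p_ref = stats.ttest_ind(y[10:], y[:10])
        assert t == pytest.approx(float(t_ref))
        assert p == pytest.approx(float(p_ref))

    def test_controlling_for_itself_is_degenerate(self, rng):
        y = rng.standard_normal(10)
        x = rng.standard_normal(10)
        with pytest.raises(ValidationError):
            covariate_association(y, x, control=x)

    def test_zero_variance_covariate_rejected(self, rng):
        with pytest.raises(ValidationError):
            covariate_association(rng.standard_normal(6), np.ones(6))


class TestBonferroni:
    def test_three_posthoc_contrasts_display_value(self):
        value, display = bonferroni_adjust(0.05, 3)
        assert value == pytest.approx(0.05 / 3)
        assert display == 0.017

    @pytest.mark.parametrize("m,expected", [(1, 0.05), (5, 0.01)])
    def test_simple_divisions(self, m, expected):
        assert bonferroni_adjust(0.05, m)[0] == pytest.approx(expected)

    def test_zero_contrasts_rejected(self):
        with pytest.raises(ValidationError):
            bonferroni_adjust(0.05, 0)
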