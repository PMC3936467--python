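import numpy as np
import pytest

from amygconn.errors import (DegenerateTableError, SampleSizeError,
                             ValidationError)
from amygconn.inference import Cluster
from amygconn.loocv import (ConfusionTable, LeaveOneOutRelapseClassifier,
                            PredictorSpec, _match_cluster, chisq_vs_chance,
                            classification_metrics, cluster_mean_series,
                            fit_logistic, reconstruct_confusion, run_fold)


def _irls_oracle(X, y, tol=1e-12, maxiter=500):
    """Independent iteratively-reweighted-least-squares logistic fit."""
    X1 = np.column_stack([np.ones(len(y)), np.atleast_2d(X)])
    beta = np.zeros(X1.shape[1])
    for _ in range(maxiter):
        p = 1.0 / (1.0 + np.exp(-X1 @ beta))
        w = p * (1.0 - p)
        step = np.linalg.solve((X1.T * w) @ X1, X1.T @ (y - p))
        beta += step
        if np.abs(step).max() < tol:
            break
    return beta


class TestFitLogistic:
    def test_antisymmetric_data_gives_zero_intercept(self):
        X = np.array([-2.0, -1.0, -1.0, 1.0, 1.0, 2.0])[:, None]
        y = np.array([0.0, 0.0, 1.0, 0.0, 1.0, 1.0])
        fit = fit_logistic(X, y)
        assert not fit.separated
        assert abs(fit.coef[0]) < 1e-6

    def test_matches_irls_oracle_on_hand_dataset(self):
        X = np.array([0.2, 1.1, 1.9, 3.0, 4.2, 5.1])[:, None]
        y = np.array([0.0, 1.0, 0.0, 1.0, 1.0, 1.0])
        fit = fit_logistic(X, y)
        oracle = _irls_oracle(X, y)
        np.testing.assert_allclose(fit.coef, oracle, atol=1e-6)

    def test_perfect_separation_is_flagged(self):
        X = np.array([-2.0, -1.0, 1.0, 2.0])[:, None]
        y = np.array([0.0, 0.0, 1.0, 1.0])
        fit = fit_logistic(X, y)
        assert fit.separated
        # limiting rule still classifies correctly at the 0.5 cutoff
        assert fit.predict_proba([[-3.0]])[0] < 0.5 < fit.predict_proba([[3.0]])[0]

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValidationError):
            fit_logistic(np.ones((6, 1)), np.array([0, 1, 0, 1, 0, 1.0]))

    def test_too_few_observations_rejected(self):
        with pytest.raises(SampleSizeError):
            fit_logistic(np.zeros((2, 1)), np.array([0.0, 1.0]))


class TestClassificationMetrics:
    def test_combined_rsfc_model_counts(self):
        # 19/24 relapsers, 14/21 non-relapsers correct
        m = classification_metrics(ConfusionTable(tp=19, fn=5, fp=7, tn=14))
        assert m == {"sensitivity": 79.2, "specificity": 66.7, "accuracy": 73.3}

    def test_years_smoking_model_accuracy(self):
        m = classification_metrics(ConfusionTable(tp=17, fn=7, fp=11, tn=10))
        assert m["accuracy"] == 60.0

    def test_all_correct_is_one_hundred(self):
        m = classification_metrics(ConfusionTable(tp=24, fn=0, fp=0, tn=21))
        assert m == {"sensitivity": 100.0, "specificity": 100.0, "accuracy": 100.0}

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            ConfusionTable(tp=-1, fn=0, fp=0, tn=1)


class TestChisqVsChance:
    @pytest.mark.parametrize("counts,expected", [
        ((19, 5, 7, 14), 9.64),
        ((17, 7, 5, 16), 9.91),
        ((17, 7, 11, 10), 1.62),
    ])
    def test_matches_hand_computation(self, counts, expected):
        tp, fn, fp, tn = counts
        chi2, df, p = chisq_vs_chance(ConfusionTable(tp, fn, fp, tn))
        assert df == 1
        assert round(chi2, 2) == expected

    def test_independent_margins_give_zero(self):
        # predicted split proportional to actual split -> independence
        chi2, _, p = chisq_vs_chance(ConfusionTable(tp=12, fn=12, fp=6, tn=6))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            chisq_vs_chance(ConfusionTable(tp=0, fn=0, fp=3, tn=4))

    def test_accuracy_identity(self):
        c = ConfusionTable(tp=19, fn=5, fp=7, tn=14)
        m = classification_metrics(c)
        assert round(m["accuracy"] * c.n / 100.0) == c.tp + c.tn


class TestReconstructConfusion:
    def test_margins_match_group_sizes(self):
        c = reconstruct_confusion(79.2, 66.7, 24, 21)
        assert (c.tp + c.fn, c.fp + c.tn) == (24, 21)
        assert (c.tp, c.tn) == (19, 14)


def _cluster(voxels, peak_stat=5.0, peak_mm=None):
    voxels = np.asarray(voxels)
    return Cluster(voxels=voxels, size=len(voxels), peak_stat=peak_stat,
                   peak_ijk=tuple(voxels[0]),
                   peak_mm=peak_mm or tuple(float(v) for v in voxels[0]))


class TestMatchCluster:
    REF = None

    def setup_method(self):
        self.ref = _cluster([[i, 0, 0] for i in range(10)])

    def test_identical_cluster_matches_with_full_overlap(self):
        fold = [_cluster([[i, 0, 0] for i in range(10)])]
        best, info = _match_cluster(fold, self.ref, k_min=5, grid=None)
        assert best is fold[0]
        assert info["overlap"] == 10 and not info["fallback"]

    def test_largest_overlap_wins(self):
        five = _cluster([[i, 0, 0] for i in range(5)] + [[i, 5, 5] for i in range(3)])
        three = _cluster([[i, 0, 0] for i in range(5, 8)] + [[i, 7, 7] for i in range(5)])
        best, info = _match_cluster([three, five], self.ref, k_min=1, grid=None)
        assert best is five and info["overlap"] == 5

    def test_small_clusters_excluded_by_kmin(self):
        small = _cluster([[0, 0, 0]])
        far = _cluster([[i, 9, 9] for i in range(8)], peak_mm=(9.0, 9.0, 9.0))
        best, info = _match_cluster([small, far], self.ref, k_min=5, grid=None)
        # the overlapping cluster is below k_min -> nearest-peak fallback
        assert info["fallback"]

    def test_nearest_peak_fallback(self):
        near = _cluster([[0, 2, 0]], peak_mm=(0.0, 2.0, 0.0))
        far = _cluster([[0, 9, 9]], peak_mm=(0.0, 9.0, 9.0))
        best, info = _match_cluster([far, near], self.ref, k_min=1, grid=None)
        assert best is near and info["fallback"] and info["overlap"] == 0

    def test_no_clusters_returns_none(self):
        best, info = _match_cluster([], self.ref, k_min=1, grid=None)
        assert best is None


class TestFoldIndependence:
    def test_left_out_subject_cannot_influence_fold(self, cohort45):
        """Scrambling the held-out map changes neither the fold cluster
        nor the training fit nor the prediction input's definition."""
        c = cohort45
        spec = PredictorSpec("one", circuits=(("L_CMA", 0),))
        refs = self._references(c)
        left_out = c["ids"][0]
        base = run_fold(c["zmaps"], c["labels"], c["ids"], spec, left_out,
                        c["settings"], c["k_min"], refs, c["mask"], c["grid"])

        scrambled = {k: v.copy() for k, v in c["zmaps"].items()}
        vol = scrambled["L_CMA"][0]
        rng = np.random.default_rng(0)
        scrambled["L_CMA"][0] = rng.permutation(vol.ravel()).reshape(vol.shape)
        pert = run_fold(scrambled, c["labels"], c["ids"], spec, left_out,
                        c["settings"], c["k_min"], refs, c["mask"], c["grid"])
        assert base.matched_clusters == pert.matched_clusters
        np.testing.assert_allclose(base.fit.coef, pert.fit.coef, rtol=1e-10)

    @staticmethod
    def _references(c):
        from amygconn.loocv import reference_clusters_for_seed
        refs = {}
        for seed in ("L_CMA",):
            for i, cl in enumerate(reference_clusters_for_seed(
                    c["zmaps"][seed], c["labels"], c["mask"], c["settings"],
                    c["k_min"], c["grid"])):
                refs[(seed, i)] = cl
        return refs

    def test_fold_count_equals_cohort_size(self, cohort45):
        c = cohort45
        clf = LeaveOneOutRelapseClassifier(circuits=(("L_CMA", 0),),
                                           k_min=c["k_min"], name="one")
        clf.fit(c["zmaps"], c["labels"], c["ids"], c["mask"], c["grid"])
        assert len(clf.report_.folds) + len(clf.report_.failed_folds) == 45

    def test_covariate_only_model_runs_through_same_machinery(self, cohort45):
        c = cohort45
        clf = LeaveOneOutRelapseClassifier(covariates=("years_education",),
                                           k_min=c["k_min"], name="edu")
        clf.fit(c["zmaps"], c["labels"], c["ids"], c["mask"], c["grid"],
                covariates=c["covariates"])
        r = clf.report_
        assert r.confusion.n == 45
        # education differs by ~1.5 years between groups: informative but
        # far from a perfect classifier
        assert 40.0 < r.accuracy < 90.0


class TestClusterMeanSeries:
    def test_mean_over_member_voxels(self, rng):
        zmaps = rng.standard_normal((3, 4, 4, 4))
        cl = _cluster([[0, 0, 0], [1, 1, 1]])
        expected = (zmaps[:, 0, 0, 0] + zmaps[:, 1, 1, 1]) / 2.0
        np.testing.assert_allclose(cluster_mean_series(zmaps, cl), expected)


class TestPredictorSpec:
    def test_empty_model_rejected(self):
        with pytest.raises(ValidationError):
            PredictorSpec("empty")
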