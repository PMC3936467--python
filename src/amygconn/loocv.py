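"""Leave-one-out cross-validated relapse classification from cluster means.

The classifier estimates how well cluster-mean connectivity (optionally
together with non-imaging covariates such as years of education or years
smoking) predicts relapse status, without letting the held-out subject
influence feature definition. For each fold the two-group contrast is
recomputed on the remaining n - 1 subjects, clusters are labelled at the
same voxel threshold and minimum extent, and for every circuit the fold
cluster with the largest voxel overlap with the full-sample reference
cluster is selected (reference clusters locate the effect; they are never
used as masks). Cluster-mean connectivity is then extracted for all n
subjects from the *fold* cluster, a logistic regression is fitted on the
n - 1 training subjects, and the left-out subject is classified at a 0.5
probability cutoff. Relapse is the positive class throughout.

Aggregated held-out predictions yield sensitivity, specificity and
accuracy, plus a Pearson chi-square (df = 1, no continuity correction) of
the 2x2 predicted-vs-actual table against chance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .errors import (DegenerateTableError, FoldError, SampleSizeError,
                     SeparationError, ValidationError)
from .inference import (ClusterInferenceSpec, group_contrast_map,
                        stat_threshold_from_p, threshold_stat_map)

logger = logging.getLogger(__name__)

POSITIVE_CLASS = "relapse"
NEGATIVE_CLASS = "nonrelapse"
#: |coefficient| beyond which a logistic fit is treated as separated
SEPARATION_COEF = 30.0


@dataclass(frozen=True)
class PredictorSpec:
    """Predictors for one model: imaging circuits and/or covariates.

    ``circuits`` is a tuple of (seed name, reference-cluster index), the
    index counting the full-sample significant clusters of that seed's
    contrast in size order. ``covariates`` are cohort-table column names.
    """

    name: str
    circuits: tuple = ()
    covariates: tuple = ()

    def __post_init__(self):
        if len(self.circuits) + len(self.covariates) < 1:
            raise ValidationError(f"model {self.name!r} has no predictors")


@dataclass
class ConfusionTable:
    """2x2 held-out confusion counts; relapse is the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValidationError("confusion counts must be >= 0")

    @property
    def n(self):
        return self.tp + self.fn + self.fp + self.tn

    def as_array(self):
        return np.array([[self.tp, self.fn], [self.fp, self.tn]])


@dataclass
class LogisticFit:
    coef: np.ndarray           # intercept first
    fitted_probs: np.ndarray
    converged: bool
    separated: bool

    def predict_proba(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        eta = self.coef[0] + X @ self.coef[1:]
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))


@dataclass
class FoldResult:
    left_out: str
    matched_clusters: dict      # circuit key -> {"size", "overlap", "fallback"}
    fit: LogisticFit
    probability: float
    predicted: str
    actual: str


@dataclass
class LoocvReport:
    model: str
    confusion: ConfusionTable
    sensitivity: float
    specificity: float
    accuracy: float
    chi2: float
    chi2_df: int
    p: float
    folds: list
    failed_folds: list


# ---------------------------------------------------------------------------
# logistic regression


def fit_logistic(X, y):
    """Maximum-likelihood logistic fit (intercept included).

    ``y`` is binary (1 = positive class). Newton iterations with tolerance
    1e-8 capped at 100; quasi-perfect separation is detected (diverging
    coefficients or a statsmodels separation signal) and flagged rather
    than raised, so callers can apply the limiting classification rule.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k + 1:
        raise SampleSizeError(f"need n > k+1 for logistic fit (n={n}, k={k})")
    if (np.ptp(X, axis=0) == 0).any():
        raise ValidationError("constant predictor column in logistic design")
    design = sm.add_constant(X, has_constant="add")
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        warnings.simplefilter("always", category=PerfectSeparationWarning)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                res = sm.Logit(y, design).fit(method="newton", maxiter=100,
                                              tol=1e-8, disp=0)
            except (PerfectSeparationError, np.linalg.LinAlgError):
                # (quasi-)separation: Newton diverges / singular Hessian;
                # refit with a gradient method to get the limiting direction
                separated = True
                res = sm.Logit(y, design).fit(method="bfgs", maxiter=200, disp=0)
            for w in caught:
                if issubclass(w.category, PerfectSeparationWarning):
                    separated = True
    coef = np.asarray(res.params, dtype=float)
    if np.abs(coef).max() > SEPARATION_COEF or not np.all(np.isfinite(coef)):
        separated = True
    if not separated and not res.mle_retvals.get("converged", True):
        raise SeparationError("logistic fit did not converge (no separation detected)")
    coef = np.where(np.isfinite(coef), coef, np.sign(coef) * 1e3)
    probs = 1.0 / (1.0 + np.exp(-np.clip(design @ coef, -500, 500)))
    return LogisticFit(coef=coef, fitted_probs=probs,
                       converged=bool(res.mle_retvals.get("converged", True)),
                       separated=separated)


# ---------------------------------------------------------------------------
# metrics


def classification_metrics(confusion):
    """Sensitivity, specificity and accuracy in percent (1 d.p.)."""
    c = confusion
    if c.n == 0:
        raise ValidationError("empty confusion table")
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ValidationError("need at least one subject in each class")
    return {
        "sensitivity": round(100.0 * c.tp / (c.tp + c.fn), 1),
        "specificity": round(100.0 * c.tn / (c.tn + c.fp), 1),
        "accuracy": round(100.0 * (c.tp + c.tn) / c.n, 1),
    }


def chisq_vs_chance(confusion):
    """Pearson chi-square (df = 1, no continuity correction) of the
    predicted-vs-actual 2x2 table; returns (chi2, df, p)."""
    c = confusion
    table = c.as_array()
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateTableError(f"zero margin in table {table.tolist()}")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def reconstruct_confusion(sensitivity_pct, specificity_pct, n_pos, n_neg):
    """Confusion counts from printed sensitivity/specificity percentages."""
    tp = int(round(sensitivity_pct / 100.0 * n_pos))
    tn = int(round(specificity_pct / 100.0 * n_neg))
    return ConfusionTable(tp=tp, fn=n_pos - tp, fp=n_neg - tn, tn=tn)


# ---------------------------------------------------------------------------
# fold machinery


def cluster_mean_series(zmaps, cluster):
    """Mean Fisher z over a cluster's voxels for every subject's map."""
    idx = tuple(cluster.voxels.T)
    return zmaps[(slice(None),) + idx].mean(axis=1)


def _match_cluster(fold_clusters, reference, k_min, grid):
    """Largest-overlap matching with the documented tie-break and fallback.

    Primary rule: among fold clusters of at least ``k_min`` voxels, pick
    the one sharing the most voxels with the reference (ties: larger
    cluster, then higher |peak|). If no candidate overlaps, fall back to
    the suprathreshold cluster (any size) whose peak is nearest in mm to
    the reference peak. Returns (cluster, info) or (None, info).
    """
    big = [cl for cl in fold_clusters if cl.size >= k_min]
    best, best_key = None, None
    for cl in big:
        ov = cl.overlap(reference)
        if ov == 0:
            continue
        key = (ov, cl.size, abs(cl.peak_stat) if np.isfinite(cl.peak_stat) else 0.0)
        if best_key is None or key > best_key:
            best, best_key = cl, key
    if best is not None:
        return best, {"size": best.size, "overlap": best_key[0], "fallback": False}
    if fold_clusters:
        ref_mm = np.asarray(reference.peak_mm if reference.peak_mm is not None
                            else grid.voxel_to_report_mm(reference.peak_ijk))
        def dist(cl):
            mm = np.asarray(cl.peak_mm if cl.peak_mm is not None
                            else grid.voxel_to_report_mm(cl.peak_ijk))
            return float(np.linalg.norm(mm - ref_mm))
        best = min(fold_clusters, key=dist)
        return best, {"size": best.size, "overlap": 0, "fallback": True}
    return None, {"size": 0, "overlap": 0, "fallback": True}


def _contrast_clusters(zmaps, labels, mask, settings, grid):
    """Two-group contrast plus bi-sided suprathreshold clustering."""
    stat_map = group_contrast_map(zmaps, labels)
    stat_map.mask &= mask
    threshold = stat_threshold_from_p(settings.voxel_p, stat_map.df, "F")
    clusters = threshold_stat_map(stat_map, threshold,
                                  neighborhood=settings.neighborhood, grid=grid)
    return stat_map, clusters


def reference_clusters_for_seed(zmaps, labels, mask, settings, k_min, grid,
                                require_significant=True):
    """Full-sample significant clusters for one seed, size-ordered.

    With ``require_significant=False`` and no cluster reaching ``k_min``,
    the largest suprathreshold cluster is returned instead (useful for
    null/permutation experiments where nothing survives correction).
    """
    _, clusters = _contrast_clusters(zmaps, labels, mask, settings, grid)
    significant = [cl for cl in clusters if cl.size >= k_min]
    if significant:
        return significant
    if require_significant or not clusters:
        return []
    return [clusters[0]]


def run_fold(zmaps_by_seed, labels, subject_ids, predictor_spec, left_out,
             settings, k_min, reference_clusters, mask, grid, covariates=None):
    """One leave-one-out fold; see the module docstring for the procedure."""
    subject_ids = list(subject_ids)
    if left_out not in subject_ids:
        raise FoldError(left_out, "not in cohort")
    pos = subject_ids.index(left_out)
    train = np.ones(len(subject_ids), dtype=bool)
    train[pos] = False
    labels = np.asarray(labels)
    for lv in np.unique(labels):
        if (labels[train] == lv).sum() < 2:
            raise FoldError(left_out, f"group {lv!r} too small after leaving one out")

    features = []
    matched = {}
    for seed_name, ref_index in predictor_spec.circuits:
        reference = reference_clusters[(seed_name, ref_index)]
        zmaps = zmaps_by_seed[seed_name]
        _, fold_clusters = _contrast_clusters(zmaps[train], labels[train],
                                              mask, settings, grid)
        cluster, info = _match_cluster(fold_clusters, reference, k_min, grid)
        matched[(seed_name, ref_index)] = info
        if cluster is None:
            raise FoldError(left_out, f"no suprathreshold cluster for seed {seed_name}")
        if info["fallback"]:
            logger.warning("fold %s seed %s: zero overlap, nearest-peak fallback "
                           "(cluster size %d)", left_out, seed_name, info["size"])
        features.append(cluster_mean_series(zmaps, cluster))
    if covariates is not None:
        for name in predictor_spec.covariates:
            features.append(np.asarray(covariates[name], dtype=float))
    X = np.column_stack(features)
    y = (labels == POSITIVE_CLASS).astype(float)

    fit = fit_logistic(X[train], y[train])
    prob = float(fit.predict_proba(X[pos])[0])
    predicted = POSITIVE_CLASS if prob >= 0.5 else NEGATIVE_CLASS
    return FoldResult(left_out=left_out, matched_clusters=matched, fit=fit,
                      probability=prob, predicted=predicted,
                      actual=str(labels[pos]))


def run_loocv(zmaps_by_seed, labels, subject_ids, predictor_spec, settings,
              k_min, reference_clusters, mask, grid, covariates=None):
    """Full leave-one-out loop -> LoocvReport (one fold per subject)."""
    folds, failed = [], []
    for left_out in subject_ids:
        try:
            folds.append(run_fold(zmaps_by_seed, labels, subject_ids,
                                  predictor_spec, left_out, settings, k_min,
                                  reference_clusters, mask, grid,
                                  covariates=covariates))
        except FoldError as exc:
            logger.warning("excluding failed fold: %s", exc)
            failed.append((left_out, str(exc)))
    if not folds:
        raise ValidationError(f"all folds failed for model {predictor_spec.name!r}")
    tp = sum(f.predicted == POSITIVE_CLASS and f.actual == POSITIVE_CLASS for f in folds)
    fn = sum(f.predicted == NEGATIVE_CLASS and f.actual == POSITIVE_CLASS for f in folds)
    fp = sum(f.predicted == POSITIVE_CLASS and f.actual == NEGATIVE_CLASS for f in folds)
    tn = sum(f.predicted == NEGATIVE_CLASS and f.actual == NEGATIVE_CLASS for f in folds)
    confusion = ConfusionTable(tp=tp, fn=fn, fp=fp, tn=tn)
    metrics = classification_metrics(confusion)
    try:
        chi2, df, p = chisq_vs_chance(confusion)
    except DegenerateTableError:
        chi2, df, p = float("nan"), 1, float("nan")
    return LoocvReport(model=predictor_spec.name, confusion=confusion,
                       chi2=chi2, chi2_df=df, p=p, folds=folds,
                       failed_folds=failed, **metrics)


def report_table(reports):
    """Summary table mirroring the per-model report layout."""
    return pd.DataFrame([
        {"model": r.model, "sensitivity": r.sensitivity,
         "specificity": r.specificity, "accuracy": r.accuracy,
         "chi2": round(r.chi2, 3), "p": round(r.p, 3),
         "n_folds": len(r.folds), "n_failed": len(r.failed_folds)}
        for r in reports
    ])


# ---------------------------------------------------------------------------
# estimator


class LeaveOneOutRelapseClassifier:
    """Estimator wrapping the full LOOCV procedure for one model.

    Parameters mirror :class:`PredictorSpec` plus the cluster-inference
    settings. ``fit`` computes the full-sample reference clusters, runs
    all leave-one-out folds, and exposes the aggregate report as fitted
    attributes (``report_``, ``confusion_``, ``reference_clusters_``).
    ``k_min`` must be supplied (calibrated once per mask/smoothness with
    :func:`amygconn.inference.mc_cluster_size_threshold`).
    """

    def __init__(self, circuits=(), covariates=(), voxel_p=0.005,
                 cluster_alpha=0.05, neighborhood=26, k_min=1,
                 require_significant=True, name="model"):
        self.circuits = circuits
        self.covariates = covariates
        self.voxel_p = voxel_p
        self.cluster_alpha = cluster_alpha
        self.neighborhood = neighborhood
        self.k_min = k_min
        self.require_significant = require_significant
        self.name = name

    def get_params(self, deep=True):
        return {"circuits": self.circuits, "covariates": self.covariates,
                "voxel_p": self.voxel_p, "cluster_alpha": self.cluster_alpha,
                "neighborhood": self.neighborhood, "k_min": self.k_min,
                "require_significant": self.require_significant,
                "name": self.name}

    def set_params(self, **params):
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def _settings(self):
        return ClusterInferenceSpec(voxel_p=self.voxel_p,
                                    cluster_alpha=self.cluster_alpha,
                                    neighborhood=self.neighborhood)

    def fit(self, zmaps_by_seed, y, subject_ids, mask, grid, covariates=None,
            reference_clusters=None):
        """Run the LOOCV procedure.

        ``zmaps_by_seed`` maps seed names to (n_subjects, x, y, z) arrays;
        ``y`` holds 'relapse'/'nonrelapse' labels aligned with
        ``subject_ids``; ``covariates`` is a DataFrame (or mapping) with
        the configured covariate columns. Precomputed
        ``reference_clusters`` (mapping (seed, index) -> Cluster) may be
        injected, e.g. for permutation experiments.
        """
        settings = self._settings()
        spec = PredictorSpec(name=self.name, circuits=tuple(self.circuits),
                             covariates=tuple(self.covariates))
        y = np.asarray(y)
        if reference_clusters is None:
            reference_clusters = {}
            for seed_name in {s for s, _ in spec.circuits}:
                refs = reference_clusters_for_seed(
                    zmaps_by_seed[seed_name], y, mask, settings, self.k_min,
                    grid, require_significant=self.require_significant)
                for i, cl in enumerate(refs):
                    reference_clusters[(seed_name, i)] = cl
        for key in spec.circuits:
            if tuple(key) not in reference_clusters:
                raise ValidationError(
                    f"no reference cluster {key}; the full-sample contrast "
                    f"yielded none at k_min={self.k_min}")
        self.reference_clusters_ = reference_clusters
        self.report_ = run_loocv(zmaps_by_seed, y, list(subject_ids), spec,
                                 settings, self.k_min, reference_clusters,
                                 mask, grid, covariates=covariates)
        self.confusion_ = self.report_.confusion
        return self
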