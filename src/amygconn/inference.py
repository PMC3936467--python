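"""Voxelwise group statistics with cluster-extent multiple-comparison control.

Group maps are massively univariate: at every voxel an ordinary
least-squares general linear model ``z ~ intercept + group (+ covariates)``
is fitted across subjects' Fisher-z maps, yielding an F statistic for the
group term (equal to the squared two-sample pooled-variance t when there
are no covariates). One-sample maps use the plain t = mean / (sd / sqrt(n)).

Multiple comparisons across voxels are controlled with cluster-extent
thresholding: voxels pass an uncorrected two-tailed threshold (default
p = 0.005), surviving voxels are grouped into connected components
(26-neighbourhood by default; positive and negative effects clustered
separately), and only clusters at least ``k_min`` voxels large are
reported. ``k_min`` is calibrated by Monte-Carlo simulation of smooth
Gaussian null fields on the analysis mask so that the family-wise
probability of any suprathreshold cluster reaching ``k_min`` is at most
``cluster_alpha`` (default 0.05) — the AlphaSim-style procedure.

Field smoothness for the simulation is either supplied (known for
synthetic data) or estimated from residual maps with the classic
variance-of-neighbour-differences estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import (DesignError, EstimationError, ResolutionError,
                     SampleSizeError, ValidationError)
from .preprocess import fwhm_to_sigma_voxels

logger = logging.getLogger(__name__)

#: connectivity structures by neighbourhood rule (number of neighbours)
NEIGHBORHOODS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class StatMap:
    """A voxelwise statistic map with its degrees of freedom.

    ``df`` is a single number for t maps and a (numerator, denominator)
    pair for F maps. ``sign`` (optional, F maps) records the direction of
    the group-mean difference at each voxel. ``mask`` is the analysis mask
    after removal of degenerate voxels.
    """

    stat_type: str
    values: np.ndarray
    df: object
    mask: np.ndarray
    contrast: str = ""
    sign: np.ndarray = None


@dataclass(frozen=True)
class ClusterInferenceSpec:
    """Thresholds for cluster-extent corrected inference."""

    voxel_p: float = 0.005
    cluster_alpha: float = 0.05
    n_iterations: int = 1000
    neighborhood: int = 26
    fwhm_mm: float = 6.0

    def __post_init__(self):
        for name in ("voxel_p", "cluster_alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValidationError(f"{name} must be in (0, 1), got {v}")
        if self.n_iterations < 100:
            raise ValidationError("n_iterations must be >= 100")
        if self.neighborhood not in NEIGHBORHOODS:
            raise ValidationError(
                f"neighborhood must be one of {sorted(NEIGHBORHOODS)}, got {self.neighborhood}"
            )


@dataclass
class Cluster:
    """A connected suprathreshold component."""

    voxels: np.ndarray       # (k, 3) integer indices
    size: int
    peak_stat: float
    peak_ijk: tuple
    peak_mm: tuple = None

    def overlap(self, other):
        """Number of voxels shared with another cluster."""
        a = {tuple(v) for v in self.voxels}
        b = {tuple(v) for v in other.voxels}
        return len(a & b)

    def member_mask(self, dims):
        m = np.zeros(dims, dtype=bool)
        m[tuple(self.voxels.T)] = True
        return m


# ---------------------------------------------------------------------------
# voxelwise statistics


def one_sample_map(maps, mask, contrast="one-sample"):
    """Voxelwise one-sample t map across subjects.

    ``maps``: (n_subjects, x, y, z). Zero-variance voxels are removed from
    the returned mask rather than producing infinities.
    """
    maps = np.asarray(maps, dtype=float)
    n = maps.shape[0]
    if n < 2:
        raise SampleSizeError(f"one-sample t needs n >= 2, got {n}")
    mask = np.asarray(mask, dtype=bool)
    data = maps[:, mask]
    sd = data.std(axis=0, ddof=1)
    good = sd > 0
    t = np.full(data.shape[1], np.nan)
    t[good] = data.mean(axis=0)[good] / (sd[good] / np.sqrt(n))
    values = np.full(mask.shape, np.nan)
    values[mask] = t
    out_mask = mask.copy()
    out_mask[mask] = good
    return StatMap("t", values, n - 1, out_mask, contrast=contrast)


def group_contrast_map(maps, labels, covariates=None, contrast="group"):
    """Voxelwise OLS GLM ``z ~ 1 + group (+ covariates)``; F for group.

    ``labels`` must contain exactly two levels, each with n >= 2. With no
    covariates the F map equals the squared pooled-variance two-sample t
    map. The ``sign`` field holds the sign of the fitted group coefficient
    (first level minus second level ordering of ``np.unique``).
    """
    maps = np.asarray(maps, dtype=float)
    labels = np.asarray(labels)
    levels = np.unique(labels)
    if len(levels) != 2:
        raise DesignError(f"need exactly 2 groups, got {list(levels)}")
    for lv in levels:
        if (labels == lv).sum() < 2:
            raise SampleSizeError(f"group {lv!r} has fewer than 2 subjects")
    n = maps.shape[0]
    g = (labels == levels[1]).astype(float)  # second level coded 1
    cols = [np.ones(n), g]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        for j in range(cov.shape[1]):
            if np.ptp(cov[:, j]) == 0:
                raise DesignError(f"covariate column {j} is constant")
            cols.append(cov[:, j])
    X = np.column_stack(cols)
    k = X.shape[1]
    if np.linalg.matrix_rank(X) < k:
        raise DesignError("design is confounded (group collinear with a covariate)")
    if n <= k:
        raise SampleSizeError(f"need n > {k} subjects for {k} design columns")

    mask = np.isfinite(maps).all(axis=0)
    Y = maps[:, mask]                               # n x V
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)                      # k x V
    resid = Y - X @ beta
    dfd = n - k
    sigma2 = (resid * resid).sum(axis=0) / dfd
    var_g = xtx_inv[1, 1] * sigma2
    good = var_g > 0
    F = np.full(Y.shape[1], np.nan)
    F[good] = beta[1, good] ** 2 / var_g[good]
    values = np.full(mask.shape, np.nan)
    values[mask] = F
    sign = np.zeros(mask.shape)
    sign[mask] = np.sign(beta[1])
    out_mask = mask.copy()
    out_mask[mask] = good
    return StatMap("F", values, (1, dfd), out_mask, contrast=contrast, sign=sign)


def stat_threshold_from_p(p, df, stat_type="t"):
    """Critical value at two-tailed probability ``p`` (t) or tail ``p`` (F)."""
    if not (0.0 < p < 1.0):
        raise ValidationError(f"p must be in (0, 1), got {p}")
    if stat_type == "t":
        if np.isinf(df):
            return float(stats.norm.isf(p / 2.0))
        return float(stats.t.isf(p / 2.0, df))
    if stat_type == "F":
        dfn, dfd = df
        return float(stats.f.isf(p, dfn, dfd))
    raise ValidationError(f"unknown stat type {stat_type!r}")


# ---------------------------------------------------------------------------
# clusters


def label_clusters(suprathreshold, stat_values=None, neighborhood=26, grid=None,
                   convention="lpi"):
    """Connected components of a binary mask, as a list of Clusters.

    Components are maximal under the chosen neighbourhood rule (6, 18 or
    26). The peak is the member voxel with the largest |statistic| (mask
    order when no statistics are given). Clusters are sorted by size
    descending, ties broken by peak statistic descending.
    """
    suprathreshold = np.asarray(suprathreshold, dtype=bool)
    labeled, n = ndimage.label(suprathreshold, structure=NEIGHBORHOODS[neighborhood])
    clusters = []
    if n:
        all_idx = np.argwhere(labeled > 0)
        lab = labeled[tuple(all_idx.T)]
        order = np.argsort(lab, kind="stable")
        all_idx, lab = all_idx[order], lab[order]
        starts = np.searchsorted(lab, np.arange(1, n + 2))
        for c in range(n):
            voxels = all_idx[starts[c]:starts[c + 1]]
            if stat_values is not None:
                vals = stat_values[tuple(voxels.T)]
                peak_pos = int(np.nanargmax(np.abs(vals)))
                peak_stat = float(vals[peak_pos])
            else:
                peak_pos, peak_stat = 0, float("nan")
            peak_ijk = tuple(int(v) for v in voxels[peak_pos])
            peak_mm = (tuple(float(x) for x in grid.voxel_to_report_mm(peak_ijk, convention))
                       if grid is not None else None)
            clusters.append(Cluster(voxels=voxels, size=len(voxels),
                                    peak_stat=peak_stat, peak_ijk=peak_ijk,
                                    peak_mm=peak_mm))
    clusters.sort(key=lambda cl: (-cl.size,
                                  -(cl.peak_stat if np.isfinite(cl.peak_stat) else -np.inf)))
    return clusters


def threshold_stat_map(stat_map, threshold, neighborhood=26, grid=None,
                       convention="lpi"):
    """Suprathreshold clusters of a StatMap, positive and negative sides
    clustered separately (bi-sided) for signed statistics."""
    vals = np.where(stat_map.mask, stat_map.values, np.nan)
    if stat_map.stat_type == "t":
        pos = np.where(np.isfinite(vals), vals, -np.inf) >= threshold
        neg = np.where(np.isfinite(vals), vals, np.inf) <= -threshold
        sides = [pos, neg]
    else:
        supra = np.where(np.isfinite(vals), vals, -np.inf) >= threshold
        if stat_map.sign is not None:
            sides = [supra & (stat_map.sign > 0), supra & (stat_map.sign < 0)]
        else:
            sides = [supra]
    clusters = []
    for side in sides:
        clusters.extend(label_clusters(side, stat_values=vals,
                                       neighborhood=neighborhood, grid=grid,
                                       convention=convention))
    clusters.sort(key=lambda cl: (-cl.size,
                                  -(abs(cl.peak_stat) if np.isfinite(cl.peak_stat) else -np.inf)))
    return clusters


# ---------------------------------------------------------------------------
# Monte-Carlo cluster-size calibration


def _null_field_max_cluster(mask, sigma_vox, z_thresh, structure, rng, norm):
    noise = rng.standard_normal(mask.shape)
    if sigma_vox is not None:
        noise = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="constant", cval=0.0)
        noise /= norm
    vals = noise[mask]
    vals = (vals - vals.mean()) / vals.std()
    z = np.zeros(mask.shape)
    z[mask] = vals
    best = 0
    for supra in ((z >= z_thresh) & mask, (z <= -z_thresh) & mask):
        if supra.any():
            labeled, n = ndimage.label(supra, structure=structure)
            if n:
                sizes = np.bincount(labeled.ravel())[1:]
                best = max(best, int(sizes.max()))
    return best


def simulate_max_cluster_sizes(mask, spec, rng, voxel_size=(3.25, 3.25, 3.0),
                               n_iterations=None):
    """Max suprathreshold cluster size per null iteration (array of ints).

    Each iteration draws a white Gaussian field on the mask's bounding
    grid, smooths it to the specified FWHM, standardises to zero mean and
    unit variance within the mask, thresholds two-tailed at ``voxel_p``
    (positive and negative sides clustered separately, mirroring the
    analysis), and records the largest cluster.
    """
    mask = np.asarray(mask, dtype=bool)
    structure = NEIGHBORHOODS[spec.neighborhood]
    z_thresh = stats.norm.isf(spec.voxel_p / 2.0)
    sigma_vox = (fwhm_to_sigma_voxels(spec.fwhm_mm, voxel_size)
                 if spec.fwhm_mm > 0 else None)
    norm = 1.0
    if sigma_vox is not None:
        from .synth import _smoothing_norm
        norm = _smoothing_norm(sigma_vox)
    n_iter = spec.n_iterations if n_iterations is None else n_iterations
    return np.array([
        _null_field_max_cluster(mask, sigma_vox, z_thresh, structure, rng, norm)
        for _ in range(n_iter)
    ])


def kmin_from_sizes(sizes, alpha):
    """Smallest k whose exceedance fraction among null maxima is <= alpha."""
    sizes = np.asarray(sizes)
    kmax = int(sizes.max()) if sizes.size else 0
    for k in range(1, kmax + 2):
        if float((sizes >= k).mean()) <= alpha:
            return k
    return kmax + 1


def mc_cluster_size_threshold(mask, spec, rng, voxel_size=(3.25, 3.25, 3.0),
                              return_sizes=False):
    """Minimum cluster extent ``k_min`` at the configured family-wise alpha.

    ``k_min`` is the smallest k such that the fraction of null iterations
    whose maximum cluster size reaches k is at most ``cluster_alpha``.
    """
    if spec.cluster_alpha < 1.0 / spec.n_iterations:
        raise ResolutionError(
            f"alpha {spec.cluster_alpha} finer than 1/{spec.n_iterations} resolution"
        )
    sizes = simulate_max_cluster_sizes(mask, spec, rng, voxel_size=voxel_size)
    k_min = kmin_from_sizes(sizes, spec.cluster_alpha)
    logger.info("Monte-Carlo k_min = %d (alpha=%g, %d iterations)",
                k_min, spec.cluster_alpha, spec.n_iterations)
    if return_sizes:
        return k_min, sizes
    return k_min


# ---------------------------------------------------------------------------
# smoothness


def estimate_smoothness(residual_maps, mask, voxel_size):
    """Per-axis FWHM (mm) from the variance of neighbour differences.

    For a Gaussian-autocorrelated field, the lag-1 difference variance
    varD relates to the kernel width via
    FWHM = voxel * sqrt(-2 ln 2 / ln(1 - varD / (2 var))); the estimate is
    averaged over maps and clamped at 0 when varD >= 2 var (rougher than
    white noise along that axis).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 27:
        raise EstimationError(f"mask too small to estimate smoothness ({int(mask.sum())} voxels)")
    maps = np.asarray(residual_maps, dtype=float)
    if maps.ndim == 3:
        maps = maps[None]
    voxel_size = np.asarray(voxel_size, dtype=float)
    fwhm = np.zeros((maps.shape[0], 3))
    for m_i, vol in enumerate(maps):
        var = vol[mask].var()
        for ax in range(3):
            sl_a = [slice(None)] * 3
            sl_b = [slice(None)] * 3
            sl_a[ax] = slice(1, None)
            sl_b[ax] = slice(None, -1)
            pair = mask[tuple(sl_a)] & mask[tuple(sl_b)]
            diff = (vol[tuple(sl_a)] - vol[tuple(sl_b)])[pair]
            if diff.size < 2 or var == 0:
                fwhm[m_i, ax] = 0.0
                continue
            ratio = diff.var() / (2.0 * var)
            if ratio >= 1.0:
                fwhm[m_i, ax] = 0.0
            else:
                fwhm[m_i, ax] = voxel_size[ax] * np.sqrt(-2.0 * np.log(2.0) / np.log(1.0 - ratio))
    return fwhm.mean(axis=0)


# ---------------------------------------------------------------------------
# reporting and post hocs


def cluster_report(stat_map, clusters, k_min, contrast=None):
    """Table of clusters at least ``k_min`` voxels large.

    Columns: contrast, size_voxels, peak_stat, x_mm, y_mm, z_mm (reporting
    coordinates are positive along Left/Posterior/Inferior by default).
    """
    rows = []
    for cl in clusters:
        if cl.size < k_min:
            continue
        mm = cl.peak_mm if cl.peak_mm is not None else (np.nan,) * 3
        rows.append({
            "contrast": contrast if contrast is not None else stat_map.contrast,
            "size_voxels": cl.size,
            "peak_stat": round(float(cl.peak_stat), 2),
            "x_mm": round(float(mm[0]), 2),
            "y_mm": round(float(mm[1]), 2),
            "z_mm": round(float(mm[2]), 2),
        })
    return pd.DataFrame(rows, columns=["contrast", "size_voxels", "peak_stat",
                                       "x_mm", "y_mm", "z_mm"])


def covariate_association(cluster_means, covariate, control=None):
    """Association between cluster-mean connectivity and a covariate.

    Continuous covariates: Pearson r with df = n - 2, or the partial
    correlation (df = n - 3) via residualisation when a single control
    covariate is given. Binary covariates: two-sample t test. Returns
    ``(statistic, df, p)`` where statistic is r (continuous) or t (binary).
    """
    y = np.asarray(cluster_means, dtype=float)
    x = np.asarray(covariate, dtype=float)
    n = len(y)
    if n < 4:
        raise SampleSizeError(f"need n >= 4, got {n}")
    if np.ptp(x) == 0:
        raise ValidationError("covariate has zero variance")
    if len(np.unique(x)) == 2:
        g0, g1 = np.unique(x)
        t, p = stats.ttest_ind(y[x == g1], y[x == g0])
        return float(t), n - 2, float(p)
    if control is not None:
        c = np.asarray(control, dtype=float)
        if np.ptp(c) == 0:
            raise ValidationError("control covariate has zero variance")
        X = np.column_stack([np.ones(n), c])
        q, _ = np.linalg.qr(X)
        x_scale, y_scale = np.linalg.norm(x), np.linalg.norm(y)
        y = y - q @ (q.T @ y)
        x = x - q @ (q.T @ x)
        df = n - 3
        if (np.linalg.norm(x) < 1e-10 * max(x_scale, 1.0)
                or np.linalg.norm(y) < 1e-10 * max(y_scale, 1.0)):
            raise ValidationError("variable fully explained by the control covariate")
        r = float(x @ y / (np.linalg.norm(x) * np.linalg.norm(y)))
    else:
        df = n - 2
        r = float(stats.pearsonr(x, y).statistic)
    r_c = min(max(r, -1.0), 1.0)
    if abs(r_c) == 1.0:
        p = 0.0
    else:
        t = r_c * np.sqrt(df / (1.0 - r_c ** 2))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return r, df, p


def bonferroni_adjust(alpha_family, m):
    """Per-test threshold alpha/m; display value rounded to 3 decimals."""
    if m < 1:
        raise ValidationError(f"number of contrasts must be >= 1, got {m}")
    value = alpha_family / m
    return value, round(value, 3)
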