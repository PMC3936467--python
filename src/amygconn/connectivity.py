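"""Seed masks and per-subject whole-brain Fisher-z connectivity maps.

Seeds are amygdala subdivisions: left/right basolateral (BLA) masks come
from one probabilistic map each; left/right corticomedial (CMA) masks are
the union of centromedial and superficial component masks. A component
mask keeps voxels whose atlas probability is at least the threshold
(default 0.5, inclusive) AND that fall inside the subject's amygdala
segmentation.

Connectivity is the nuisance-partialled Pearson correlation between the
seed's mean time course and every brain voxel: both sides are residualised
against an intercept plus eight nuisance regressors (six motion parameters
and the mean white-matter and CSF signals) and then correlated. Partial
correlation rather than a raw regression slope realises the "cross
correlation map" of seed-based resting-state analysis in a scale-free way.
Global-signal regression is deliberately not performed (it can introduce
spurious negative correlations). Maps are variance-stabilised with
Fisher's z = atanh(r); |r| is clipped at 1 - 1e-7 (z ~ 8.4) so
self-correlated voxels stay finite.

Pipeline order: seed time courses are extracted from temporally filtered
but spatially *unsmoothed* data; the voxelwise maps use the smoothed data.
Nuisance regressors receive the same detrend + bandpass as the data so
both occupy the same frequency band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DesignError, EmptySeedError, ValidationError
from .preprocess import BOLDPreprocessor

logger = logging.getLogger(__name__)

SEED_NAMES = ("L_BLA", "R_BLA", "L_CMA", "R_CMA")
#: |r| clip so Fisher z stays finite on (near-)perfect correlations
R_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class SeedSpec:
    """One seed: its probabilistic component maps and threshold.

    BLA seeds have one component; CMA seeds have exactly two
    (centromedial + superficial), combined by union after thresholding.
    """

    name: str
    components: tuple
    threshold: float = 0.5

    def __post_init__(self):
        if not (0.0 < self.threshold <= 1.0):
            raise ValidationError(f"threshold must be in (0, 1], got {self.threshold}")
        n = len(self.components)
        if self.name.endswith("CMA") and n != 2:
            raise ValidationError(f"CMA seed needs exactly 2 components, got {n}")
        if self.name.endswith("BLA") and n != 1:
            raise ValidationError(f"BLA seed needs exactly 1 component, got {n}")


def default_seed_specs():
    """The four standard seeds in terms of component-map names."""
    return [
        SeedSpec("L_BLA", ("L_BLA",)),
        SeedSpec("R_BLA", ("R_BLA",)),
        SeedSpec("L_CMA", ("L_CM", "L_SF")),
        SeedSpec("R_CMA", ("R_CM", "R_SF")),
    ]


def build_seed_mask(prob_map, threshold, segmentation_mask):
    """Threshold a probabilistic map and intersect with the segmentation."""
    prob_map = np.asarray(prob_map, dtype=float)
    if prob_map.min() < 0 or prob_map.max() > 1:
        raise ValidationError("probabilistic map values must lie in [0, 1]")
    segmentation_mask = np.asarray(segmentation_mask, dtype=bool)
    if prob_map.shape != segmentation_mask.shape:
        raise ValidationError("probabilistic map and segmentation shapes differ")
    mask = (prob_map >= threshold) & segmentation_mask
    if not mask.any():
        raise EmptySeedError(
            f"seed mask empty at threshold {threshold} within segmentation"
        )
    return mask


def combine_cma(centromedial_mask, superficial_mask):
    """Union of the centromedial and superficial component masks."""
    cm = np.asarray(centromedial_mask, dtype=bool)
    sf = np.asarray(superficial_mask, dtype=bool)
    if cm.shape != sf.shape:
        raise ValidationError("component mask shapes differ")
    out = cm | sf
    if not out.any():
        raise EmptySeedError("both CMA components are empty")
    return out


def resolve_seed_mask(spec, prob_maps, segmentation_mask):
    """Build the binary mask for one SeedSpec from named component maps."""
    parts = []
    for comp in spec.components:
        if comp not in prob_maps:
            raise ValidationError(f"missing probabilistic map {comp!r} for seed {spec.name}")
        try:
            parts.append(build_seed_mask(prob_maps[comp], spec.threshold, segmentation_mask))
        except EmptySeedError:
            parts.append(np.zeros_like(segmentation_mask, dtype=bool))
    if len(parts) == 1:
        if not parts[0].any():
            raise EmptySeedError(f"seed {spec.name} is empty")
        return parts[0]
    return combine_cma(*parts)


def extract_seed_timecourse(series, seed_mask):
    """Mean time course over the seed voxels (series indexed x, y, z, t)."""
    seed_mask = np.asarray(seed_mask, dtype=bool)
    if not seed_mask.any():
        raise EmptySeedError("cannot extract a time course from an empty seed")
    if series.shape[:3] != seed_mask.shape:
        raise ValidationError("series and seed mask shapes differ")
    return series[seed_mask].mean(axis=0)


def build_nuisance_design(motion, wm_ts, csf_ts):
    """T x 8 nuisance table: 6 motion parameters + mean WM + mean CSF."""
    motion = np.asarray(motion, dtype=float)
    cols = np.column_stack([motion, wm_ts, csf_ts])
    if cols.shape[1] != 8:
        raise DesignError(f"nuisance design must have 8 columns, got {cols.shape[1]}")
    if (np.ptp(cols, axis=0) == 0).any():
        raise DesignError("nuisance design contains a constant column")
    return cols


def connectivity_map(seed_ts, series, nuisance, brain_mask):
    """Nuisance-partialled correlation of the seed with every brain voxel.

    Returns ``(r_map, df)``: a 3D map that is NaN outside the brain mask
    (and at zero-variance voxels), and the effective degrees of freedom
    T - 8 - 2.
    """
    seed_ts = np.asarray(seed_ts, dtype=float)
    T = seed_ts.shape[0]
    nuisance = np.asarray(nuisance, dtype=float)
    if nuisance.shape[0] != T or series.shape[3] != T:
        raise ValidationError("seed, series and nuisance time lengths differ")
    df = T - nuisance.shape[1] - 2
    if df <= 0:
        raise ValidationError(f"not enough timepoints: df = {df}")
    X = np.column_stack([np.ones(T), nuisance])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("nuisance design is rank deficient")
    q, _ = np.linalg.qr(X)

    brain_mask = np.asarray(brain_mask, dtype=bool)
    Y = series[brain_mask].T                       # T x V
    Y = Y - q @ (q.T @ Y)
    s = seed_ts - q @ (q.T @ seed_ts)
    s_norm = np.linalg.norm(s)
    if s_norm == 0:
        raise DesignError("seed time course is entirely explained by nuisance")
    y_norm = np.linalg.norm(Y, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (s @ Y) / (s_norm * y_norm)
    r[y_norm == 0] = np.nan
    n_dead = int(np.isnan(r).sum())
    if n_dead:
        logger.info("%d zero-variance voxels marked invalid", n_dead)

    r_map = np.full(brain_mask.shape, np.nan)
    r_map[brain_mask] = r
    return r_map, df


def fisher_z(r):
    """Fisher's variance-stabilising transform z = atanh(r).

    Accepts scalars or arrays with |r| <= 1 (NaN passes through);
    |r| >= 1 - 1e-7 is clipped with a logged warning so z stays finite.
    """
    r = np.asarray(r, dtype=float)
    finite = np.isfinite(r)
    if np.any(np.abs(r[finite]) > 1.0):
        raise ValidationError("correlations must satisfy |r| <= 1")
    n_clip = int((np.abs(r[finite]) >= R_CLIP).sum())
    if n_clip:
        logger.warning("clipping %d near-unit correlations to %.0e below 1",
                       n_clip, 1.0 - R_CLIP)
    out = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    return out if out.ndim else float(out)


@dataclass
class ConnectivityMap:
    """Per-voxel Fisher-z connectivity for one subject x one seed."""

    subject_id: str
    seed_name: str
    z: np.ndarray
    df: int


class SeedConnectivity:
    """Transformer: SubjectScan -> {seed name: Fisher-z map}.

    Applies the full per-subject pipeline: temporal preprocessing (quadratic
    detrend + 0.01-0.1 Hz bandpass), seed extraction from unsmoothed data,
    spatial smoothing, nuisance design assembly (motion + WM/CSF means,
    identically filtered), partial correlation, Fisher z.
    """

    def __init__(self, seed_specs=None, f_lo=0.01, f_hi=0.1, fwhm=6.0,
                 temporal_filter=True):
        self.seed_specs = seed_specs
        self.f_lo = f_lo
        self.f_hi = f_hi
        self.fwhm = fwhm
        self.temporal_filter = temporal_filter

    def get_params(self, deep=True):
        return {"seed_specs": self.seed_specs, "f_lo": self.f_lo,
                "f_hi": self.f_hi, "fwhm": self.fwhm,
                "temporal_filter": self.temporal_filter}

    def set_params(self, **params):
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r} for SeedConnectivity")
            setattr(self, key, value)
        return self

    def fit(self, X=None, y=None):
        self.seed_specs_ = self.seed_specs or default_seed_specs()
        return self

    def transform(self, scan, prob_maps):
        """Compute one ConnectivityMap per configured seed for ``scan``.

        ``prob_maps`` maps component names to probabilistic maps on the
        scan's grid.
        """
        if not hasattr(self, "seed_specs_"):
            self.fit()
        pre = BOLDPreprocessor(f_lo=self.f_lo, f_hi=self.f_hi, tr=scan.tr,
                               fwhm=self.fwhm, voxel_size=scan.grid.voxel_size)
        pre.fit()
        # series may arrive already temporally filtered (preprocess stage)
        filtered = (pre.transform(scan.series) if self.temporal_filter
                    else np.asarray(scan.series, dtype=float))
        smoothed = pre.smooth(filtered, mask=scan.brain_mask)
        wm_ts = extract_seed_timecourse(filtered, scan.wm_mask)
        csf_ts = extract_seed_timecourse(filtered, scan.csf_mask)
        motion = pre.transform(scan.motion.T).T  # same filtering as the data
        nuisance = build_nuisance_design(motion, wm_ts, csf_ts)

        out = {}
        for spec in self.seed_specs_:
            seed_mask = resolve_seed_mask(spec, prob_maps, scan.segmentation)
            seed_ts = extract_seed_timecourse(filtered, seed_mask)
            r_map, df = connectivity_map(seed_ts, smoothed, nuisance, scan.brain_mask)
            out[spec.name] = ConnectivityMap(scan.subject_id, spec.name,
                                             fisher_z(r_map), df)
        return out

    def fit_transform(self, scan, prob_maps):
        return self.fit().transform(scan, prob_maps)
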