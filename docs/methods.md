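# Methods

`amygconn` implements a seed-based resting-state functional-connectivity
(rsFC) analysis of early cocaine-relapse risk: per-subject Fisher-z
connectivity maps for amygdala-subdivision seeds, voxelwise group contrasts
with Monte-Carlo cluster-extent correction, and a leave-one-out
cross-validated (LOOCV) logistic classifier of relapse status built on
cluster-mean connectivity. Because no public data accompany the design, a
first-class synthetic cohort generator provides the inputs; every stage is
tested against it.

## The synthetic cohort

The generator emulates a treatment cohort — subjects who relapse within 30
days post-treatment (default n = 24), subjects who stay abstinent (n = 21)
and healthy controls (n = 22) — each with a 6-minute resting BOLD scan: 212
volumes at TR = 1.7 s on a common grid. The default grid is 24 x 24 x 18
voxels at 3.25 x 3.25 x 3 mm, a desk-scale stand-in for a 64 x 64 x 36
acquisition grid; the anatomical layout (brain ellipsoid, left/right
amygdala boxes with basolateral [BLA] and centromedial/superficial [CM/SF]
components, medial-prefrontal-like and visual-cortex-like target zones, a
null zone, and white-matter/CSF blocks) scales with the grid.

A subject's series is

    y_v(t) = signal_v(t) + noise_sd * eta_v(t) + sum_k w_k n_k(t) + drift(t)

* **Signal.** Each circuit owns a latent signal with power confined exactly
  to 0.01–0.1 Hz (complex Gaussian rFFT coefficients on in-band bins only,
  unit variance). Seed-region voxels carry the latent signal at unit
  amplitude (plus low noise, sd 0.1, so a handful of voxels recovers it);
  target-region voxels carry `beta_group` times it. Default couplings:
  0.6 (non-relapse) vs 0.2 (relapse) for the prefrontal-like circuit and
  0.1 vs 0.5 for the two visual-like circuits, with controls at 0.6 / 0.5
  respectively. These are invented, documented-as-arbitrary values chosen
  so both directions of group difference are recoverable at the default
  cohort size.
* **Noise.** White Gaussian noise convolved with a 6-mm-FWHM kernel and
  rescaled by the exact kernel L2 norm, so interior voxels have unit noise
  variance *after* smoothing. Consequently the nuisance-partialled
  correlation between the latent signal and a target voxel has the closed
  form `beta / sqrt(beta^2 + noise_sd^2)` on raw (detrended, unfiltered)
  data — the anchor for the generator's effect-size tests. Temporal
  bandpass later *raises* in-band SNR (out-of-band noise is removed), so
  pipeline z-values exceed this closed form by design.
* **Nuisance and drift.** Six motion parameters (smoothed random walks
  scaled to a +/-1 mm/deg range), plus band-limited white-matter and CSF
  tissue signals, are mixed into every brain voxel with fixed weights; the
  same series are emitted as the motion table and are recoverable as tissue
  means, so nuisance regression can remove them near-exactly. A quadratic
  drift is shared by all brain voxels and is annihilated exactly by
  quadratic detrending.

The generator does **not** simulate between-subject variability in coupling
strength (beta is fixed per group), scanner artifacts, voxel displacement
from motion, or physiological noise spectra. Passing tests therefore show
that the *pipeline machinery* is correct and calibrated, not that effect
sizes of real cohorts would be detected: with no between-subject coupling
variance, group F statistics and classification accuracy on synthetic data
are near their ceilings.

Everything is reproducible from one integer: a `SeedSequence` counter
scheme derives per-subject streams, and datasets written to disk are
byte-identical across reruns.

## Per-subject connectivity maps

Processing order: quadratic detrend → hard discrete-Fourier bandpass
(0.01–0.1 Hz; every out-of-band rFFT bin, including DC, zeroed — exactly
idempotent and bin-testable) → seed time-course extraction from the
*unsmoothed* series → 6-mm isotropic Gaussian smoothing (mask-renormalised
to avoid edge dilution) → nuisance-partialled correlation → Fisher z.

Seeds are the four amygdala subdivisions (L/R BLA, L/R CMA). A component
mask keeps voxels with atlas probability >= 0.5 (inclusive) inside the
subject's amygdala segmentation; CMA is the union of its centromedial and
superficial components. Connectivity is the partial Pearson correlation
between the seed mean and each brain voxel controlling an intercept plus
eight nuisance regressors (six motion parameters and the WM/CSF means),
all given the identical detrend + bandpass as the data so regressors and
data occupy the same frequency band. Partial correlation (rather than a
regression slope) realises the cross-correlation map in a scale-free way;
global-signal regression is deliberately omitted because it can introduce
spurious negative correlations. Fisher z = atanh(r) with |r| clipped at
1 − 1e−7 (z ≈ 8.4) keeps self-correlated voxels finite. Effective df is
T − 8 − 2.

## Group inference

Group maps are massively univariate OLS GLMs `z ~ 1 + group (+ covariates)`
fitted across subjects; the group F (df 1, n − k) equals the squared
pooled-variance two-sample t when there are no covariates, an identity the
tests assert exactly. One-sample maps use t = mean/(sd/sqrt(n)).

Cluster-extent correction follows the AlphaSim logic: voxels pass a
two-tailed uncorrected threshold (default p = 0.005); surviving voxels are
clustered under 26-connectivity (configurable to 6/18 — cluster sizes
depend on the rule), positive and negative effects separately; and only
clusters of at least `k_min` voxels are reported. `k_min` is calibrated by
simulating (default 1000) smooth Gaussian null fields on the analysis
mask, standardising within the mask, thresholding and clustering exactly
as the analysis does, and taking the smallest k whose null exceedance
fraction is <= the family-wise alpha (default 0.05).

The smoothness fed to the simulation defaults to an estimate from the
contrast residual maps (variance-of-neighbour-differences estimator,
clamped at 0 when the field is rougher than white noise, averaged over
axes). With 6 mm applied smoothing on top of 6 mm intrinsic noise
smoothness the residual maps are ~8.5 mm smooth; using the applied kernel
alone would understate the null cluster sizes and inflate the family-wise
error, which is why estimation is the default and a fixed value is only a
configuration option.

Peak coordinates are reported in mm with printed values positive along the
Left/Posterior/Inferior axes (the radiology-style table convention);
internal arrays are RAS-oriented and the convention is a single switch.
Bonferroni-adjusted post-hoc thresholds are alpha/m, displayed to 3
decimals (0.05 over 3 contrasts → 0.017).

## LOOCV relapse classification

For each left-out subject the two-group contrast is recomputed on the
remaining n − 1 subjects and clustered at the same voxel threshold and
`k_min` (not re-simulated per fold: dropping one subject does not change
the field smoothness). For every configured circuit, the fold cluster with
the largest voxel overlap with the full-sample reference cluster is
selected (ties: larger cluster, then higher |peak|); reference clusters
only *locate* the effect and are never applied as masks. If no adequately
sized fold cluster overlaps, the suprathreshold cluster whose peak is
nearest (mm) to the reference peak is used with a logged warning; a fold
with no suprathreshold cluster at all is recorded as failed and excluded.
Cluster-mean Fisher z for all n subjects is extracted from the *fold*
cluster, a maximum-likelihood logistic regression (intercept included,
unstandardised predictors, Newton iterations, tol 1e−8, cap 100) is fitted
on the n − 1 training subjects, and the held-out subject is classified at
a 0.5 probability cutoff with relapse as the positive class. Quasi-perfect
separation (diverging coefficients or a singular Hessian) is flagged and
the limiting direction used for prediction rather than erroring — on
synthetic cohorts with fixed per-group coupling, separation is the norm.

Aggregated held-out predictions give sensitivity, specificity and accuracy
(percent, 1 d.p.) and a Pearson chi-square of the 2 x 2
predicted-vs-actual table (df 1, *no* continuity correction — the variant
that exactly reproduces published cross-validation chi-squares
reconstructed from sensitivity/specificity and group sizes).

**Permutation behaviour.** Under label permutation (with the true-label
reference clusters held fixed) held-out accuracy is centred near the
majority-class rate, confirming that fold-wise cluster re-identification
leaks nothing about the left-out subject. At some cohort seeds the mean
sits a few points *below* the majority rate: the familiar conservative
LOOCV bias — leaving out a subject tilts the training class balance
against that subject's own class, so an intercept-dominated fit votes
against it. The property that matters, absence of optimistic bias, holds
throughout.

## Numerical choices and degenerate inputs

* Bandpass bins are selected with a 1e−12 Hz tolerance; an empty band is an
  error, as is a band reaching Nyquist.
* Zero-variance voxels are marked invalid (NaN) in correlation maps and
  removed from stat-map masks rather than propagating infinities.
* Rank-deficient nuisance or confounded group/covariate designs raise
  design errors before any voxel loop.
* Cluster lists sort by size descending, ties by |peak| descending; the
  peak is the member voxel with the largest |statistic|.
* `k_min` requires alpha >= 1/n_iterations (resolution error otherwise).
* Smoothness estimation requires >= 27 mask voxels.
* The Monte-Carlo cluster simulation, cohort synthesis and permutations
  all draw from explicit `numpy.random.Generator`s; nothing uses global
  random state.

## Problem sizes

The test suite runs the full default cohort (24/21 cocaine subjects, 212
volumes, 24 x 24 x 18 grid) for effect-recovery (20 effect + 20 null runs)
and LOOCV checks (45 folds; 20 label permutations), 1000-iteration
Monte-Carlo calibration plus 500 fresh null fields for family-wise-error
validation, and 200 random masks against a brute-force flood-fill oracle.
`scripts/acceptance.py` repeats the same computations with 5 effect and 5
null cohort runs and 20 permutations.
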