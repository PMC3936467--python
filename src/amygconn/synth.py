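"""Synthetic resting-state BOLD cohort with known connectivity ground truth.

The generator emulates the study design the pipeline targets: a cohort of
cocaine-treatment subjects who either relapse within 30 days or stay
abstinent, plus healthy controls, each with a 6-minute resting scan
(212 volumes at TR 1.7 s by default) on a common grid.

A scan is assembled from
  * per-circuit latent signals, band-limited to 0.01-0.1 Hz, shared between
    a seed region (amygdala-subdivision stand-in) and a cortical target
    region with a group-dependent coupling weight beta;
  * additive nuisance: six motion-parameter time courses (smoothed random
    walks scaled to +/-1 mm/deg) and white-matter / CSF tissue signals,
    mixed into every brain voxel with fixed weights;
  * a quadratic drift shared by all brain voxels;
  * spatially smooth Gaussian noise: white noise convolved with a Gaussian
    of known FWHM and standardised so every interior voxel has unit noise
    variance before scaling by ``noise_sd``.

Because the noise is standardised after smoothing, the nuisance-partialled
correlation between the latent signal and a target voxel has the closed
form beta / sqrt(beta^2 + noise_sd^2), which downstream tests exploit.

Grids default to 24 x 24 x 18 voxels at 3.25 x 3.25 x 3 mm — a desk-scale
stand-in for a whole-brain 64 x 64 x 36 acquisition grid; the region layout
scales with the grid. Everything is reproducible from a single integer
seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import io as vio
from .errors import ValidationError
from .grid import VolumeGrid
from .preprocess import FilterSpec, band_keep_indices, fwhm_to_sigma_voxels

#: noise amplitude inside seed regions (high seed SNR so the latent signal
#: is recoverable by averaging a handful of voxels)
SEED_NOISE_SD = 0.1
#: noise amplitude inside WM/CSF blocks (tissue means act as clean nuisance
#: regressors)
TISSUE_NOISE_SD = 0.05

GROUPS = ("relapse", "nonrelapse", "control")

#: covariate moments per group: (mean, sd) for years of education and years
#: smoking cigarettes, matching the cohort demographics the pipeline models
COVARIATE_MOMENTS = {
    "years_education": {"relapse": (11.83, 1.88), "nonrelapse": (13.29, 2.05),
                        "control": (13.91, 1.41)},
    "years_smoking": {"relapse": (24.32, 9.32), "nonrelapse": (17.88, 9.07),
                      "control": (0.0, 0.0)},
}


@dataclass(frozen=True)
class CohortSpec:
    """Sizes and acquisition parameters of a synthetic cohort."""

    n_relapse: int = 24
    n_nonrelapse: int = 21
    n_control: int = 22
    grid_dims: tuple = (24, 24, 18)
    voxel_size: tuple = (3.25, 3.25, 3.0)
    n_volumes: int = 212
    tr: float = 1.7
    seed: int = 0

    def __post_init__(self):
        for name in ("n_relapse", "n_nonrelapse", "n_control"):
            if getattr(self, name) < 2:
                raise ValidationError(f"{name} must be >= 2, got {getattr(self, name)}")
        if self.n_volumes < 8:
            raise ValidationError("n_volumes must be >= 8")
        if any(v <= 0 for v in self.voxel_size):
            raise ValidationError(f"voxel sizes must be > 0, got {self.voxel_size}")
        if any(d < 16 for d in self.grid_dims):
            raise ValidationError("grid dims must be >= 16 to place all regions")

    @property
    def grid(self):
        return VolumeGrid(dims=self.grid_dims, voxel_size=self.voxel_size)

    @property
    def scan_seconds(self):
        return self.n_volumes * self.tr


@dataclass
class CircuitTruth:
    """Ground-truth seed-to-target coupling for one circuit.

    ``coupling_by_group`` maps a group label to beta, the weight of the
    shared band-limited latent signal in the target region. ``noise_sd``
    is the standard deviation of the smooth noise at each voxel, so the
    nuisance-partialled seed-target correlation is
    beta / sqrt(beta^2 + noise_sd^2).
    """

    name: str
    seed_region: str
    target_region: str
    coupling_by_group: dict
    noise_sd: float = 1.0
    smoothness_fwhm: float = 6.0
    nuisance_weights: tuple = (0.4, 0.4, 0.4, 0.4, 0.4, 0.4, 0.8, 0.8)
    drift_coeffs: tuple = (0.0, 1.5, 1.0)

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if self.smoothness_fwhm < 0:
            raise ValidationError("smoothness_fwhm must be >= 0")
        for g, b in self.coupling_by_group.items():
            if not np.isfinite(b):
                raise ValidationError(f"coupling for {g} must be finite")
        if len(self.nuisance_weights) != 8:
            raise ValidationError("nuisance_weights must have 8 entries (6 motion + WM + CSF)")


@dataclass
class TruthManifest:
    """Everything needed to generate — and later score — a synthetic cohort."""

    grid: VolumeGrid
    regions: dict            # region name -> bool mask (seeds, targets, null)
    brain_mask: np.ndarray
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    segmentation: dict       # hemisphere 'L'/'R' -> amygdala mask
    seed_probs: dict         # component name -> probabilistic map in [0, 1]
    circuits: list
    subjects: pd.DataFrame
    seed: int

    def __post_init__(self):
        flat = np.zeros(self.grid.dims, dtype=int)
        for mask in self.regions.values():
            flat += mask.astype(int)
        if (flat > 1).any():
            raise ValidationError("truth region masks must be pairwise disjoint")
        if self.subjects["subject_id"].duplicated().any():
            raise ValidationError("subject ids in truth manifest must be unique")

    def coupling_table(self):
        rows = []
        for c in self.circuits:
            for g, b in c.coupling_by_group.items():
                rows.append({"circuit": c.name, "group": g, "beta": b})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# signals


def make_band_limited_signal(n_volumes, tr, f_lo=0.01, f_hi=0.1, rng=None):
    """Zero-mean, unit-variance series with power only inside [f_lo, f_hi].

    Built directly in the Fourier domain: complex Gaussian coefficients on
    the in-band rFFT bins, zero elsewhere (including DC), inverted to a
    real series and rescaled to unit sample variance. Spectral containment
    is exact by construction.
    """
    rng = np.random.default_rng(rng)
    keep = band_keep_indices(n_volumes, FilterSpec(f_lo, f_hi, tr))
    coeffs = np.zeros(keep.size, dtype=complex)
    n_keep = int(keep.sum())
    coeffs[keep] = rng.standard_normal(n_keep) + 1j * rng.standard_normal(n_keep)
    series = np.fft.irfft(coeffs, n=n_volumes)
    sd = series.std()
    if sd == 0:  # pragma: no cover - requires degenerate draw
        raise ValidationError("degenerate band-limited draw (zero variance)")
    return series / sd


def _make_motion(n_volumes, rng, n_params=6):
    """Smoothed random walks, zero-mean, scaled to a +/-1 mm/deg range."""
    steps = rng.standard_normal((n_volumes, n_params))
    walks = np.cumsum(steps, axis=0)
    walks = ndimage.gaussian_filter1d(walks, sigma=3.0, axis=0, mode="nearest")
    walks -= walks.mean(axis=0)
    peak = np.abs(walks).max(axis=0)
    peak[peak == 0] = 1.0
    return walks / peak


def _smoothing_norm(sigma_vox):
    """sqrt(sum k^2) of the separable Gaussian kernel scipy applies.

    Dividing a smoothed white-noise field by this constant restores unit
    variance at interior voxels.
    """
    total = 1.0
    for s in sigma_vox:
        if s == 0:
            continue
        radius = int(4.0 * s + 0.5)  # scipy's default truncate=4.0
        n = 2 * radius + 1
        impulse = np.zeros(n)
        impulse[radius] = 1.0
        k = ndimage.gaussian_filter1d(impulse, sigma=s)
        total *= float(np.sum(k * k))
    return np.sqrt(total)


def smooth_unit_noise(dims, n_volumes, fwhm_mm, voxel_size, rng):
    """Spatially smooth noise field with unit variance per interior voxel."""
    field_ = rng.standard_normal(tuple(dims) + (n_volumes,))
    if fwhm_mm > 0:
        sigma = fwhm_to_sigma_voxels(fwhm_mm, voxel_size)
        field_ = ndimage.gaussian_filter(
            field_, sigma=tuple(sigma) + (0.0,), mode="constant", cval=0.0
        )
        field_ /= _smoothing_norm(sigma)
    return field_


# ---------------------------------------------------------------------------
# geometry


def _box(dims, fracs):
    """Integer box from fractional bounds ((fx0, fx1), (fy0, fy1), (fz0, fz1))."""
    slices = []
    for d, (lo, hi) in zip(dims, fracs):
        a, b = int(round(lo * d)), int(round(hi * d))
        b = max(b, a + 1)
        slices.append(slice(a, b))
    return tuple(slices)


def _mask_from_box(dims, fracs):
    m = np.zeros(dims, dtype=bool)
    m[_box(dims, fracs)] = True
    return m


def build_anatomy(grid):
    """Region layout on ``grid``: brain ellipsoid, amygdala seed boxes with
    probabilistic component maps, two cortical target zones, a null zone,
    and WM/CSF blocks. Scales with the grid dimensions."""
    dims = grid.dims
    centre = (np.asarray(dims) - 1) / 2.0
    radii = np.asarray(dims) * 0.46
    idx = np.indices(dims)
    dist2 = sum(((idx[i] - centre[i]) / radii[i]) ** 2 for i in range(3))
    brain = dist2 <= 1.0

    def f(a, b, d=24):
        return (a / d, b / d)

    seg = {}
    seed_probs = {}
    regions = {}
    for hemi, (x0, x1) in (("L", (4, 8)), ("R", (16, 20))):
        amyg = _box(dims, ((x0 / 24, x1 / 24), f(11, 14), (6 / 18, 9 / 18)))
        seg[hemi] = np.zeros(dims, dtype=bool)
        seg[hemi][amyg] = True
        # split the integer segmentation box (never re-round fractions, so
        # components always nest inside it): posterior y slabs form the
        # BLA, the most anterior slab splits into CM (lateral-to-midline
        # half) and SF
        xs, ys, zs = amyg
        y_split = max(ys.start + 1, ys.stop - 1)
        x_mid = (xs.start + xs.stop) // 2
        bla = np.zeros(dims, dtype=bool)
        bla[xs, ys.start:y_split, zs] = True
        cm = np.zeros(dims, dtype=bool)
        cm[xs.start:x_mid, y_split:ys.stop, zs] = True
        sf = np.zeros(dims, dtype=bool)
        sf[x_mid:xs.stop, y_split:ys.stop, zs] = True
        # probabilistic maps: 0.9 in the core, 0.6 rim one voxel anterior of
        # the segmentation box (exercises the segmentation-exclusion rule),
        # 0.3 subthreshold halo
        for name, core in ((f"{hemi}_BLA", bla), (f"{hemi}_CM", cm), (f"{hemi}_SF", sf)):
            prob = np.zeros(dims)
            halo = ndimage.binary_dilation(core, iterations=1)
            prob[halo] = 0.3
            rim = ndimage.binary_dilation(core, iterations=1) & ~core & ~seg[hemi]
            prob[rim] = np.where(prob[rim] > 0, 0.6, prob[rim])
            prob[core] = 0.9
            seed_probs[name] = prob
        regions[f"{hemi}_BLA"] = bla
        regions[f"{hemi}_CMA"] = cm | sf

    regions["vmpfc"] = _mask_from_box(dims, (f(9, 15), f(18, 21), (5 / 18, 8 / 18)))
    regions["visual_l"] = _mask_from_box(dims, (f(5, 11), f(4, 7), (6 / 18, 10 / 18)))
    regions["visual_r"] = _mask_from_box(dims, (f(13, 19), f(4, 7), (6 / 18, 10 / 18)))
    regions["null_zone"] = _mask_from_box(dims, (f(10, 13), f(10, 13), (12 / 18, 15 / 18)))
    wm = _mask_from_box(dims, (f(10, 14), f(8, 11), (8 / 18, 11 / 18)))
    csf = _mask_from_box(dims, (f(11, 13), f(12, 15), (9 / 18, 11 / 18)))

    for name, m in list(regions.items()) + [("wm", wm), ("csf", csf)]:
        if not (m <= brain).all():
            raise ValidationError(f"region {name} extends outside the brain ellipsoid")
    occupied = np.zeros(dims, dtype=int)
    for m in list(regions.values()) + [wm, csf]:
        occupied += m.astype(int)
    if (occupied > 1).any():
        raise ValidationError("anatomy regions overlap")
    return {"brain": brain, "segmentation": seg, "seed_probs": seed_probs,
            "regions": regions, "wm": wm, "csf": csf}


def default_circuits():
    """The three planted circuits and their per-group couplings.

    The couplings are invented defaults, chosen so both directions of
    group difference are recoverable at the default cohort size: the
    medial-prefrontal-like circuit couples more strongly in non-relapse
    subjects (0.6 vs 0.2), the visual-like circuits more strongly in
    relapse subjects (0.5 vs 0.1); controls resemble non-relapse in the
    prefrontal circuit and relapse in the visual circuits.
    """
    return [
        CircuitTruth("cma_vmpfc", "L_CMA", "vmpfc",
                     {"nonrelapse": 0.6, "relapse": 0.2, "control": 0.6}),
        CircuitTruth("bla_visual_l", "L_BLA", "visual_l",
                     {"nonrelapse": 0.1, "relapse": 0.5, "control": 0.5}),
        CircuitTruth("bla_visual_r", "R_BLA", "visual_r",
                     {"nonrelapse": 0.1, "relapse": 0.5, "control": 0.5}),
    ]


def null_circuits():
    """Circuits with identical coupling in every group (null truth)."""
    circuits = default_circuits()
    for c in circuits:
        c.coupling_by_group = {g: 0.3 for g in GROUPS}
    return circuits


def make_subject_table(spec, rng):
    rows = []
    counts = (("relapse", spec.n_relapse), ("nonrelapse", spec.n_nonrelapse),
              ("control", spec.n_control))
    i = 0
    for group, n in counts:
        for _ in range(n):
            i += 1
            edu_m, edu_s = COVARIATE_MOMENTS["years_education"][group]
            smk_m, smk_s = COVARIATE_MOMENTS["years_smoking"][group]
            edu = float(np.clip(rng.normal(edu_m, edu_s), 8.0, 20.0))
            smk = float(np.clip(rng.normal(smk_m, smk_s), 0.0, 45.0))
            rows.append({"subject_id": f"sub-{i:03d}", "group": group,
                         "years_education": round(edu, 1),
                         "years_smoking": round(smk, 1)})
    return pd.DataFrame(rows)


def make_truth(spec, circuits=None):
    """Build the ground-truth manifest (anatomy, circuits, subject table)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0xA17]))
    anatomy = build_anatomy(spec.grid)
    circuits = default_circuits() if circuits is None else circuits
    region_names = set(anatomy["regions"])
    for c in circuits:
        for r in (c.seed_region, c.target_region):
            if r not in region_names:
                raise ValidationError(f"circuit {c.name}: unknown region {r!r}")
    return TruthManifest(
        grid=spec.grid,
        regions=anatomy["regions"],
        brain_mask=anatomy["brain"],
        wm_mask=anatomy["wm"],
        csf_mask=anatomy["csf"],
        segmentation=anatomy["segmentation"],
        seed_probs=anatomy["seed_probs"],
        circuits=circuits,
        subjects=make_subject_table(spec, rng),
        seed=int(spec.seed),
    )


# ---------------------------------------------------------------------------
# subject synthesis


def synthesize_subject(spec, truth, group, rng, subject_id="sub-000"):
    """Generate one subject's scan; see the module docstring for the model."""
    if group not in GROUPS:
        raise ValidationError(f"unknown group {group!r}; expected one of {GROUPS}")
    rng = np.random.default_rng(rng)
    T, dims = spec.n_volumes, spec.grid.dims
    base = truth.circuits[0]

    latents = {c.name: make_band_limited_signal(T, spec.tr, rng=rng) for c in truth.circuits}
    wm_sig = make_band_limited_signal(T, spec.tr, rng=rng)
    csf_sig = make_band_limited_signal(T, spec.tr, rng=rng)
    motion = _make_motion(T, rng)
    nuisance = np.column_stack([motion, wm_sig, csf_sig])  # T x 8
    nuisance_mix = nuisance @ np.asarray(base.nuisance_weights)

    u = np.linspace(-1.0, 1.0, T)
    a0, a1, a2 = base.drift_coeffs
    drift = a0 + a1 * u + a2 * u * u

    eta = smooth_unit_noise(dims, T, base.smoothness_fwhm, spec.voxel_size, rng)

    series = np.zeros(dims + (T,))
    brain = truth.brain_mask
    series[brain] = base.noise_sd * eta[brain]
    for c in truth.circuits:
        s = latents[c.name]
        seed_m = truth.regions[c.seed_region]
        series[seed_m] = s + SEED_NOISE_SD * eta[seed_m]
        beta = c.coupling_by_group[group]
        target_m = truth.regions[c.target_region]
        series[target_m] = beta * s + c.noise_sd * eta[target_m]
    series[truth.wm_mask] = wm_sig + TISSUE_NOISE_SD * eta[truth.wm_mask]
    series[truth.csf_mask] = csf_sig + TISSUE_NOISE_SD * eta[truth.csf_mask]
    series[brain] += nuisance_mix + drift

    return vio.SubjectScan(
        subject_id=subject_id, grid=spec.grid, series=series, tr=spec.tr,
        motion=motion, brain_mask=brain, wm_mask=truth.wm_mask,
        csf_mask=truth.csf_mask,
        segmentation=truth.segmentation["L"] | truth.segmentation["R"],
    )


def subject_seed(master_seed, index):
    """Per-subject child seed from the cohort seed (stable counter scheme)."""
    return np.random.SeedSequence([int(master_seed), 1, int(index)])


def iter_subject_scans(spec, truth):
    """Yield (row, SubjectScan) per cohort subject, deterministically."""
    for index, row in truth.subjects.reset_index(drop=True).iterrows():
        rng = np.random.default_rng(subject_seed(spec.seed, index))
        yield row, synthesize_subject(spec, truth, row["group"], rng, row["subject_id"])


# ---------------------------------------------------------------------------
# on-disk dataset

MANIFEST_NAME = "truth.json"


def synthesize_cohort(spec, out_dir, circuits=None):
    """Write a full synthetic cohort dataset under ``out_dir``.

    Layout: ``cohort.tsv``, ``truth.json``, a ``masks/`` directory with the
    shared masks and probabilistic seed component maps, and one directory
    per subject holding ``bold.nii.gz`` and ``motion.txt``. Reruns with the
    same spec produce byte-identical files.
    """
    out = Path(out_dir)
    truth = make_truth(spec, circuits=circuits)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    grid = spec.grid
    vio.write_mask(truth.brain_mask, grid, out / "masks" / "brain.nii.gz")
    vio.write_mask(truth.wm_mask, grid, out / "masks" / "wm.nii.gz")
    vio.write_mask(truth.csf_mask, grid, out / "masks" / "csf.nii.gz")
    for hemi, m in truth.segmentation.items():
        vio.write_mask(m, grid, out / "masks" / f"seg_{hemi}.nii.gz")
    for name, prob in truth.seed_probs.items():
        vio.write_volume(prob, grid, out / "masks" / f"prob_{name}.nii.gz")
    for name, m in truth.regions.items():
        vio.write_mask(m, grid, out / "masks" / f"region_{name}.nii.gz")
    vio.write_cohort(truth.subjects, out / "cohort.tsv")

    for row, scan in iter_subject_scans(spec, truth):
        sub_dir = out / row["subject_id"]
        sub_dir.mkdir(exist_ok=True)
        vio.write_volume(scan.series, grid, sub_dir / "bold.nii.gz")
        vio.write_motion(scan.motion, sub_dir / "motion.txt")

    manifest = {
        "spec": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in asdict(spec).items()},
        "circuits": [
            {**{k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(c).items()}}
            for c in truth.circuits
        ],
        "region_sizes": {k: int(v.sum()) for k, v in truth.regions.items()},
        "n_subjects": int(len(truth.subjects)),
    }
    with open(out / MANIFEST_NAME, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth


def read_cohort_dataset(path):
    """Read a dataset written by :func:`synthesize_cohort`.

    Returns ``(manifest, cohort_table, masks, scans)`` where ``masks`` maps
    names to arrays (brain/wm/csf/segmentation/probabilistic components)
    and ``scans`` is a lazy iterator of SubjectScan.
    """
    path = Path(path)
    with open(path / MANIFEST_NAME) as fh:
        manifest = json.load(fh)
    table = vio.load_cohort(path / "cohort.tsv")
    spec_d = dict(manifest["spec"])
    grid = VolumeGrid(dims=tuple(spec_d["grid_dims"]), voxel_size=tuple(spec_d["voxel_size"]))
    masks = {
        "brain": vio.read_mask(path / "masks" / "brain.nii.gz", grid),
        "wm": vio.read_mask(path / "masks" / "wm.nii.gz", grid),
        "csf": vio.read_mask(path / "masks" / "csf.nii.gz", grid),
    }
    for hemi in ("L", "R"):
        masks[f"seg_{hemi}"] = vio.read_mask(path / "masks" / f"seg_{hemi}.nii.gz", grid)
    for p in sorted((path / "masks").glob("prob_*.nii.gz")):
        name = p.name[len("prob_"):-len(".nii.gz")]
        masks[f"prob_{name}"], _ = vio.read_volume(p, expected_grid=grid)
    for p in sorted((path / "masks").glob("region_*.nii.gz")):
        name = p.name[len("region_"):-len(".nii.gz")]
        masks[f"region_{name}"] = vio.read_mask(p, grid)

    def scans():
        for _, row in table.iterrows():
            sub_dir = path / row["subject_id"]
            series, _ = vio.read_volume(sub_dir / "bold.nii.gz", expected_grid=grid)
            motion = vio.read_motion(sub_dir / "motion.txt", n_volumes=series.shape[3])
            yield vio.SubjectScan(
                subject_id=row["subject_id"], grid=grid, series=series,
                tr=float(spec_d["tr"]), motion=motion,
                brain_mask=masks["brain"], wm_mask=masks["wm"],
                csf_mask=masks["csf"],
                segmentation=masks["seg_L"] | masks["seg_R"],
            )

    return manifest, table, masks, scans()
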