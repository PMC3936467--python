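"""Run configuration and stage orchestration.

A single YAML configuration drives the whole study:
simulate -> preprocess -> connectivity -> group -> loocv -> report.
All thresholds are surfaced in the config with the standard analysis
defaults (0.01-0.1 Hz band, 6 mm FWHM, voxel p = 0.005, cluster alpha =
0.05, classification cutoff 0.5); an empty config therefore runs the full
default analysis. One master seed fans out to per-stage, per-subject
child seeds through ``numpy.random.SeedSequence`` counters so any subset
of the pipeline can be regenerated independently and reruns are
bit-identical.

Each stage writes its artifacts plus a provenance entry (parameters,
seeds, input hashes) to ``provenance.json`` in the output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as vio
from .connectivity import SeedConnectivity, default_seed_specs
from .errors import ValidationError
from .grid import VolumeGrid
from .inference import (ClusterInferenceSpec, cluster_report,
                        estimate_smoothness, group_contrast_map,
                        mc_cluster_size_threshold, stat_threshold_from_p,
                        threshold_stat_map)
from .loocv import (LeaveOneOutRelapseClassifier, PredictorSpec, report_table)
from .preprocess import BOLDPreprocessor, FilterSpec
from .synth import CohortSpec, read_cohort_dataset, synthesize_cohort

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "connectivity", "group", "loocv", "report")

_DEFAULT_MODELS = (
    {"name": "cma_vmpfc", "circuits": (("L_CMA", 0),), "covariates": ()},
    {"name": "bla_visual_r", "circuits": (("R_BLA", 0),), "covariates": ()},
    {"name": "bla_visual_l", "circuits": (("L_BLA", 0),), "covariates": ()},
    {"name": "rsfc_combined",
     "circuits": (("L_CMA", 0), ("R_BLA", 0), ("L_BLA", 0)), "covariates": ()},
    {"name": "rsfc_plus_education",
     "circuits": (("L_CMA", 0), ("R_BLA", 0), ("L_BLA", 0)),
     "covariates": ("years_education",)},
)

_KNOWN_KEYS = {
    "out_dir", "seed", "cohort", "filter", "smoothing_fwhm", "seeds",
    "inference", "smoothness", "models", "cutoff",
}


@dataclass
class RunConfig:
    out_dir: Path
    seed: int
    cohort: CohortSpec
    filter_spec: FilterSpec
    smoothing_fwhm: float
    seed_names: tuple
    inference: ClusterInferenceSpec
    smoothness: object          # "estimate" or a number (mm FWHM)
    models: tuple               # of PredictorSpec
    cutoff: float = 0.5


def validate_config(source, out_dir=None, seed=None):
    """Parse + validate a YAML config (path, text, or dict) into RunConfig.

    Missing fields get the standard defaults; every problem found is
    reported at once, with its field path.
    """
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        raw = yaml.safe_load(Path(source).read_text()) or {}
    elif isinstance(source, dict):
        raw = dict(source)
    elif source in (None, ""):
        raw = {}
    else:
        raw = yaml.safe_load(str(source)) or {}
    if not isinstance(raw, dict):
        raise ValidationError("config must be a mapping")

    problems = []
    unknown = sorted(set(raw) - _KNOWN_KEYS)
    if unknown:
        problems.append(f"unknown keys: {unknown}")

    if out_dir is None:
        out_dir = raw.get("out_dir", "amygconn_run")
    if seed is None:
        seed = int(raw.get("seed", 0))

    cohort_kw = dict(raw.get("cohort", {}))
    cohort_kw.setdefault("seed", seed)
    for key in ("grid_dims", "voxel_size"):
        if key in cohort_kw:
            cohort_kw[key] = tuple(cohort_kw[key])
    cohort = None
    try:
        cohort = CohortSpec(**cohort_kw)
    except (TypeError, ValidationError) as exc:
        problems.append(f"cohort: {exc}")

    filt_kw = dict(raw.get("filter", {}))
    filt_kw.setdefault("tr", cohort.tr if cohort else 1.7)
    filter_spec = None
    try:
        filter_spec = FilterSpec(**filt_kw)
    except Exception as exc:
        problems.append(f"filter: {exc}")

    fwhm = float(raw.get("smoothing_fwhm", 6.0))
    if fwhm < 0:
        problems.append(f"smoothing_fwhm: must be >= 0, got {fwhm}")

    seed_names = tuple(raw.get("seeds", [s.name for s in default_seed_specs()]))
    valid_seed_names = {s.name for s in default_seed_specs()}
    bad = sorted(set(seed_names) - valid_seed_names)
    if bad:
        problems.append(f"seeds: unknown seed names {bad}")

    inf_kw = dict(raw.get("inference", {}))
    inference = None
    try:
        inference = ClusterInferenceSpec(**inf_kw)
    except Exception as exc:
        problems.append(f"inference: {exc}")

    smoothness = raw.get("smoothness", "estimate")
    if not (smoothness == "estimate" or isinstance(smoothness, (int, float))):
        problems.append(f"smoothness: expected 'estimate' or a number, got {smoothness!r}")

    cutoff = float(raw.get("cutoff", 0.5))
    if not (0.0 < cutoff < 1.0):
        problems.append(f"cutoff: must be in (0, 1), got {cutoff}")

    models = []
    names = set()
    for i, m in enumerate(raw.get("models", [dict(d) for d in _DEFAULT_MODELS])):
        try:
            spec = PredictorSpec(
                name=m["name"],
                circuits=tuple((s, int(j)) for s, j in m.get("circuits", ())),
                covariates=tuple(m.get("covariates", ())),
            )
        except (KeyError, ValidationError) as exc:
            problems.append(f"models[{i}]: {exc}")
            continue
        if spec.name in names:
            problems.append(f"models[{i}]: duplicate model name {spec.name!r}")
        names.add(spec.name)
        for s, _ in spec.circuits:
            if s not in seed_names:
                problems.append(f"models[{i}]: circuit seed {s!r} not in configured seeds")
        models.append(spec)

    if problems:
        raise ValidationError("invalid configuration:\n  " + "\n  ".join(problems))
    return RunConfig(out_dir=Path(out_dir), seed=seed, cohort=cohort,
                     filter_spec=filter_spec, smoothing_fwhm=fwhm,
                     seed_names=seed_names, inference=inference,
                     smoothness=smoothness, models=tuple(models), cutoff=cutoff)


# ---------------------------------------------------------------------------
# in-memory pipeline helpers (used by stages, tests and the acceptance script)


def compute_cohort_zmaps(spec, truth, seed_names=None, f_lo=0.01, f_hi=0.1,
                         fwhm=6.0, groups=None):
    """Synthesize each subject, run the per-subject connectivity pipeline,
    and stack the Fisher-z maps per seed.

    Returns ``(zmaps_by_seed, table)`` where each entry of
    ``zmaps_by_seed`` is an (n_subjects, x, y, z) array aligned with the
    cohort ``table``. Scans are generated and discarded one at a time.
    ``groups`` restricts synthesis to a subset of group labels (e.g. the
    two cocaine groups when controls are not analysed).
    """
    specs = [s for s in default_seed_specs()
             if seed_names is None or s.name in seed_names]
    conn = SeedConnectivity(seed_specs=specs, f_lo=f_lo, f_hi=f_hi, fwhm=fwhm)
    conn.fit()
    from .synth import subject_seed, synthesize_subject

    zmaps = {s.name: [] for s in specs}
    kept = []
    for index, row in truth.subjects.reset_index(drop=True).iterrows():
        if groups is not None and row["group"] not in groups:
            continue
        kept.append(row)
        rng = np.random.default_rng(subject_seed(spec.seed, index))
        scan = synthesize_subject(spec, truth, row["group"], rng,
                                  row["subject_id"])
        maps = conn.transform(scan, truth.seed_probs)
        for name, cmap in maps.items():
            zmaps[name].append(np.nan_to_num(cmap.z, nan=0.0))
    table = (truth.subjects if groups is None
             else pd.DataFrame(kept).reset_index(drop=True))
    return {k: np.stack(v) for k, v in zmaps.items()}, table


def contrast_smoothness(zmaps, labels, mask, voxel_size):
    """Scalar FWHM (mm) of the group-contrast residual maps."""
    labels = np.asarray(labels)
    resid = zmaps.copy()
    for lv in np.unique(labels):
        sel = labels == lv
        resid[sel] -= resid[sel].mean(axis=0)
    per_axis = estimate_smoothness(resid, mask, voxel_size)
    return float(np.mean(per_axis))


# ---------------------------------------------------------------------------
# stage runner


def _md5(path):
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _record_provenance(out_dir, stage, params, inputs=()):
    prov_path = Path(out_dir) / "provenance.json"
    entries = []
    if prov_path.exists():
        entries = json.loads(prov_path.read_text())
    entries = [e for e in entries if e["stage"] != stage]
    entries.append({
        "stage": stage,
        "params": params,
        "inputs": {str(p): _md5(p) for p in inputs},
    })
    prov_path.write_text(json.dumps(entries, indent=2, sort_keys=True) + "\n")


def _require(path, stage, needed_by):
    if not Path(path).exists():
        raise ValidationError(
            f"stage {needed_by!r} needs output of stage {stage!r}: missing {path}")
    return Path(path)


def run_pipeline(config, stages=None):
    """Execute the requested stages in order; returns artifact paths."""
    stages = list(STAGES) if stages is None else list(stages)
    bad = sorted(set(stages) - set(STAGES))
    if bad:
        raise ValidationError(f"unknown stages: {bad}")
    stages.sort(key=STAGES.index)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = {}

    dataset_dir = out / "dataset"
    pre_dir = out / "preprocessed"
    zmap_dir = out / "zmaps"
    group_dir = out / "group"
    loocv_dir = out / "loocv"

    if "simulate" in stages:
        synthesize_cohort(config.cohort, dataset_dir)
        _record_provenance(out, "simulate",
                           {"cohort": _jsonable(asdict(config.cohort))},
                           [dataset_dir / "truth.json"])
        artifacts["dataset"] = dataset_dir

    if "preprocess" in stages:
        _require(dataset_dir / "truth.json", "simulate", "preprocess")
        manifest, table, masks, scans = read_cohort_dataset(dataset_dir)
        pre_dir.mkdir(exist_ok=True)
        fs = config.filter_spec
        for scan in scans:
            pre = BOLDPreprocessor(f_lo=fs.f_lo, f_hi=fs.f_hi, tr=scan.tr,
                                   fwhm=config.smoothing_fwhm,
                                   voxel_size=scan.grid.voxel_size)
            filtered = pre.fit_transform(scan.series)
            vio.write_volume(filtered, scan.grid,
                             pre_dir / f"{scan.subject_id}_filtered.nii.gz")
        (pre_dir / "parameters.json").write_text(json.dumps({
            "detrend": "quadratic", "f_lo": fs.f_lo, "f_hi": fs.f_hi,
            "tr": fs.tr, "note": "spatial smoothing applied at connectivity stage"},
            indent=2, sort_keys=True) + "\n")
        _record_provenance(out, "preprocess",
                           {"f_lo": fs.f_lo, "f_hi": fs.f_hi, "tr": fs.tr},
                           [dataset_dir / "truth.json"])
        artifacts["preprocessed"] = pre_dir

    if "connectivity" in stages:
        _require(pre_dir / "parameters.json", "preprocess", "connectivity")
        manifest, table, masks, scans = read_cohort_dataset(dataset_dir)
        zmap_dir.mkdir(exist_ok=True)
        specs = [s for s in default_seed_specs() if s.name in config.seed_names]
        conn = SeedConnectivity(seed_specs=specs, f_lo=config.filter_spec.f_lo,
                                f_hi=config.filter_spec.f_hi,
                                fwhm=config.smoothing_fwhm, temporal_filter=False)
        conn.fit()
        prob_maps = {k[len("prob_"):]: v for k, v in masks.items()
                     if k.startswith("prob_")}
        for scan in scans:
            filtered, _ = vio.read_volume(
                pre_dir / f"{scan.subject_id}_filtered.nii.gz",
                expected_grid=scan.grid)
            scan.series = filtered
            for name, cmap in conn.transform(scan, prob_maps).items():
                vio.write_volume(np.nan_to_num(cmap.z, nan=0.0), scan.grid,
                                 zmap_dir / f"{scan.subject_id}_{name}_zmap.nii.gz")
        _record_provenance(out, "connectivity",
                           {"seeds": list(config.seed_names),
                            "fwhm": config.smoothing_fwhm},
                           [pre_dir / "parameters.json"])
        artifacts["zmaps"] = zmap_dir

    if "group" in stages:
        _require(dataset_dir / "cohort.tsv", "simulate", "group")
        manifest, table, masks, _ = read_cohort_dataset(dataset_dir)
        grid = VolumeGrid(dims=tuple(manifest["spec"]["grid_dims"]),
                          voxel_size=tuple(manifest["spec"]["voxel_size"]))
        mask = masks["brain"]
        cocaine = table[table["group"].isin(["relapse", "nonrelapse"])]
        labels = cocaine["group"].to_numpy()
        zmaps_by_seed = {}
        for name in config.seed_names:
            vols = []
            for sid in cocaine["subject_id"]:
                p = _require(zmap_dir / f"{sid}_{name}_zmap.nii.gz",
                             "connectivity", "group")
                vol, _ = vio.read_volume(p, expected_grid=grid)
                vols.append(vol)
            zmaps_by_seed[name] = np.stack(vols)

        group_dir.mkdir(exist_ok=True)
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
        if config.smoothness == "estimate":
            fwhm_est = float(np.mean([
                contrast_smoothness(z, labels, mask, grid.voxel_size)
                for z in zmaps_by_seed.values()]))
        else:
            fwhm_est = float(config.smoothness)
        spec_mc = ClusterInferenceSpec(
            voxel_p=config.inference.voxel_p,
            cluster_alpha=config.inference.cluster_alpha,
            n_iterations=config.inference.n_iterations,
            neighborhood=config.inference.neighborhood,
            fwhm_mm=fwhm_est)
        k_min = mc_cluster_size_threshold(mask, spec_mc, rng,
                                          voxel_size=grid.voxel_size)
        tables = []
        for name, zmaps in zmaps_by_seed.items():
            stat_map = group_contrast_map(zmaps, labels,
                                          contrast=f"{name}:relapse-vs-nonrelapse")
            stat_map.mask &= mask
            vio.write_volume(np.nan_to_num(stat_map.values, nan=0.0), grid,
                             group_dir / f"{name}_Fmap.nii.gz")
            thr = stat_threshold_from_p(spec_mc.voxel_p, stat_map.df, "F")
            clusters = threshold_stat_map(stat_map, thr,
                                          neighborhood=spec_mc.neighborhood,
                                          grid=grid)
            tables.append(cluster_report(stat_map, clusters, k_min))
        nonempty = [t for t in tables if len(t)]
        report = (pd.concat(nonempty, ignore_index=True) if nonempty
                  else tables[0])
        report.to_csv(group_dir / "clusters.tsv", sep="\t", index=False)
        (group_dir / "inference.json").write_text(json.dumps({
            "k_min": int(k_min), "fwhm_mm": fwhm_est,
            "voxel_p": spec_mc.voxel_p, "cluster_alpha": spec_mc.cluster_alpha,
            "neighborhood": spec_mc.neighborhood,
            "n_iterations": spec_mc.n_iterations}, indent=2, sort_keys=True) + "\n")
        _record_provenance(out, "group",
                           {"k_min": int(k_min), "fwhm_mm": fwhm_est,
                            "mc_seed": [config.seed, 3]},
                           [dataset_dir / "cohort.tsv"])
        artifacts["group"] = group_dir

    if "loocv" in stages:
        _require(group_dir / "inference.json", "group", "loocv")
        manifest, table, masks, _ = read_cohort_dataset(dataset_dir)
        grid = VolumeGrid(dims=tuple(manifest["spec"]["grid_dims"]),
                          voxel_size=tuple(manifest["spec"]["voxel_size"]))
        inf = json.loads((group_dir / "inference.json").read_text())
        cocaine = table[table["group"].isin(["relapse", "nonrelapse"])]
        labels = cocaine["group"].to_numpy()
        ids = cocaine["subject_id"].tolist()
        zmaps_by_seed = {}
        for name in config.seed_names:
            vols = [vio.read_volume(zmap_dir / f"{sid}_{name}_zmap.nii.gz",
                                    expected_grid=grid)[0] for sid in ids]
            zmaps_by_seed[name] = np.stack(vols)
        loocv_dir.mkdir(exist_ok=True)
        reports = []
        for model in config.models:
            clf = LeaveOneOutRelapseClassifier(
                circuits=model.circuits, covariates=model.covariates,
                voxel_p=inf["voxel_p"], cluster_alpha=inf["cluster_alpha"],
                neighborhood=inf["neighborhood"], k_min=inf["k_min"],
                name=model.name)
            clf.fit(zmaps_by_seed, labels, ids, masks["brain"], grid,
                    covariates=cocaine.reset_index(drop=True))
            reports.append(clf.report_)
        report_table(reports).to_csv(loocv_dir / "report.tsv", sep="\t",
                                     index=False)
        fold_rows = [
            {"model": r.model, "left_out": f.left_out,
             "probability": round(f.probability, 4),
             "predicted": f.predicted, "actual": f.actual}
            for r in reports for f in r.folds
        ]
        pd.DataFrame(fold_rows).to_csv(loocv_dir / "folds.tsv", sep="\t",
                                       index=False)
        _record_provenance(out, "loocv",
                           {"models": [m.name for m in config.models],
                            "k_min": inf["k_min"], "cutoff": config.cutoff},
                           [group_dir / "inference.json"])
        artifacts["loocv"] = loocv_dir

    if "report" in stages:
        _require(loocv_dir / "report.tsv", "loocv", "report")
        summary = {
            "clusters": (group_dir / "clusters.tsv").read_text(),
            "models": (loocv_dir / "report.tsv").read_text(),
        }
        (out / "summary.txt").write_text(
            "Cluster table\n" + summary["clusters"] + "\nModel report\n"
            + summary["models"])
        artifacts["summary"] = out / "summary.txt"

    return artifacts


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
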