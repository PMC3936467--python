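import numpy as np
import pytest
from hypothesis import settings

from amygconn import synth
from amygconn.inference import ClusterInferenceSpec, mc_cluster_size_threshold
from amygconn.pipeline import compute_cohort_zmaps, contrast_smoothness

settings.register_profile("default", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_spec():
    """Full-size cocaine cohort (24 relapse / 21 non-relapse) with the
    minimum number of controls; the LOOCV machinery only uses the cocaine
    groups."""
    return synth.CohortSpec(n_relapse=24, n_nonrelapse=21, n_control=2, seed=11)


@pytest.fixture(scope="session")
def default_truth(default_spec):
    return synth.make_truth(default_spec)


@pytest.fixture(scope="session")
def cohort45(default_spec, default_truth):
    """Fisher-z maps for the three effect-bearing seeds of the default
    cohort, plus the calibrated minimum cluster size. Shared across the
    heavier group-inference and LOOCV tests."""
    zmaps, table = compute_cohort_zmaps(default_spec, default_truth,
                                        seed_names=("L_CMA", "L_BLA", "R_BLA"))
    cocaine = table["group"].isin(["relapse", "nonrelapse"]).to_numpy()
    labels = table["group"].to_numpy()[cocaine]
    zmaps = {k: v[cocaine] for k, v in zmaps.items()}
    ids = table["subject_id"].to_numpy()[cocaine].tolist()
    mask = default_truth.brain_mask
    grid = default_spec.grid
    fwhm = float(np.mean([contrast_smoothness(z, labels, mask, grid.voxel_size)
                          for z in zmaps.values()]))
    spec_mc = ClusterInferenceSpec(fwhm_mm=fwhm)
    k_min = mc_cluster_size_threshold(mask, spec_mc,
                                      np.random.default_rng(2024),
                                      voxel_size=grid.voxel_size)
    covariates = table.loc[cocaine].reset_index(drop=True)
    return {
        "spec": default_spec, "truth": default_truth, "zmaps": zmaps,
        "labels": labels, "ids": ids, "mask": mask, "grid": grid,
        "fwhm": fwhm, "k_min": k_min, "covariates": covariates,
        "settings": spec_mc,
    }


@pytest.fixture(scope="session")
def tiny_spec():
    """Desk-top cohort for end-to-end pipeline tests."""
    return synth.CohortSpec(n_relapse=4, n_nonrelapse=4, n_control=2,
                            grid_dims=(16, 16, 16), voxel_size=(3.25, 3.25, 3.0),
                            n_volumes=64, tr=1.7, seed=5)
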