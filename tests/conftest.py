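import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dtipair import (
    SimulationConfig,
    build_subject_matrix,
    compute_scalar_maps,
    fit_tensor_loglinear,
    load_region_table,
    make_gradient_table,
    make_label_volume,
    simulate_feature_cohort,
    simulate_subject_dwi,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def regions():
    return load_region_table()


@pytest.fixture(scope="session")
def gtab32():
    return make_gradient_table(32, b=1000.0, n_b0=1)


@pytest.fixture(scope="session")
def labels48():
    # 144 voxels: every one of the 48 regions gets exactly 3 voxels
    return make_label_volume((6, 6, 4), 48)


@pytest.fixture(scope="session")
def noiseless_subject(gtab32, labels48):
    """One noiseless case subject: DWI volume plus per-region truth tensors."""
    config = SimulationConfig(
        n_per_class=1, grid_shape=(6, 6, 4), noise_sigma=0.0, effect_size=1.5, seed=11
    )
    dwi, truth = simulate_subject_dwi(config, 1, labels48, gtab32, seed=0)
    return dwi, truth


@pytest.fixture(scope="session")
def noiseless_maps(noiseless_subject, labels48):
    dwi, _ = noiseless_subject
    field = fit_tensor_loglinear(dwi, labels48.labels > 0)
    return compute_scalar_maps(field)


@pytest.fixture(scope="session")
def subject_features(noiseless_maps, labels48, regions):
    return build_subject_matrix(noiseless_maps, labels48.labels, regions, "fixture")


@pytest.fixture(scope="session")
def small_cohort():
    """Strong planted effect, small n: quick substrate for selection tests."""
    return simulate_feature_cohort(
        SimulationConfig(n_per_class=20, effect_size=2.0, seed=5)
    )
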