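import numpy as np
import pytest
from hypothesis import settings

from pfntopo.synthetic import CohortConfig, make_group_atlas, make_sphere_mesh, simulate_cohort

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mesh_small():
    """Two-hemisphere icosphere at subdivision 1: 84 vertices."""
    return make_sphere_mesh(1)


@pytest.fixture(scope="session")
def mesh_single():
    """Single-hemisphere icosphere at subdivision 2: 162 vertices, no wall."""
    return make_sphere_mesh(2, two_hemispheres=False, medial_wall_fraction=0.0)


@pytest.fixture(scope="session")
def atlas_small(mesh_small):
    return make_group_atlas(mesh_small, 6, seed=1)


@pytest.fixture(scope="session")
def loadings_cohort(mesh_small):
    """Fast cohort without time series, planted coupling on network 0."""
    cfg = CohortConfig(n_subjects=200, K=6, T=10, mesh_subdivisions=1,
                       seed=7, include_timeseries=False)
    subjects, truth, mesh = simulate_cohort(cfg, mesh=mesh_small)
    return subjects, truth, mesh


@pytest.fixture(scope="session")
def ts_cohort(mesh_small):
    """Small cohort with time series for decomposition tests."""
    cfg = CohortConfig(n_subjects=8, K=4, T=60, mesh_subdivisions=1, seed=3)
    subjects, truth, mesh = simulate_cohort(cfg, mesh=mesh_small)
    return subjects, truth, mesh


def outcome_and_covariates(subjects, domain=0):
    y = np.array([s.cognition[domain] for s in subjects])
    from pfntopo.prediction import encode_covariates
    cov = encode_covariates([s.age_months for s in subjects],
                            [s.sex for s in subjects],
                            [s.site_id for s in subjects],
                            [s.mean_fd for s in subjects])
    return y, cov
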