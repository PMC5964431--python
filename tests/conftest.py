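import numpy as np
import pytest

from metcovnet import (
    build_group_covariance,
    make_toy_atlas,
    normalize_region_matrix,
    sample_region_matrix,
)


@pytest.fixture(scope="session")
def base_spec():
    """Default 90-region small-world covariance shared across tests."""
    return build_group_covariance(seed=11)


@pytest.fixture(scope="session")
def cohort_pair(base_spec):
    """Two normalized 22-subject cohorts drawn from the same covariance."""
    a = normalize_region_matrix(sample_region_matrix(base_spec, 22, seed=101))
    b = normalize_region_matrix(sample_region_matrix(base_spec, 22, seed=202))
    return a, b


@pytest.fixture(scope="session")
def small_cohort_pair():
    """Two normalized cohorts on 20 regions (fast permutation tests)."""
    spec = build_group_covariance(n_regions=20, backbone_degree=4, seed=5)
    a = normalize_region_matrix(sample_region_matrix(spec, 12, seed=7))
    b = normalize_region_matrix(sample_region_matrix(spec, 12, seed=8))
    return a, b


@pytest.fixture(scope="session")
def toy_atlas():
    return make_toy_atlas(grid_shape=(24, 24, 24), n_regions=90, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
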