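import numpy as np
import pytest

from restica import decompose_cohort, make_ground_truth, simulate_cohort
from restica.backrecon import backreconstruct_cohort


@pytest.fixture(scope="session")
def default_gt():
    """Default-scale ground truth (24^3 grid, T=150, K=6)."""
    return make_ground_truth(seed=0)


@pytest.fixture(scope="session")
def default_cohort(default_gt):
    return simulate_cohort(default_gt, (12, 8, 8), seed=0)


@pytest.fixture(scope="session")
def default_decomp(default_cohort):
    return decompose_cohort(default_cohort, seed=0)


@pytest.fixture(scope="session")
def small_gt():
    """Small ground truth shared by decomposition/backrecon/SDR tests."""
    return make_ground_truth(grid_shape=(16, 16, 16), n_timepoints=100, seed=5)


@pytest.fixture(scope="session")
def small_cohort(small_gt):
    return simulate_cohort(small_gt, (8, 6, 6), seed=5)


@pytest.fixture(scope="session")
def small_decomp(small_cohort):
    return decompose_cohort(small_cohort, seed=5)


@pytest.fixture(scope="session")
def small_networks(small_cohort, small_decomp):
    return backreconstruct_cohort(small_cohort, small_decomp.group_maps, method="guided")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20190083)
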