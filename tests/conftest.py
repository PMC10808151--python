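import numpy as np
import pytest

from ependysurv.predictors import hyper_grid
from ependysurv.preprocess import run_probe_filters
from ependysurv.simulate import CohortConfig, simulate_cohort
from ependysurv.survival import INDETERMINATE, binarize_at_horizon

REDUCED_C = (-3, -1, 1, 3)
REDUCED_GAMMA = (-3, -1, 1, 3)


def reduced_grid(n_features: int):
    """Small C/gamma grid used throughout the tests to keep nested CV fast."""
    return hyper_grid(n_features, c_exponents=REDUCED_C, gamma_exponents=REDUCED_GAMMA)


def labeled_outcomes(cohort, sample_ids=None, horizon: float = 60.0):
    ids = sample_ids if sample_ids is not None else cohort.sample_ids
    statuses = {s: binarize_at_horizon(cohort.pfs[s], horizon).status for s in ids}
    return {s: v for s, v in statuses.items() if v != INDETERMINATE}


@pytest.fixture(scope="session")
def small_cohort():
    cfg = CohortConfig(
        n_samples=200, n_cpgs=1000, n_informative=200, n_batch_cpgs=50, seed=11
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def filtered_small_cohort(small_cohort):
    beta, report = run_probe_filters(small_cohort.beta)
    return small_cohort, beta, report
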