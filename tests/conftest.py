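import numpy as np
import pytest

from connectomeclf.cohort import CohortSpec, between_module_pairs, generate_cohort
from connectomeclf.features import cohort_features
from connectomeclf.network import SparsityGrid


@pytest.fixture(scope="session")
def small_grid():
    """Coarse sparsity grid used by the reduced-scale pipeline tests."""
    return SparsityGrid(0.1, 0.5, 0.05)


@pytest.fixture(scope="session")
def planted_cohort():
    """21-subject cohort with a strong planted between-module edge effect."""
    base = CohortSpec(n_group_pos=11, n_group_neg=10, n_roi=16, n_timepoints=120)
    spec = CohortSpec(
        n_group_pos=11,
        n_group_neg=10,
        n_roi=16,
        n_timepoints=120,
        within_module_weight=0.4,
        between_module_weight=0.1,
        effect_edges=tuple(between_module_pairs(base)[:10]),
        effect_delta=0.25,
        noise_sd=0.5,
        seed=3,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def planted_features(planted_cohort, small_grid):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cohort_features(planted_cohort.timeseries, grid=small_grid, n_random=4, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
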