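import numpy as np
import pytest

from habistrat.cohort import (CohortConfig, default_archetypes,
                              generate_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def archetypes():
    return default_archetypes(8)


def small_cohort_config(**overrides) -> CohortConfig:
    """Scaled-down study conditions for fast end-to-end tests: same cluster
    mixtures and hazards as the defaults, smaller tumors on an isotropic
    grid."""
    params = dict(n_patients=20, tumor_size_range=(8.0, 16.0),
                  spacing=(1.0, 1.0, 1.0), blob_size_mm=3.0, seed=11)
    params.update(overrides)
    return CohortConfig(**params)


@pytest.fixture(scope="session")
def small_cohort():
    cases, truth = generate_cohort(small_cohort_config())
    return cases, truth
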