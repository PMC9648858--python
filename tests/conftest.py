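import warnings

import numpy as np
import pytest

from diffnet import CohortSpec, default_schema, generate_cohort


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def small_cohort():
    """Single-phase cohort with planted drivers, small enough for unit tests."""
    spec = CohortSpec(n_low=80, n_high=80, p=20, n_phases=1, n_drivers=4, seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table, truth = generate_cohort(spec)
    return table, truth


@pytest.fixture(scope="session")
def four_phase_table():
    """Four-phase cohort (15 features per phase) with grade and survival."""
    spec = CohortSpec(
        n_low=70, n_high=50, p=15, n_phases=4, n_drivers=3, n_perturb=2, seed=11
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table, truth = generate_cohort(spec)
    return table, truth


@pytest.fixture(scope="session")
def default_cohort():
    """The full 175-patient, 4x107-feature cohort shape."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table, truth = generate_cohort(CohortSpec(seed=42))
    return table, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
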