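"""Shared fixtures: calibrated parameter sets and reference cohorts.

Session-scoped so the (seconds-long) calibrations run once per test session.
"""

import numpy as np
import pytest

from missim import (
    calibrated_missingness,
    default_population_params,
    generate_complete,
    impose_missingness,
)


@pytest.fixture(scope="session")
def simple_params():
    return default_population_params("simple")


@pytest.fixture(scope="session")
def complex_params():
    return default_population_params("complex")


@pytest.fixture(scope="session")
def mparams_simple_a(simple_params):
    return calibrated_missingness(simple_params, "A", "simple")


@pytest.fixture(scope="session")
def mparams_simple_b(simple_params):
    return calibrated_missingness(simple_params, "B", "simple")


@pytest.fixture(scope="session")
def big_incomplete_a(simple_params, mparams_simple_a):
    """100k-record simple-scenario cohort with calibrated m-DAG A missingness."""
    cohort = generate_complete(simple_params, 100_000, 2_024_001)
    return impose_missingness(cohort, mparams_simple_a, 2_024_002)


@pytest.fixture(scope="session")
def small_cohort(simple_params):
    return generate_complete(simple_params, 2000, 99)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
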