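import numpy as np
import pandas as pd
import pytest

from pigqsc import default_schema
from pigqsc.scoring import perfect_assessment, worst_assessment
from pigqsc.synthetic import GeneratorConfig, generate_cohort
from pigqsc import io as pio


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def perfect(schema):
    return perfect_assessment(schema, n_rooms=3)


@pytest.fixture(scope="session")
def worst(schema):
    return worst_assessment(schema, n_rooms=3)


@pytest.fixture(scope="session")
def small_cohort(schema):
    """A 23-farm synthetic cohort, the study-scale default."""
    return generate_cohort(GeneratorConfig(n_farms=23, seed=7), schema)


@pytest.fixture(scope="session")
def small_cohort_frame(small_cohort):
    return pio.cohort_frame(small_cohort.scorecards, small_cohort.kpis)


@pytest.fixture(scope="session")
def large_cohort(schema):
    """A large calibration cohort shared across correlation-recovery tests."""
    return generate_cohort(GeneratorConfig(n_farms=20_000, seed=1), schema)


@pytest.fixture(scope="session")
def large_cohort_frame(large_cohort):
    return pio.cohort_frame(large_cohort.scorecards, large_cohort.kpis)
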