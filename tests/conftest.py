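import warnings

import numpy as np
import pandas as pd
import pytest

from pefrisk.engine import featurize_patient
from pefrisk.synth import CohortConfig, simulate_cohort, simulate_patient

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort at the default study conditions (seed 1)."""
    return simulate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def default_tables(default_cohort):
    """Labeled daily feature tables for the default cohort."""
    return {p.patient_id: featurize_patient(p) for p in default_cohort}


@pytest.fixture(scope="session")
def small_cohort_config():
    """A reduced cohort for fast structural tests (not calibration)."""
    return CohortConfig(n_patients=3, days_range=(70, 80), mean_days=75, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_cohort_config):
    return simulate_cohort(small_cohort_config)


@pytest.fixture(scope="session")
def small_patient(small_cohort):
    return small_cohort[0]


@pytest.fixture(scope="session")
def small_tables(small_cohort):
    return {p.patient_id: featurize_patient(p) for p in small_cohort}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
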