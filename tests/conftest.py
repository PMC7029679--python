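import numpy as np
import pytest

from watershed_sem import DataInput
from watershed_sem.synthetic_data import CohortConfig, generate_cohort
from watershed_sem.watershed_models import CALM_BATTERY, NKI_BATTERY


@pytest.fixture(scope="session")
def calm_battery():
    return CALM_BATTERY


@pytest.fixture(scope="session")
def nki_battery():
    return NKI_BATTERY


@pytest.fixture(scope="session")
def calm_cohort_5k():
    """Complete-imaging CALM-like cohort, linear task scores."""
    config = CohortConfig(n_subjects=5000, imaging_fraction=1.0,
                          emit_raw_speed=False, seed=11)
    return config, generate_cohort(config)


@pytest.fixture(scope="session")
def calm_cov_5k(calm_cohort_5k):
    """Covariance DataInput over the full CALM battery + tracts."""
    _, df = calm_cohort_5k
    cols = list(CALM_BATTERY.all_columns)
    return DataInput.from_covariance(df[cols].cov().to_numpy(), n=len(df),
                                     names=cols)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
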