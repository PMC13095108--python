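import numpy as np
import pytest

from snpflow.synthetic import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-patient clean cohort reused across model tests."""
    visits, gt = simulate_cohort(CohortSpec(n_patients=60, seed=42))
    return visits, gt


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    from snpflow.cli import prepare_dataset

    visits, _ = small_cohort
    ds, scaler = prepare_dataset(visits, k=4, test_fraction=0.2, seed=42)
    return ds, scaler
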