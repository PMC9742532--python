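import numpy as np
import pandas as pd
import pytest

from dmscreen.synthpop import default_config, sample_population, split_dev_test

#: features used when fitting classifiers in tests
MODEL_FEATURES = [
    "age", "rpr", "sbp", "dbp", "weight", "height", "wc", "hc",
    "bmi", "whr", "whtr", "sleep_duration", "cellphone_years",
    "sex", "smoke", "drink", "physical_activity", "work_status", "education",
]


@pytest.fixture(scope="session")
def big_cohort() -> pd.DataFrame:
    """Calibrated default cohort at n=50,000 (shared; do not mutate)."""
    return sample_population(default_config(n_participants=50_000, seed=20221128))


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """Calibrated default cohort at n=6,000 (shared; do not mutate)."""
    return sample_population(default_config(n_participants=6_000, seed=11))


@pytest.fixture(scope="session")
def dev_test_split(small_cohort):
    return split_dev_test(small_cohort, 0.6, seed=5)


def two_blobs(n: int = 400, separation: float = 4.0, seed: int = 0,
              prevalence: float = 0.5) -> pd.DataFrame:
    """Two Gaussian blobs as a linearly separable toy cohort."""
    rng = np.random.default_rng(seed)
    n_pos = int(round(n * prevalence))
    y = np.concatenate([np.ones(n_pos, bool), np.zeros(n - n_pos, bool)])
    x1 = rng.standard_normal(n) + separation * y
    x2 = rng.standard_normal(n) + separation * y
    return pd.DataFrame({
        "person_id": np.arange(n),
        "f1": x1, "f2": x2,
        "dm_status": y,
    })
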