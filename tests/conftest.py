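import numpy as np
import pandas as pd
import pytest

from taikt.synthetic import CohortSpec, generate_cohort


def vector_with_moments(n: int, mean: float, sd: float) -> np.ndarray:
    """Deterministic vector with exactly the requested sample mean and SD."""
    z = np.arange(n, dtype=float)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z


@pytest.fixture(scope="session")
def small_cohort():
    """Default 27-athlete synthetic cohort (raw records + ground truth)."""
    return generate_cohort(CohortSpec(seed=11))


@pytest.fixture(scope="session")
def small_raw(small_cohort) -> pd.DataFrame:
    return small_cohort[0]


@pytest.fixture(scope="session")
def small_truth(small_cohort) -> dict:
    return small_cohort[1]
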