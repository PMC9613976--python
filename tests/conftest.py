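"""Shared fixtures: random z-tables and a small synthetic cohort."""

import numpy as np
import pandas as pd
import pytest

from speechdx.registry import INDEX_COLUMNS
from speechdx.synthesis import CohortSpec, simulate_feature_cohort


def random_z_table(rng: np.random.Generator, n: int = 12) -> pd.DataFrame:
    """Random z-table holding every column the composite indices need."""
    data = rng.standard_normal((n, len(INDEX_COLUMNS)))
    return pd.DataFrame(data, columns=list(INDEX_COLUMNS))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """One fixed small cohort (feature table, clinical scores) for reuse."""
    spec = CohortSpec(
        n_per_group={"HC": 40, "PD": 10, "PSP": 10, "MSA": 12},
        severity_coupling=0.5,
        seed=7,
    )
    return simulate_feature_cohort(spec)
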