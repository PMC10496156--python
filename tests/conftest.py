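import numpy as np
import pandas as pd
import pytest

from fhpdetect.classify import ModelSpec
from fhpdetect.features import FEATURE_COLUMNS
from fhpdetect.synth_cohort import CohortParams, simulate_feature_table


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """240-subject default cohort used by several module tests."""
    return simulate_feature_table(CohortParams(n_subjects=240, seed=42))


@pytest.fixture(scope="session")
def fast_etc() -> ModelSpec:
    """A small extremely-randomized-trees spec for quick wrapper tests."""
    return ModelSpec.make("extremely_randomized_trees", 0, n_estimators=12)


@pytest.fixture()
def separable_table() -> pd.DataFrame:
    """A table where one feature separates the classes perfectly."""
    rng = np.random.default_rng(7)
    n = 40
    label = np.repeat([0, 1], n // 2)
    df = pd.DataFrame({c: rng.normal(size=n) for c in FEATURE_COLUMNS})
    df["NAH"] = label * 10.0 + df["NAH"] * 0.01
    df["subject_id"] = [f"S{i}" for i in range(n)]
    df["label"] = label
    return df
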