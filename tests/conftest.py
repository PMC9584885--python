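import warnings

import numpy as np
import pandas as pd
import pytest

from proteostrat.io import OmicsMatrix
from proteostrat.simulate import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic cohort shared across the session."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_cohort(CohortConfig(seed=0))


@pytest.fixture(scope="session")
def validation_bundle():
    """An independent synthetic cohort at validation size."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_cohort(CohortConfig(seed=101, n_samples=165))


@pytest.fixture
def toy_matrix():
    """Tiny two-group matrix with a known +1.0 shift in half the features."""
    rng = np.random.default_rng(42)
    n_feat, n_per = 20, 8
    samples = [f"s{i}" for i in range(2 * n_per)]
    base = rng.normal(10, 1, size=(n_feat, 1))
    noise = rng.normal(0, 0.3, size=(n_feat, 2 * n_per))
    values = base + noise
    values[:10, n_per:] += 1.0
    df = pd.DataFrame(values, index=[f"f{i}" for i in range(n_feat)],
                      columns=samples)
    labels = pd.Series(["a"] * n_per + ["b"] * n_per, index=samples)
    return OmicsMatrix(df), labels
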