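import numpy as np
import pandas as pd
import pytest

from aldhnet.network import default_network, derive_coefficients
from aldhnet.simulate import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def coefficients():
    return derive_coefficients(default_network())


@pytest.fixture(scope="session")
def cohort():
    """A moderate synthetic cohort with a strong planted basal-like module."""
    expr, truth = simulate_cohort(CohortSpec(n_samples=200, seed=1))
    return expr, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def tiny_expr():
    """6 genes x 8 samples, fixed values."""
    rng = np.random.default_rng(7)
    genes = [f"g{i}" for i in range(6)]
    samples = [f"s{i}" for i in range(8)]
    return pd.DataFrame(rng.normal(5, 2, (6, 8)), index=genes, columns=samples)
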