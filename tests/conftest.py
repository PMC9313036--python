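import numpy as np
import pandas as pd
import pytest

from urinorm import GeneratorConfig, generate_cohort


@pytest.fixture
def small_table() -> pd.DataFrame:
    """A tiny strictly positive concentration table with named metabolites."""
    rng = np.random.default_rng(42)
    data = rng.lognormal(mean=0.0, sigma=0.5, size=(12, 6))
    return pd.DataFrame(
        data,
        index=[f"S{i}" for i in range(12)],
        columns=["creatinine", "glucose", "urea", "pseudouridine", "citrate", "hippurate"],
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (n=500, 44 metabolites), shared across tests."""
    return generate_cohort(GeneratorConfig(n_samples=500, seed=11))


def random_positive_matrix(rng, n_rows, n_cols):
    frame = pd.DataFrame(
        rng.lognormal(mean=0.0, sigma=1.0, size=(n_rows, n_cols)),
        columns=[f"m{j}" for j in range(n_cols)],
    )
    return frame
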