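import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hyp_settings

hyp_settings.register_profile("repro", derandomize=True, deadline=None)
hyp_settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_table(rng):
    """A 100-row table with two continuous and one categorical covariate."""
    n = 100
    X = pd.DataFrame({
        "age": rng.uniform(20, 80, n),
        "bmi": rng.uniform(15, 45, n),
        "smoker": rng.choice(["never", "former", "current"], n),
    })
    y = rng.normal(0, 1, n) + 0.8 * (X["age"] > 60)
    return X, y.to_numpy()


def random_table(rng, n_rows, n_cols):
    """Small all-continuous table with a noisy outcome, for oracle checks."""
    X = pd.DataFrame(
        rng.uniform(-1, 1, size=(n_rows, n_cols)),
        columns=[f"x{j + 1}" for j in range(n_cols)],
    )
    y = rng.normal(0, 1, n_rows)
    return X, y
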