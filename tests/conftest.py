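import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from amplimark.io import ExpressionMatrix
from amplimark.simulate import default_config, simulate_cohort


@pytest.fixture(scope="session")
def fixture_cohort():
    """The standard synthetic cohort: 2000 genes, 3 batches of 100 samples,
    two planted 25-gene amplicons (prevalence 0.25, 4-MAD shift, HR 4)."""
    return simulate_cohort(default_config(seed=1))


@pytest.fixture()
def small_matrix():
    rng = np.random.default_rng(7)
    genes = [f"g{i}" for i in range(20)]
    samples = [f"s{j}" for j in range(12)]
    values = pd.DataFrame(rng.normal(8, 1, (20, 12)), index=genes, columns=samples)
    batches = pd.Series(["x"] * 6 + ["y"] * 6, index=samples)
    return ExpressionMatrix(values=values, batches=batches)
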