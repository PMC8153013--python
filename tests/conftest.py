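import numpy as np
import pandas as pd
import pytest

from timequad.io import ExpressionMatrix
from timequad.simulate import CohortConfig, generate, generate_toy_fixtures


@pytest.fixture(scope="session")
def toy():
    return generate_toy_fixtures()


@pytest.fixture(scope="session")
def small_cohort():
    """One shared 600-sample synthetic cohort for cross-module tests."""
    return generate(CohortConfig(n_samples=600, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_log2tpm(values, genes=None, samples=None) -> ExpressionMatrix:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), unit="log2TPM"
    )
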