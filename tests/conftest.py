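import numpy as np
import pandas as pd
import pytest

from m6apattern.core_io import ExpressionMatrix
from m6apattern.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One modest planted cohort shared by read-only tests."""
    cfg = SyntheticConfig(n_ra=120, n_hc=40, n_treated=60, seed=11)
    expr, meta, truth = generate_cohort(cfg)
    return cfg, expr, meta, truth


@pytest.fixture
def rng():
    return np.random.default_rng(202409)


def make_matrix(values, genes=None, samples=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(1, values.shape[0] + 1)]
    samples = samples or [f"S{j}" for j in range(1, values.shape[1] + 1)]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))
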