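import numpy as np
import pandas as pd
import pytest

from tmescore.io import ExpressionMatrix
from tmescore.survival import SurvivalData
from tmescore.synthetic import SimulationConfig, generate_cohort, generate_signature_matrix


@pytest.fixture(scope="session")
def signature22():
    """Standard 22-type block signature (15 markers per type)."""
    return generate_signature_matrix(15, 22, seed=1)


@pytest.fixture(scope="session")
def small_signature():
    """Tiny 5-type signature for fast tests."""
    return generate_signature_matrix(8, 5, seed=2)


@pytest.fixture(scope="session")
def benchmark_cohort(signature22):
    """Standard synthetic benchmark: 300 samples, 3 subtypes, hazardous cell types."""
    betas = np.zeros(22)
    betas[[0, 1, 2]] = 6.0
    betas[[7, 8]] = -4.0
    cfg = SimulationConfig(n_samples=300, survival_betas=betas, seed=7)
    return generate_cohort(cfg, signature22)


@pytest.fixture()
def exp_surv_data():
    """Exponential survival with one informative covariate, n=200."""
    rng = np.random.default_rng(5)
    n = 200
    x = rng.normal(size=n)
    t = rng.exponential(1.0 / (0.001 * np.exp(0.7 * x)))
    c = rng.exponential(1500.0, n)
    time = np.maximum(np.minimum(t, c), 1.0)
    event = (t <= c).astype(int)
    ids = np.array([f"s{i}" for i in range(n)])
    return x, SurvivalData(ids, time, event)


def make_expression(values: np.ndarray, prefix_g: str = "g", prefix_s: str = "s") -> ExpressionMatrix:
    genes = [f"{prefix_g}{i}" for i in range(values.shape[0])]
    samples = [f"{prefix_s}{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))
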