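import numpy as np
import pytest

from aftmix import synthetic
from aftmix.survival_data import SurvivalDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(rng):
    """Uncensored n=60, p=4 dataset with one strong covariate."""
    n, p = 60, 4
    X = rng.standard_normal((n, p))
    y = 1.0 + 2.0 * X[:, 0] + 0.3 * rng.standard_normal(n)
    return SurvivalDataset(
        X=X, y=y, delta=np.ones(n, dtype=int),
        gene_names=[f"g{j}" for j in range(p)],
        sample_ids=[f"s{i}" for i in range(n)],
    )


@pytest.fixture
def censored_dataset():
    """Small censored single-component dataset (n=120, p=3)."""
    cfg = synthetic.SimConfig(
        n=120, p=3, K_true=1, pi=np.array([1.0]),
        beta0=np.array([1.0]), beta=np.array([[1.0, -0.5, 0.0]]),
        sigma=np.array([0.6]), censor_rate=0.3, seed=7,
    )
    return synthetic.simulate_dataset(cfg).dataset


def two_component_config(n=200, p=10, seed=0, censor_rate=0.3):
    """Small, well-signalled two-component scenario for EM tests."""
    beta = np.zeros((2, p))
    beta[0, :3] = [1.5, -1.0, 0.8]
    beta[1, -3:] = [-1.2, 1.0, 0.9]
    return synthetic.SimConfig(
        n=n, p=p, K_true=2, pi=np.array([0.45, 0.55]),
        beta0=np.array([1.0, 4.0]), beta=beta,
        sigma=np.array([0.5, 0.8]), rho=0.2, corr_structure="AR1",
        censor_rate=censor_rate, seed=seed,
    )
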