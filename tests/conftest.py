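import numpy as np
import pandas as pd
import pytest

from xsc.expression import CountMatrix, SampleInfo
from xsc.synthetic import SyntheticConfig, generate_counts


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(n_genes=600, n_cell_types=6, n_replicates=3, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """(counts_a, counts_b, ortholog table, truth) on a 600-gene draw."""
    return generate_counts(small_config)


@pytest.fixture
def tiny_matrix() -> CountMatrix:
    counts = pd.DataFrame(
        {
            "s1": [10, 0, 30, 5],
            "s2": [12, 1, 28, 4],
            "s3": [50, 2, 100, 20],
        },
        index=["gA", "gB", "gC", "gD"],
    )
    samples = [
        SampleInfo("s1", "human", "ct0", 1),
        SampleInfo("s2", "human", "ct0", 2),
        SampleInfo("s3", "human", "ct1", 1),
    ]
    return CountMatrix(counts, samples)


def nb_counts(rng: np.random.Generator, mu, alpha: float, size) -> np.ndarray:
    """Reference NB sampler (Var = mu + alpha mu^2) used by simulation tests."""
    if alpha == 0:
        return rng.poisson(mu, size=size)
    lam = rng.gamma(1.0 / alpha, alpha * np.broadcast_to(mu, size))
    return rng.poisson(lam)
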