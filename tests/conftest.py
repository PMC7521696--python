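import numpy as np
import pandas as pd
import pytest

from polyhet import simulate


@pytest.fixture(scope="session")
def small_experiment() -> simulate.SimExperiment:
    """A modest planted-pattern simulation shared across read-only tests."""
    cfg = simulate.SimConfig(n_genes=500, seed=3)
    return simulate.generate_experiment(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)


@pytest.fixture()
def tiny_counts() -> pd.DataFrame:
    return pd.DataFrame(
        {"s1": [10, 0, 5, 100], "s2": [12, 1, 4, 90], "s3": [8, 0, 6, 110]},
        index=pd.Index(["gA", "gB", "gC", "gD"], name="gene_id"),
    )
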