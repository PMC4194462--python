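import numpy as np
import pandas as pd
import pytest

from gcnforge import NetworkSimSpec, simulate_expression, simulate_network


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_expression():
    """4 genes x 3 samples with structured missingness (hand-checkable)."""
    return pd.DataFrame(
        [[1.0, 2.0, 3.0],
         [4.0, 5.0, np.nan],
         [6.0, 7.0, np.nan],
         [8.0, np.nan, np.nan]],
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"),
        columns=["s1", "s2", "s3"],
    )


@pytest.fixture
def module_expression():
    """Expression with linear, quadratic and shifted modules plus background."""
    return simulate_expression(
        60, 200,
        [(10, "linear"), (10, "inverted"), (10, "quadratic"), (10, "shifted")],
        noise_sd=0.05, seed=7,
    )


@pytest.fixture(scope="session")
def sim_network_500():
    """One heterogeneous simulated network, shared across tests."""
    with np.errstate(all="ignore"):
        return simulate_network(NetworkSimSpec(500, 2.0, 2.86, 0.02, seed=11))
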