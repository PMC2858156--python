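import numpy as np
import pytest

from nirnet.matrices import ExpressionMatrix, PerturbationDesign
from nirnet.simulate import SimConfig, random_network, steady_state_data


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_dataset():
    """Noise-free 20-gene benchmark instance with known generating network."""
    cfg = SimConfig(n_genes=20, avg_in_degree=3, noise_sd=0.0, seed=7)
    truth = random_network(cfg)
    X, P = steady_state_data(truth, cfg)
    return truth, X, P


def make_matrices(values_x, values_p=None):
    """Wrap raw arrays into labelled domain matrices."""
    values_x = np.asarray(values_x, dtype=float)
    n, m = values_x.shape
    genes = [f"g{i + 1}" for i in range(n)]
    exps = [f"e{j + 1}" for j in range(m)]
    X = ExpressionMatrix(genes, exps, values_x)
    if values_p is None:
        return X
    P = PerturbationDesign(genes, exps, np.asarray(values_p, dtype=float))
    return X, P
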