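import numpy as np
import pytest

from fconnet import CouplingSpec, generate_coupled_channels, preprocess


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def paired_epochs():
    """EpochSet from a 16-channel recording with 8 disjoint coupled pairs
    (s=0.8) and otherwise independent channels; 20 clean 1-s epochs."""
    edges = [(2 * k, 2 * k + 1, 0.8) for k in range(8)]
    spec = CouplingSpec(
        n_channels=16, coupling_edges=edges, duration_s=20.0, seed=777
    )
    rec = generate_coupled_channels(spec)
    return preprocess(rec), set((i, j) for i, j, _ in edges)


def random_weight_matrix(rng, n, distinct=False):
    """Symmetric non-negative weight matrix with zero diagonal."""
    w = rng.uniform(0.05, 1.0, size=(n, n))
    if distinct:
        iu = np.triu_indices(n, 1)
        vals = rng.permutation(len(iu[0])) + 1.0
        w = np.zeros((n, n))
        w[iu] = vals / (len(vals) + 1.0)
    w = np.triu(w, 1)
    return w + w.T
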