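import numpy as np
import pytest

from symptomnet.simulate import default_truth_network, make_truth_network, simulate_scores


@pytest.fixture(scope="session")
def chain_truth():
    """5-node chain with partial correlations of exactly 0.3."""
    return make_truth_network(5, "chain", 0.3)


@pytest.fixture(scope="session")
def emulator_truth():
    return default_truth_network()


@pytest.fixture(scope="session")
def chain_scores_2000(chain_truth):
    return simulate_scores(chain_truth, n=2000, seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_weight_matrix(rng, p, density=0.5, scale=0.45):
    """Random symmetric zero-diagonal signed weight matrix for graph tests."""
    w = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() < density:
                w[i, j] = w[j, i] = rng.uniform(0.05, scale) * rng.choice([-1.0, 1.0])
    return w
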