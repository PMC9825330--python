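import numpy as np
import pytest

from comorbnet.simulate import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sim_config():
    """Reduced study size for fast end-to-end tests."""
    return SimulationConfig(m_diseases=12, n_clusters=3, snps_per_disease=10,
                            n_patients=4000, seed=7)


def random_signed_weights(rng, m, density=0.4):
    """Random symmetric signed weight matrix with zero diagonal, |w| <= 1."""
    W = rng.uniform(-1, 1, size=(m, m))
    mask = rng.random((m, m)) < density
    W = np.triu(W * mask, k=1)
    return W + W.T
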