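import numpy as np
import pytest

from conformakin import synthetic


@pytest.fixture(scope="session")
def two_state_T():
    """Asymmetric two-state chain with stationary (2/3, 1/3)."""
    return np.array([[0.95, 0.05], [0.10, 0.90]])


@pytest.fixture(scope="session")
def three_state_T():
    """Reversible three-state chain (detailed balance by construction)."""
    pi = np.array([0.5, 0.3, 0.2])
    # symmetric rate skeleton -> reversible transition matrix
    S = np.array([[0.0, 0.06, 0.02],
                  [0.06, 0.0, 0.05],
                  [0.02, 0.05, 0.0]])
    T = S / pi[:, None]
    np.fill_diagonal(T, 1.0 - T.sum(axis=1))
    assert np.all(T >= 0)
    return T


@pytest.fixture(scope="session")
def polymer_traj():
    """Small two-state toy-polymer trajectory with labels."""
    return synthetic.toy_polymer(3000, switch_prob=0.05, noise_sigma=0.3, seed=7)
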