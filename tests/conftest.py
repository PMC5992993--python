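import numpy as np
import pytest

from microstates import (LabelProcessSpec, synth_labels, synth_maps,
                         synthetic_layout)

# A generic 4-state transition matrix with the strong diagonal typical of
# resting-state microstate sequences; row-normalized to machine precision.
STRONG_DIAGONAL_T = np.array([
    [0.799, 0.071, 0.069, 0.061],
    [0.079, 0.771, 0.094, 0.057],
    [0.053, 0.064, 0.767, 0.116],
    [0.099, 0.061, 0.056, 0.784],
])
STRONG_DIAGONAL_T /= STRONG_DIAGONAL_T.sum(axis=1, keepdims=True)


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eig(T.T)
    pi = np.real(v[:, np.argmin(np.abs(w - 1))])
    return pi / pi.sum()


@pytest.fixture(scope="session")
def chain_T():
    return STRONG_DIAGONAL_T.copy()


@pytest.fixture(scope="session")
def chain_pi(chain_T):
    return stationary_distribution(chain_T)


@pytest.fixture(scope="session")
def layout30():
    return synthetic_layout(30)


@pytest.fixture(scope="session")
def maps4(layout30):
    return synth_maps(layout30, n_maps=4, seed=11)


@pytest.fixture(scope="session")
def markov_seq(chain_T):
    """One long first-order chain shared across read-only tests."""
    spec = LabelProcessSpec(mode="markov", n_states=4, T=chain_T, seed=101)
    return synth_labels(spec, 100_000)
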