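import numpy as np
import pytest

from eqprop import (
    LOGISTIC,
    NetworkParams,
    NetworkState,
    RelaxationConfig,
    WorldInput,
    make_fixture_network,
)
from eqprop.data import fixture_state


@pytest.fixture
def small_net():
    """Seeded 4-6-3 layered fixture with one world input."""
    return make_fixture_network((4, 6, 3), seed=7)


@pytest.fixture
def small_state(small_net):
    p, w = small_net
    return fixture_state(p, w)


@pytest.fixture
def oracle_cfg():
    """Tolerance-mode, unclipped relaxation used by all gradient checks."""
    return RelaxationConfig(epsilon=0.5, tolerance=1e-13, max_iter=200_000,
                            clip=False)


@pytest.fixture
def two_unit_net():
    """Two connected units, W_12 = 0.5, no biases: energies computable by
    hand."""
    mask = np.array([[False, True], [True, False]])
    W = np.array([[0.0, 0.5], [0.5, 0.0]])
    p = NetworkParams(W, np.zeros(2), mask)
    u = NetworkState(np.array([1.0, 1.0]), input_idx=np.array([0]),
                     hidden_idx=np.array([], dtype=int),
                     output_idx=np.array([1]))
    return p, u


def random_interior_state(p, w, seed=0):
    """Random state with free units strictly inside (0, 1)."""
    rng = np.random.default_rng(seed)
    st = fixture_state(p, w)
    vals = st.values.copy()
    vals[st.free_idx] = rng.uniform(0.1, 0.9, size=st.free_idx.size)
    return st.with_values(vals)
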