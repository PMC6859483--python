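import numpy as np
import pytest

from loopchar import build_network
from loopchar.fixtures import random_network_spec


@pytest.fixture(scope="session")
def random_networks():
    """A pool of random smooth signed networks (n <= 6) with probe states."""
    rng = np.random.default_rng(20240117)
    nets = []
    for seed in range(100):
        n = int(rng.integers(2, 7))
        net = build_network(random_network_spec(n, edge_prob=0.6, seed=seed))
        state = rng.uniform(0.05, 3.0, size=n)
        nets.append((net, state))
    return nets


def fd_jacobian(f, x, h=1e-6):
    """Central finite-difference Jacobian, the derivative oracle for tests."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    cols = []
    for j in range(n):
        xp, xm = x.copy(), x.copy()
        step = h * (1.0 + abs(x[j]))
        xp[j] += step
        xm[j] -= step
        cols.append((np.asarray(f(xp)) - np.asarray(f(xm))) / (2 * step))
    return np.array(cols).T
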