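import numpy as np
import pytest

from oto.containers import ContactMatrix
from oto.genome import make_bins
from oto.synthetic import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def default_config():
    return SimulationConfig(seed=0)


@pytest.fixture
def small_matrix(rng):
    """A random positive symmetric 30x30 contact matrix."""
    n = 30
    a = rng.uniform(0.5, 3.0, (n, n))
    a = (a + a.T) / 2
    return ContactMatrix(a, make_bins("chr1", n, 250_000))


def sinkhorn_oracle(counts: np.ndarray, tol: float = 1e-12, iters: int = 50_000) -> np.ndarray:
    """Independent symmetric balancing oracle: divide by sqrt of the outer
    product of normalized marginals until row sums equalize, then restore
    the original total. Coded separately from the package's ICE iteration."""
    m = np.array(counts, dtype=float)
    for _ in range(iters):
        s = m.sum(axis=0)
        if s.std() / s.mean() < tol:
            break
        r = s / s.mean()
        m /= np.sqrt(np.outer(r, r))
    m *= counts.sum() / m.sum()
    return m
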