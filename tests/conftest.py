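import numpy as np
import pytest

from cscca.preprocess import OmicsMatrix


@pytest.fixture(scope="session", autouse=True)
def _warm_prox_kernel():
    """Compile the ALM kernel once so timings reflect steady state."""
    from cscca.prox import prox_zero_sum_weighted_l1

    prox_zero_sum_weighted_l1(np.array([1.0, -2.0, 3.0, 0.5]), 0.3, np.ones(4))


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


def make_rank1_pair(n=60, p=12, q=8, noise=0.0, seed=3):
    """Noiseless (or nearly) rank-1 data from known directions.

    b_star is zero-sum (compositional side), a_star unconstrained; returns
    (Y, Z, a_star_unit, b_star_unit).
    """
    rs = np.random.default_rng(seed)
    b_star = rs.normal(size=p)
    b_star -= b_star.mean()
    a_star = np.abs(rs.normal(size=q)) + 0.5
    nu = rs.normal(0.0, 3.0, size=n)
    Z = np.outer(nu, b_star / np.linalg.norm(b_star) ** 2)
    Y = np.outer(nu, a_star / np.linalg.norm(a_star) ** 2)
    if noise:
        Z = Z + rs.normal(0.0, noise, size=Z.shape)
        Y = Y + rs.normal(0.0, noise, size=Y.shape)
    return Y, Z, a_star / np.linalg.norm(a_star), b_star / np.linalg.norm(b_star)


@pytest.fixture
def toy_counts():
    """Small compositional count table with zeros."""
    rs = np.random.default_rng(11)
    counts = rs.poisson(8.0, size=(20, 12)).astype(float)
    counts[rs.random(counts.shape) < 0.2] = 0.0
    return OmicsMatrix(values=counts, compositional=True)
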