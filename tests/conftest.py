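import numpy as np
import pytest

from relbel import DiscreteDistribution
from relbel.models import NormalLocationBase, two_point_base


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def categorical_and_half_bases():
    """Two-point model with one categorical prior (p1=1) and one at 1/2."""
    return two_point_base(1.0), two_point_base(0.5)


@pytest.fixture
def location_bases_n10():
    """Three conjugate location bases: priors (12,2), (9,1), (11,4), n=10."""
    return [
        NormalLocationBase(m, t2, 1.0, 10, 9.87)
        for m, t2 in [(12.0, 2.0), (9.0, 1.0), (11.0, 4.0)]
    ]


def random_discrete_pair(rng, m=4):
    """A random prior/posterior pair on a common support."""
    support = tuple(f"s{i}" for i in range(m))
    prior = DiscreteDistribution(support, rng.dirichlet(np.ones(m)))
    post = DiscreteDistribution(support, rng.dirichlet(np.ones(m)))
    return prior, post


def random_bases(rng, k=3, m=4, n_out=3):
    """k random discrete bases sharing a sampling table and observed outcome."""
    from relbel.models import DiscreteBase

    table = rng.dirichlet(np.ones(n_out), size=m)
    support = tuple(f"t{i}" for i in range(m))
    outcomes = tuple(range(n_out))
    return [
        DiscreteBase(
            table,
            DiscreteDistribution(support, rng.dirichlet(np.ones(m))),
            outcomes,
            0,
        )
        for _ in range(k)
    ]
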