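import numpy as np
import pytest

from conga.sampler import PosteriorDraws
from conga.transform import ConditionalConfig, CountMatrix, EdgeState, TransformSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_counts(rng):
    """Small Poisson count matrix (n=12, P=3) for unit tests."""
    return CountMatrix(values=rng.poisson(3.0, size=(12, 3)))


@pytest.fixture
def spec1():
    return TransformSpec(1.0)


@pytest.fixture
def cfg_small():
    return ConditionalConfig(truncation_B=30)


def make_draws(beta_draws, theta=1.0):
    """Wrap an S x P x P array as PosteriorDraws for inference tests."""
    beta_draws = np.asarray(beta_draws, dtype=float)
    return PosteriorDraws(beta=beta_draws, theta=theta)


@pytest.fixture
def draws_factory():
    return make_draws


def random_edges(P, rng, scale=0.5):
    b = rng.normal(0, scale, size=(P, P))
    b = 0.5 * (b + b.T)
    e = EdgeState.zeros(P)
    e.beta[:] = b
    np.fill_diagonal(e.beta, e.diag_fixed)
    return e


@pytest.fixture
def edges_factory():
    return random_edges
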