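"""Synthetic multivariate count data.

Two generators are provided:

* a Gaussian-copula Poisson scheme -- latent MVN(0, Omega^-1) draws are
  pushed through the standard-normal CDF and the Poisson(lam) quantile
  function, so a zero off-diagonal entry of the latent precision Omega
  implies conditional independence of the corresponding count columns
  while the marginals stay Poisson(lam); and

* an exact enumeration sampler for the count Markov random field
  itself on a truncated lattice, usable only for small node counts but
  exact, which doubles as the oracle for conditional-independence and
  normalization checks.

The default benchmark precision has ceil(0.1 * P(P-1)/2) edges with
weights drawn uniformly from [0.3, 0.6] in magnitude with random sign
before diagonal inflation, and Poisson mean 5 -- a sparse graph with
moderate dependence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .transform import CountMatrix, EdgeState, TransformSpec, transform

__all__ = [
    "CopulaSimConfig",
    "simulate_copula_poisson",
    "make_sparse_precision",
    "default_benchmark_precision",
    "oracle_joint_table",
    "oracle_sample_conga",
    "conditional_mutual_information",
]

DEFAULT_POISSON_MEAN = 5.0
DEFAULT_EDGE_FRACTION = 0.1
DEFAULT_WEIGHT_RANGE = (0.3, 0.6)
DEFAULT_DIAG_DOMINANCE = 0.5


@dataclass
class CopulaSimConfig:
    """Settings of the Gaussian-copula Poisson generator."""

    n: int
    P: int
    precision: np.ndarray
    poisson_mean: float = DEFAULT_POISSON_MEAN
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.precision = np.asarray(self.precision, dtype=float)
        if self.precision.shape != (self.P, self.P):
            raise ValueError("precision must be P x P")
        if not np.allclose(self.precision, self.precision.T):
            raise ValueError("precision must be symmetric")
        if np.any(np.linalg.eigvalsh(self.precision) <= 0):
            raise ValueError("precision must be positive definite")
        if self.poisson_mean <= 0:
            raise ValueError("poisson_mean must be positive")
        if self.n < 2 or self.P < 2:
            raise ValueError("need n >= 2 and P >= 2")


def simulate_copula_poisson(cfg: CopulaSimConfig) -> tuple[CountMatrix, np.ndarray]:
    """Draw counts from the copula scheme; also return the truth graph.

    Z ~ MVN(0, Omega^-1), U = Phi(Z), Y = Q_Pois(lam)(U) columnwise,
    with the Poisson quantile function the left-continuous generalized
    inverse (smallest k with CDF >= u).  Truth adjacency is the support
    of the off-diagonal of Omega.
    """
    rng = np.random.default_rng(cfg.seed)
    cov = np.linalg.inv(cfg.precision)
    cov = 0.5 * (cov + cov.T)
    Z = rng.multivariate_normal(np.zeros(cfg.P), cov, size=cfg.n, method="cholesky")
    U = stats.norm.cdf(Z)
    Y = stats.poisson.ppf(U, cfg.poisson_mean).astype(np.int64)
    truth = np.abs(cfg.precision) > 1e-12
    np.fill_diagonal(truth, False)
    return CountMatrix(values=Y), truth


def make_sparse_precision(
    P: int,
    n_edges: int,
    weight_range: tuple[float, float] = DEFAULT_WEIGHT_RANGE,
    seed: Optional[int] = None,
    diag_dominance: float = DEFAULT_DIAG_DOMINANCE,
) -> tuple[np.ndarray, np.ndarray]:
    """Random sparse symmetric positive-definite precision matrix.

    Chooses ``n_edges`` unordered pairs uniformly, assigns weights of
    random sign with magnitude uniform in ``weight_range``, then sets
    each diagonal entry to the row sum of absolute off-diagonals plus
    ``diag_dominance`` (strict diagonal dominance guarantees positive
    definiteness for any positive margin).
    """
    max_edges = P * (P - 1) // 2
    if not 0 <= n_edges <= max_edges:
        raise ValueError(f"n_edges must lie in [0, {max_edges}]")
    lo, hi = weight_range
    if not 0 < lo <= hi:
        raise ValueError("weight_range must satisfy 0 < low <= high")
    rng = np.random.default_rng(seed)
    pairs = [(j, l) for j in range(P) for l in range(j + 1, P)]
    chosen = rng.choice(max_edges, size=n_edges, replace=False)
    omega = np.zeros((P, P))
    for c in chosen:
        j, l = pairs[int(c)]
        w = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
        omega[j, l] = omega[l, j] = w
    np.fill_diagonal(omega, np.sum(np.abs(omega), axis=1) + diag_dominance)
    if np.any(np.linalg.eigvalsh(omega) <= 0):
        raise ValueError("failed to construct a positive-definite precision")
    adjacency = np.abs(omega) > 1e-12
    np.fill_diagonal(adjacency, False)
    return omega, adjacency


def default_benchmark_precision(
    P: int, seed: Optional[int] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Benchmark precision: ceil(0.1 P(P-1)/2) edges, weights +-[0.3, 0.6],
    diagonal margin 0.5 (latent partial correlations ~0.25-0.5)."""
    n_edges = math.ceil(DEFAULT_EDGE_FRACTION * P * (P - 1) / 2)
    return make_sparse_precision(
        P, n_edges, DEFAULT_WEIGHT_RANGE, seed=seed,
        diag_dominance=DEFAULT_DIAG_DOMINANCE,
    )


def oracle_joint_table(
    log_lambda, edges: EdgeState, spec: TransformSpec, support_max: int
) -> np.ndarray:
    """Exact normalized joint pmf on the lattice {0..support_max}^P.

    Memory is (support_max + 1)^P; intended for P <= 3 with small
    support, as an enumeration oracle.
    """
    log_lambda = np.asarray(log_lambda, dtype=float)
    P = edges.n_nodes
    if log_lambda.shape != (P,):
        raise ValueError("log_lambda must have one entry per node")
    size = (support_max + 1) ** P
    if P > 3 or size > 3_000_000:
        raise ValueError("joint table too large; reduce P or support_max")
    k = np.arange(support_max + 1)
    fk = transform(k, spec)
    node = [k * log_lambda[j] - gammaln(k + 1.0) for j in range(P)]
    off = edges.offdiag()
    shape = (support_max + 1,) * P
    logp = np.zeros(shape)
    for j in range(P):
        sl = [None] * P
        sl[j] = slice(None)
        logp = logp + node[j][tuple(sl)]
    for j in range(P):
        for l in range(j + 1, P):
            slj = [None] * P
            slj[j] = slice(None)
            sll = [None] * P
            sll[l] = slice(None)
            logp = logp - off[j, l] * fk[tuple(slj)] * fk[tuple(sll)]
    m = logp.max()
    p = np.exp(logp - m)
    return p / p.sum()


def oracle_sample_conga(
    log_lambda,
    edges: EdgeState,
    spec: TransformSpec,
    n: int,
    support_max: int = 25,
    seed: Optional[int] = None,
) -> tuple[CountMatrix, np.ndarray]:
    """Exact sampling from the truncated-lattice joint; returns the table too."""
    table = oracle_joint_table(log_lambda, edges, spec, support_max)
    rng = np.random.default_rng(seed)
    flat = rng.choice(table.size, size=n, p=table.ravel())
    rows = np.column_stack(np.unravel_index(flat, table.shape))
    return CountMatrix(values=rows.astype(np.int64)), table


def conditional_mutual_information(table: np.ndarray, j: int, l: int) -> float:
    """Conditional mutual information I(X_j; X_l | rest) from a joint table.

    Computed by summing p(x) log [ p(x_j, x_l | rest) /
    (p(x_j | rest) p(x_l | rest)) ] over the lattice; zero iff the two
    nodes are conditionally independent given the remaining ones.
    """
    P = table.ndim
    if j == l or not (0 <= j < P and 0 <= l < P):
        raise ValueError("need two distinct valid axes")
    rest = tuple(ax for ax in range(P) if ax not in (j, l))
    p_rest = table.sum(axis=(j, l), keepdims=True)
    p_j_rest = table.sum(axis=l, keepdims=True)
    p_l_rest = table.sum(axis=j, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            table > 0,
            np.log(table) + np.log(p_rest) - np.log(p_j_rest) - np.log(p_l_rest),
            0.0,
        )
    del rest
    return float(np.sum(table * ratio))
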