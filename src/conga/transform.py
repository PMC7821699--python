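"""Probability model for the count Markov random field.

The joint pmf of a count vector :math:`X = (X_1, \\dots, X_P)` is

.. math::

    \\Pr(X_1, \\dots, X_P) \\propto
        \\prod_j \\frac{\\lambda_j^{X_j}}{X_j!}
        \\exp\\Big(-\\sum_{j<l} \\beta_{jl} F(X_j) F(X_l)\\Big),

with the bounded, strictly increasing transform
:math:`F(x) = (\\tan^{-1} x)^\\theta`.  Because :math:`F` is bounded by
:math:`U = (\\pi/2)^\\theta`, the edge coefficients :math:`\\beta_{jl}`
are unrestricted in sign: both positive and negative conditional
dependence are representable, unlike the Poisson auto-model.
:math:`\\beta_{jl} = 0` encodes conditional independence of nodes *j*
and *l*.

Node conditionals have an intractable infinite-sum normalizer which is
truncated at ``B`` (default 100) and renormalized; the truncation error
carries an analytic bound exposed here.  All pmf arithmetic is done in
log space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln, logsumexp

__all__ = [
    "TransformSpec",
    "EdgeState",
    "ConditionalConfig",
    "CountMatrix",
    "ThetaSearchResult",
    "transform",
    "log_joint_unnormalized",
    "normalizing_constant_bounds",
    "conditional_logpmf",
    "truncation_error_bound",
    "tune_theta",
]


@dataclass(frozen=True)
class TransformSpec:
    """The edge-potential transform F(x) = (arctan x)**theta.

    Parameters
    ----------
    theta : float
        Positive exponent. Controls both the shape and the range of F;
        the image of F is [0, (pi/2)**theta).
    """

    theta: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.theta) or self.theta <= 0:
            raise ValueError(f"theta must be a positive finite real, got {self.theta}")

    @property
    def sup_value(self) -> float:
        """Supremum U = (pi/2)**theta of the transform."""
        return (np.pi / 2.0) ** self.theta


@dataclass
class EdgeState:
    """Symmetric edge-coefficient matrix with a structurally fixed diagonal.

    ``beta`` holds the off-diagonal edge coefficients (symmetric); the
    diagonal entries are the fixed diagonal of the Gaussian working
    precision surrogate used to build block proposals, and never change
    during sampling.
    """

    beta: np.ndarray
    diag_fixed: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.diag_fixed = np.asarray(self.diag_fixed, dtype=float)
        P = self.beta.shape[0]
        if self.beta.shape != (P, P):
            raise ValueError("beta must be square")
        if self.diag_fixed.shape != (P,):
            raise ValueError("diag_fixed must have one entry per node")
        if not np.allclose(self.beta, self.beta.T):
            raise ValueError("beta must be symmetric")
        np.fill_diagonal(self.beta, self.diag_fixed)

    @property
    def n_nodes(self) -> int:
        return self.beta.shape[0]

    def offdiag(self) -> np.ndarray:
        """beta with a zeroed diagonal (pure edge coefficients)."""
        out = self.beta.copy()
        np.fill_diagonal(out, 0.0)
        return out

    @classmethod
    def zeros(cls, P: int, diag_fixed=None) -> "EdgeState":
        diag = np.ones(P) if diag_fixed is None else np.asarray(diag_fixed, float)
        beta = np.zeros((P, P))
        np.fill_diagonal(beta, diag)
        return cls(beta=beta, diag_fixed=diag)


@dataclass(frozen=True)
class ConditionalConfig:
    """Truncation of the node-conditional normalizer at ``truncation_B``."""

    truncation_B: int = 100

    def __post_init__(self) -> None:
        if int(self.truncation_B) != self.truncation_B or self.truncation_B < 1:
            raise ValueError("truncation_B must be a positive integer")

    def validate_counts(self, counts: np.ndarray) -> None:
        m = int(np.max(counts))
        if m > self.truncation_B:
            warnings.warn(
                f"max observed count {m} exceeds truncation_B={self.truncation_B}; "
                "raise truncation_B before fitting",
                UserWarning,
            )


@dataclass
class CountMatrix:
    """An n x P matrix of non-negative integer counts.

    Rows are independent replicates, columns are nodes of the graph.
    """

    values: np.ndarray
    node_names: list[str] = field(default_factory=list)
    replicate_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(np.isfinite(vals)) or np.any(vals != np.floor(vals)):
                raise ValueError("counts must be integers")
            vals = vals.astype(np.int64)
        if np.any(vals < 0):
            raise ValueError("counts must be non-negative")
        n, P = vals.shape
        if n < 2 or P < 2:
            raise ValueError(f"need at least 2 replicates and 2 nodes, got {n} x {P}")
        self.values = vals.astype(np.int64)
        if not self.node_names:
            self.node_names = [f"V{j + 1}" for j in range(P)]
        if not self.replicate_ids:
            self.replicate_ids = [str(t + 1) for t in range(n)]
        if len(self.node_names) != P or len(self.replicate_ids) != n:
            raise ValueError("label lengths do not match matrix shape")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def P(self) -> int:
        return self.values.shape[1]


def transform(x, spec: TransformSpec) -> np.ndarray:
    """Apply F(x) = (arctan x)**theta elementwise.

    Values lie in [0, (pi/2)**theta); F is strictly increasing on
    [0, inf), so the ordering of counts is preserved.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0):
        raise ValueError("transform is defined for finite non-negative inputs only")
    return np.arctan(arr) ** spec.theta


def log_joint_unnormalized(
    x, log_lambda, edges: EdgeState, spec: TransformSpec
) -> float:
    """Log of the unnormalized joint pmf at a single count vector.

    Returns sum_j [x_j log(lambda_j) - log(x_j!)]
    - sum_{j<l} beta_jl F(x_j) F(x_l).
    """
    x = np.asarray(x)
    log_lambda = np.asarray(log_lambda, dtype=float)
    if x.shape != log_lambda.shape or x.shape[0] != edges.n_nodes:
        raise ValueError("dimension mismatch between x, log_lambda and edges")
    if np.any(x < 0) or np.any(x != np.floor(x)):
        raise ValueError("x must be non-negative integers")
    fx = transform(x, spec)
    B = edges.offdiag()
    pois = float(np.sum(x * log_lambda - gammaln(np.asarray(x, float) + 1.0)))
    pair = 0.5 * float(fx @ B @ fx)
    return pois - pair


def normalizing_constant_bounds(
    log_lambda_per_node, edges: EdgeState, spec: TransformSpec
) -> tuple[float, float]:
    """Log-space bounds on the joint normalizing constant A(alpha, beta).

    With U the supremum of F, replacing F by 0 or U in the pairwise term
    sandwiches A between exp(sum_j exp(alpha_j) -/+ U^2 sum_{j<l}|beta_jl|);
    the bounds are returned on the log scale and collapse when all
    beta_jl = 0.
    """
    alpha = np.asarray(log_lambda_per_node, dtype=float)
    if not np.all(np.isfinite(alpha)):
        raise ValueError("log_lambda_per_node must be finite")
    base = float(np.sum(np.exp(alpha)))
    off = edges.offdiag()
    spread = spec.sup_value**2 * 0.5 * float(np.sum(np.abs(off)))
    return base - spread, base + spread


def _conditional_lognumer_grid(
    a: float, eta: float, B: int, spec: TransformSpec
) -> np.ndarray:
    """Unnormalized log conditional mass at k = 0..B for one node/replicate.

    ``a`` is log(lambda_tj); ``eta`` is sum_{l != j} beta_jl F(x_tl).
    """
    k = np.arange(B + 1)
    fk = transform(k, spec)
    return k * a - gammaln(k + 1.0) - fk * eta


def conditional_logpmf(
    j: int,
    x_row,
    log_lambda_tj: float,
    edges: EdgeState,
    spec: TransformSpec,
    cfg: ConditionalConfig,
) -> float:
    """Log conditional pmf of node j given the other nodes in a replicate.

    The infinite normalizer of the node conditional is truncated at
    ``cfg.truncation_B`` and the conditional renormalized over {0..B},
    so the truncated conditional is a proper pmf by construction.
    """
    x_row = np.asarray(x_row)
    B = cfg.truncation_B
    if x_row[j] > B:
        raise ValueError(
            f"observed count {x_row[j]} at node {j} exceeds truncation_B={B}; "
            "raise truncation_B"
        )
    fx = transform(x_row, spec)
    brow = edges.offdiag()[j]
    eta = float(brow @ fx) - brow[j] * fx[j]
    grid = _conditional_lognumer_grid(float(log_lambda_tj), eta, B, spec)
    return float(grid[int(x_row[j])] - logsumexp(grid))


def truncation_error_bound(
    B: int,
    lambda_tj: float,
    x_others,
    beta_row,
    spec: TransformSpec,
    loose: bool = False,
) -> float:
    """Analytic bound on the error of truncating the conditional normalizer.

    The bound is exp(lambda) * P(Poisson(lambda) > B) *
    exp(-sum_{l: beta_jl < 0} beta_jl (pi/2)^theta (arctan x_tl)^theta);
    only negative edge coefficients inflate the tail.  ``loose=True``
    replaces (arctan x_tl)^theta by its supremum (pi/2)^theta, giving a
    data-free bound.  The Poisson tail is taken as P(X >= B+1), which
    makes the bound exact when no coefficient is negative.
    """
    if B < 0 or lambda_tj <= 0:
        raise ValueError("need B >= 0 and lambda_tj > 0")
    x_others = np.asarray(x_others, dtype=float)
    beta_row = np.asarray(beta_row, dtype=float)
    if x_others.shape != beta_row.shape:
        raise ValueError("x_others and beta_row must align")
    tail = stats.poisson.sf(B, lambda_tj)  # P(X >= B+1)
    neg = beta_row < 0
    if loose:
        expo = -np.sum(beta_row[neg]) * spec.sup_value**2
    else:
        expo = -float(
            np.sum(beta_row[neg] * spec.sup_value * transform(x_others[neg], spec))
        )
    return float(np.exp(lambda_tj + expo) * tail)


@dataclass
class ThetaSearchResult:
    """Outcome of the covariance-matching search for theta."""

    theta: float
    objective: float
    grid: np.ndarray
    grid_values: np.ndarray

    @property
    def spec(self) -> TransformSpec:
        return TransformSpec(self.theta)


def _theta_objective(theta: float, X: np.ndarray, cov_x: np.ndarray) -> float:
    fx = np.arctan(X) ** theta
    return float(np.linalg.norm(np.cov(fx, rowvar=False) - cov_x, ord="fro"))


def tune_theta(
    counts: CountMatrix,
    search_interval: tuple[float, float] = (0.1, 10.0),
    grid_size: int = 60,
) -> ThetaSearchResult:
    """Choose theta by covariance matching.

    Minimizes || cov((arctan X)^theta) - cov(X) ||_F over theta in the
    search interval.  A coarse grid scan locates the best bracket, then
    bounded scalar minimization refines within it, so a non-unimodal
    objective is still handled.  Constant columns carry no covariance
    signal and are dropped from the objective with a warning.
    """
    low, high = search_interval
    if low <= 0 or high <= low:
        raise ValueError("need 0 < low < high")
    X = counts.values.astype(float)
    keep = X.std(axis=0) > 0
    if not np.all(keep):
        warnings.warn(
            "constant columns dropped from the theta objective", UserWarning
        )
        X = X[:, keep]
    grid = np.geomspace(low, high, grid_size)
    if X.shape[1] == 0:
        return ThetaSearchResult(low, 0.0, grid, np.zeros_like(grid))
    cov_x = np.cov(X, rowvar=False)
    vals = np.array([_theta_objective(t, X, cov_x) for t in grid])
    if np.allclose(vals, vals[0]):
        warnings.warn("theta objective is constant; returning lower endpoint")
        return ThetaSearchResult(low, float(vals[0]), grid, vals)
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid_size - 1)]
    res = optimize.minimize_scalar(
        _theta_objective,
        bounds=(lo, hi),
        args=(X, cov_x),
        method="bounded",
        options={"xatol": 1e-6},
    )
    theta = float(res.x)
    obj = float(res.fun)
    if vals[i] < obj:  # guard against a flat refine bracket
        theta, obj = float(grid[i]), float(vals[i])
    return ThetaSearchResult(theta, obj, grid, vals)
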