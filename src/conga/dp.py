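"""Dirichlet-process random effects for the node rate parameters.

Each node j carries replicate-specific Poisson-type rates
lambda_tj ~ D_j with D_j ~ DP(M_j D0), D0 = Gamma(a, b), and a
Gamma(c, d) hyperprior on the concentration M_j.  The DP induces ties
among the lambda_tj within a column, clustering replicates and letting
the marginal count distribution at each node be overdispersed or
multimodal relative to the Poisson.

Updates follow the classic collapsed scheme for conjugate-style DP
mixtures: each observation is reassigned to an existing cluster with
weight given by its Poisson likelihood under that cluster's rate, or
to a fresh draw with weight proportional to M_j times the
prior-predictive mass of the observation under the Gamma base measure
(a switchable literal variant evaluates the Gamma density at the
current value instead).  Fresh values are proposed from the conjugate
Gamma(a + x, b + 1) posterior, shrunk toward the current value by a
tuning factor K1, and corrected by Metropolis-Hastings under the
truncated node-conditional pseudo-likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp, roots_genlaguerre

from . import _kernels
from .transform import (
    ConditionalConfig,
    CountMatrix,
    EdgeState,
    TransformSpec,
    conditional_logpmf,
)

__all__ = [
    "NodeEffectsState",
    "reassign_logweights",
    "reassign_lambda",
    "propose_new_lambda",
    "update_concentration",
]


@dataclass
class NodeEffectsState:
    """Rates lambda_tj with DP bookkeeping and concentrations M_j."""

    lam: np.ndarray  # n x P, strictly positive
    concentration: np.ndarray  # P, strictly positive
    base_shape: float = 1.0  # a of the Gamma base measure
    base_rate: float = 1.0  # b of the Gamma base measure
    conc_shape: float = 10.0  # c of the Gamma prior on M_j
    conc_rate: float = 10.0  # d of the Gamma prior on M_j

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=float)
        self.concentration = np.asarray(self.concentration, dtype=float)
        if np.any(self.lam <= 0):
            raise ValueError("all lambda_tj must be strictly positive")
        if np.any(self.concentration <= 0):
            raise ValueError("all concentrations must be strictly positive")
        for v in (self.base_shape, self.base_rate, self.conc_shape, self.conc_rate):
            if v <= 0:
                raise ValueError("hyperparameters must be positive")

    @property
    def n(self) -> int:
        return self.lam.shape[0]

    @property
    def P(self) -> int:
        return self.lam.shape[1]

    def n_unique(self, j: int) -> int:
        """Number of distinct rate values (clusters) in column j."""
        return int(np.unique(self.lam[:, j]).size)

    def to_json(self) -> str:
        """Serialize the state for checkpointing."""
        import json

        return json.dumps(
            {
                "lam": self.lam.tolist(),
                "concentration": self.concentration.tolist(),
                "base_shape": self.base_shape,
                "base_rate": self.base_rate,
                "conc_shape": self.conc_shape,
                "conc_rate": self.conc_rate,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "NodeEffectsState":
        import json

        d = json.loads(text)
        return cls(
            lam=np.asarray(d["lam"], dtype=float),
            concentration=np.asarray(d["concentration"], dtype=float),
            base_shape=d["base_shape"],
            base_rate=d["base_rate"],
            conc_shape=d["conc_shape"],
            conc_rate=d["conc_rate"],
        )

    @classmethod
    def initialize(
        cls, counts: CountMatrix, rng: np.random.Generator, **hyper
    ) -> "NodeEffectsState":
        """Collapsed start: one shared rate per column.

        Each column begins as a single cluster at the base-measure
        posterior mean given all its counts; the reassignment sweep
        splits clusters as the data demand.  (A per-observation start
        makes every rate distinct, which is both a poor match to the
        clustering prior and quadratically expensive for the exact
        reassignment weights until the state collapses.)
        """
        a = hyper.get("base_shape", 1.0)
        b = hyper.get("base_rate", 1.0)
        col_mean = (a + counts.values.sum(axis=0)) / (b + counts.n)
        lam = np.tile(col_mean, (counts.n, 1))
        conc = np.full(
            counts.P, hyper.get("conc_shape", 10.0) / hyper.get("conc_rate", 10.0)
        )
        return cls(lam=lam, concentration=conc, **hyper)


def reassign_logweights(
    t: int,
    j: int,
    state: NodeEffectsState,
    counts: CountMatrix,
    mode: str = "predictive",
    edges: EdgeState | None = None,
    spec: TransformSpec | None = None,
    cfg: ConditionalConfig | None = None,
    n_quad: int = 12,
) -> np.ndarray:
    """Log weights of the collapsed reassignment of observation (t, j).

    In ``mode='exact'`` (requires ``edges``, ``spec`` and ``cfg``) entry
    k != t is the truncated node-conditional log likelihood of x_tj
    under the k-th replicate's rate, and entry t is log M_j plus the
    log integral of that conditional over the Gamma(a, b) base measure
    (generalized Gauss-Laguerre quadrature).  The cheaper modes use the
    plain Poisson likelihood, with the fresh-draw weight either the
    prior-predictive (negative-binomial) mass (``'predictive'``) or the
    Gamma(a + x, b + 1) density at the current value (``'density'``,
    the literal algorithmic form).
    """
    x = float(counts.values[t, j])
    lam_col = state.lam[:, j]
    out = np.empty(state.n)
    if mode == "exact":
        if edges is None or spec is None or cfg is None:
            raise ValueError("exact mode needs edges, spec and cfg")
        x_row = counts.values[t]
        for k in range(state.n):
            if k != t:
                out[k] = conditional_logpmf(
                    j, x_row, np.log(lam_col[k]), edges, spec, cfg
                )
        qn, qw = roots_genlaguerre(n_quad, state.base_shape - 1.0)
        cond_q = np.array(
            [
                conditional_logpmf(
                    j, x_row, np.log(v / state.base_rate), edges, spec, cfg
                )
                for v in qn
            ]
        )
        out[t] = np.log(state.concentration[j]) + logsumexp(
            np.log(qw) - gammaln(state.base_shape) + cond_q
        )
        return out
    _kernels.reassign_logweights(
        x,
        t,
        lam_col,
        state.concentration[j],
        state.base_shape,
        state.base_rate,
        _kernels.MODE_PREDICTIVE if mode == "predictive" else _kernels.MODE_DENSITY,
        out,
    )
    return out


def reassign_lambda(
    t: int,
    j: int,
    state: NodeEffectsState,
    counts: CountMatrix,
    rng: np.random.Generator,
    mode: str = "predictive",
    edges: EdgeState | None = None,
    spec: TransformSpec | None = None,
    cfg: ConditionalConfig | None = None,
) -> tuple[NodeEffectsState, bool]:
    """Sample a cluster reassignment for observation (t, j) in place.

    Returns the state and ``needs_new_value``: True when the fresh-draw
    branch was selected, in which case the caller must follow with
    :func:`propose_new_lambda`.
    """
    lw = reassign_logweights(t, j, state, counts, mode=mode, edges=edges, spec=spec, cfg=cfg)
    w = np.exp(lw - np.max(lw))
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        warnings.warn("degenerate reassignment weights; taking the fresh-draw branch")
        return state, True
    k = int(rng.choice(state.n, p=w / total))
    if k == t:
        return state, True
    state.lam[t, j] = state.lam[k, j]
    return state, False


def propose_new_lambda(
    t: int,
    j: int,
    state: NodeEffectsState,
    counts: CountMatrix,
    edges: EdgeState,
    spec: TransformSpec,
    cfg: ConditionalConfig,
    K1: float,
    rng: np.random.Generator,
) -> float:
    """Metropolis-Hastings fresh draw for lambda_tj.

    Candidate from Gamma(a + x_tj, b + 1), shrunk toward the current
    value by K1 in (0, 1]; the target is the Gamma(a, b) base density
    times the truncated node-conditional likelihood of x_tj.  The
    proposal correction is the ratio of shrunk-Gamma densities; a move
    whose reverse pre-image would be non-positive is rejected outright.
    Returns the (possibly unchanged) value and writes it into the state.
    """
    if not 0 < K1 <= 1:
        raise ValueError("K1 must lie in (0, 1]")
    a, b = state.base_shape, state.base_rate
    x = float(counts.values[t, j])
    lam0 = float(state.lam[t, j])
    lamc = rng.gamma(a + x, 1.0 / (b + 1.0))
    lamp = lam0 + K1 * (lamc - lam0)
    if lamp <= 0:
        return lam0
    lamcr = (lam0 - (1.0 - K1) * lamp) / K1
    if lamcr <= 0:
        return lam0
    x_row = counts.values[t]
    ll0 = conditional_logpmf(j, x_row, np.log(lam0), edges, spec, cfg)
    llp = conditional_logpmf(j, x_row, np.log(lamp), edges, spec, cfg)
    d_target = (a - 1.0) * (np.log(lamp) - np.log(lam0)) - b * (lamp - lam0) + (
        llp - ll0
    )
    aa, bb = a + x, b + 1.0
    d_prop = (aa - 1.0) * (np.log(lamcr) - np.log(lamc)) - bb * (lamcr - lamc)
    if np.log(rng.random()) < d_target + d_prop:
        state.lam[t, j] = lamp
        return lamp
    return lam0


def update_concentration(
    j: int, state: NodeEffectsState, rng: np.random.Generator
) -> float:
    """Two-step augmentation update of the DP concentration M_j.

    delta ~ Beta(M_j, n), then M_j ~ Gamma(c + U_j, d - log delta) with
    U_j the number of distinct rates in column j; d - log delta > 0
    always since delta in (0, 1).
    """
    U = state.n_unique(j)
    delta = rng.beta(max(state.concentration[j], 1e-300), state.n)
    delta = min(max(delta, 1e-300), 1.0 - 1e-16)  # guard the log at 0 and 1
    rate = state.conc_rate - np.log(delta)
    m_new = rng.gamma(state.conc_shape + U, 1.0 / rate)
    state.concentration[j] = m_new
    return float(m_new)


def prior_predictive_logmass(x: float, a: float, b: float) -> float:
    """Log mass of a count under Pois(lam) mixed over Gamma(a, b)."""
    return float(
        gammaln(a + x)
        - gammaln(a)
        - gammaln(x + 1.0)
        + a * np.log(b / (b + 1.0))
        - x * np.log(b + 1.0)
    )


def truncated_gamma_poisson_logpdf(
    lam: np.ndarray, x: int, a: float, b: float, B: int
) -> np.ndarray:
    """Log density (unnormalized) of the beta = 0 fresh-draw target.

    With no edges the node conditional is a Poisson truncated to
    {0..B}, so the target is Gamma(a, b) x Pois_B(x | lam); used as the
    closed-form oracle in conjugate-limit checks.
    """
    lam = np.asarray(lam, dtype=float)
    k = np.arange(B + 1)
    # log S_B(lam) = log sum_k lam^k / k!
    grid = k[None, :] * np.log(lam)[:, None] - gammaln(k + 1.0)[None, :]
    m = grid.max(axis=1)
    logS = m + np.log(np.exp(grid - m[:, None]).sum(axis=1))
    return (a - 1.0 + x) * np.log(lam) - b * lam - logS


def concentration_resim_oracle(
    m0: float, n: int, U: int, c: float, d: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Direct re-simulation of the two-step concentration update."""
    delta = rng.beta(m0, n, size=size)
    return rng.gamma(c + U, 1.0 / (d - np.log(delta)))
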