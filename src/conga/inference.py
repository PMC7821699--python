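"""Graph estimation and comparison from posterior edge-coefficient draws.

An edge (j, l) enters the estimated conditional-independence graph iff
the equal-tailed 95% (by default) credible interval of beta_jl excludes
zero.  The accompanying significance measure

    S_jl = |0.5 - P(beta_jl > 0)| / 0.5  in [0, 1]

is 1 under posterior sign certainty and near 0 when the posterior mass
is balanced around zero.  Cross-condition comparison forms per-edge
differences of draws from two independent chains and flags edges whose
difference interval excludes zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sampler import PosteriorDraws

__all__ = [
    "GraphEstimate",
    "select_edges",
    "compare_graphs",
    "compare_conditions",
    "replication_edge_rate",
    "edge_table",
]


@dataclass
class GraphEstimate:
    """Selected graph with per-edge interval and significance summaries."""

    adjacency: np.ndarray  # P x P bool, symmetric, diagonal False
    significance: np.ndarray  # S_jl in [0, 1]
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    beta_median: np.ndarray
    level: float = 0.95
    node_names: list[str] | None = None

    @property
    def P(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.sum(np.triu(self.adjacency, 1)))

    def edge_list(self) -> list[tuple[int, int]]:
        ju, lu = np.where(np.triu(self.adjacency, 1))
        return list(zip(ju.tolist(), lu.tolist()))


def select_edges(draws: PosteriorDraws, level: float = 0.95) -> GraphEstimate:
    """Equal-tailed credible-interval edge selection.

    Edge present iff 0 lies outside the per-edge interval at the given
    level.  Raising the level widens intervals and never adds edges.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    if draws.n_draws == 0:
        raise ValueError("no stored draws")
    b = draws.beta
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(b, alpha, axis=0)
    hi = np.quantile(b, 1.0 - alpha, axis=0)
    med = np.median(b, axis=0)
    pos = np.mean(b > 0, axis=0)
    sig = np.abs(0.5 - pos) / 0.5
    adj = (lo > 0) | (hi < 0)
    np.fill_diagonal(adj, False)
    np.fill_diagonal(sig, 0.0)
    return GraphEstimate(
        adjacency=adj,
        significance=sig,
        ci_lower=lo,
        ci_upper=hi,
        beta_median=med,
        level=level,
        node_names=list(draws.node_names) or None,
    )


def compare_graphs(est: GraphEstimate | np.ndarray, truth_adjacency) -> tuple[float, float]:
    """False-positive and false-negative edge proportions (p1, p2).

    p1 = (# selected but truly absent) / (# truly absent pairs);
    p2 = (# not selected but truly present) / (# truly present pairs);
    both over unordered pairs j < l.  A truth with no absent (or no
    present) pairs leaves the corresponding proportion undefined (NaN).
    """
    adj = est.adjacency if hasattr(est, "adjacency") else np.asarray(est, bool)
    truth = np.asarray(truth_adjacency, dtype=bool)
    if adj.shape != truth.shape:
        raise ValueError("estimate and truth dimensions differ")
    iu = np.triu_indices(adj.shape[0], 1)
    e, t = adj[iu], truth[iu]
    n_absent = int(np.sum(~t))
    n_present = int(np.sum(t))
    if n_absent == 0:
        warnings.warn("truth has no absent edges; p1 undefined (NaN)")
        p1 = np.nan
    else:
        p1 = float(np.sum(e & ~t) / n_absent)
    if n_present == 0:
        warnings.warn("truth has no present edges; p2 undefined (NaN)")
        p2 = np.nan
    else:
        p2 = float(np.sum(~e & t) / n_present)
    return p1, p2


def compare_conditions(
    draws_s: PosteriorDraws, draws_sprime: PosteriorDraws, level: float = 0.95
) -> tuple[np.ndarray, float]:
    """Cross-condition difference test on edge coefficients.

    Pairs the draws of two independent chains by index (truncating to
    the common draw count), forms Delta_jl = beta^s_jl - beta^s'_jl,
    and flags edges whose equal-tailed interval for Delta excludes
    zero.  Returns the symmetric flag matrix and the similarity
    percentage 100 x (# unflagged pairs) / (# pairs).
    """
    if draws_s.P != draws_sprime.P:
        raise ValueError("draw sets have different numbers of nodes")
    S = min(draws_s.n_draws, draws_sprime.n_draws)
    diff = draws_s.beta[:S] - draws_sprime.beta[:S]
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(diff, alpha, axis=0)
    hi = np.quantile(diff, 1.0 - alpha, axis=0)
    flags = (lo > 0) | (hi < 0)
    np.fill_diagonal(flags, False)
    iu = np.triu_indices(draws_s.P, 1)
    n_pairs = len(iu[0])
    similarity = 100.0 * float(np.sum(~flags[iu])) / n_pairs
    return flags, similarity


def replication_edge_rate(
    per_replicate_estimates: list[GraphEstimate], truth_adjacency
) -> tuple[float, float]:
    """Average (p1, p2) over replicate graph estimates."""
    if not per_replicate_estimates:
        raise ValueError("need at least one replicate estimate")
    pairs = [compare_graphs(est, truth_adjacency) for est in per_replicate_estimates]
    p1s = np.array([p[0] for p in pairs])
    p2s = np.array([p[1] for p in pairs])
    return float(np.nanmean(p1s)), float(np.nanmean(p2s))


def edge_table(est: GraphEstimate) -> pd.DataFrame:
    """Tidy per-pair summary: one row per unordered node pair."""
    P = est.P
    names = est.node_names or [f"V{j + 1}" for j in range(P)]
    rows = []
    for j in range(P):
        for l in range(j + 1, P):
            rows.append(
                {
                    "node_j": names[j],
                    "node_l": names[l],
                    "beta_median": est.beta_median[j, l],
                    "ci_lower": est.ci_lower[j, l],
                    "ci_upper": est.ci_upper[j, l],
                    "S": est.significance[j, l],
                    "selected": bool(est.adjacency[j, l]),
                }
            )
    return pd.DataFrame(rows)
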