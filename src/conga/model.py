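"""Model and results objects for count graphical analysis.

:class:`CongaModel` wraps an observed count matrix; ``fit()`` runs the
pseudo-likelihood MCMC and returns a :class:`CongaResults` holding the
posterior draws of the edge coefficients, interval summaries, edge
selection, and cross-condition comparison.

Example
-------
>>> from conga import CongaModel, simulate
>>> omega, truth = simulate.default_benchmark_precision(10, seed=1)
>>> counts, _ = simulate.simulate_copula_poisson(
...     simulate.CopulaSimConfig(n=100, P=10, precision=omega, seed=1))
>>> res = CongaModel(counts).fit(iterations=4000, burn_in=2000, seed=1)
>>> res.summary().head()
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .inference import (
    GraphEstimate,
    compare_conditions,
    edge_table,
    select_edges,
)
from .sampler import ChainConfig, PosteriorDraws, PriorConfig, run_chain
from .transform import CountMatrix, ThetaSearchResult, tune_theta

__all__ = ["CongaModel", "CongaResults"]


class CongaModel:
    """Count graphical model on an n x P matrix of non-negative counts.

    Parameters
    ----------
    counts : CountMatrix or array-like
        Non-negative integer counts; rows are independent replicates,
        columns are nodes.
    theta : float, optional
        Transform exponent.  Tuned by covariance matching when omitted.
    truncation : int
        Upper limit B of the truncated conditional normalizer.
    priors : PriorConfig, optional
        Hyperparameters of the pseudo-posterior.
    """

    def __init__(
        self,
        counts,
        node_names: Optional[list[str]] = None,
        theta: Optional[float] = None,
        truncation: int = 100,
        priors: Optional[PriorConfig] = None,
    ):
        if not isinstance(counts, CountMatrix):
            counts = CountMatrix(
                values=np.asarray(counts), node_names=list(node_names or [])
            )
        self.counts = counts
        self.theta = theta
        self.truncation = int(truncation)
        self.priors = priors or PriorConfig()
        self._theta_search: Optional[ThetaSearchResult] = None

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "CongaModel":
        counts = CountMatrix(
            values=df.to_numpy(),
            node_names=[str(c) for c in df.columns],
            replicate_ids=[str(i) for i in df.index],
        )
        return cls(counts, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "CongaModel":
        from .io import read_counts

        return cls(read_counts(path), **kwargs)

    def tune_theta(
        self, search_interval: tuple[float, float] = (0.1, 10.0)
    ) -> ThetaSearchResult:
        """Covariance-matching search for theta (cached)."""
        if self._theta_search is None:
            self._theta_search = tune_theta(self.counts, search_interval)
        return self._theta_search

    def fit(
        self,
        iterations: int = 10000,
        burn_in: int = 5000,
        thin: int = 1,
        seed: Optional[int] = None,
        K1: float = 0.5,
        K2: float = 1.0,
        adapt: bool = True,
        store_lambda: bool = False,
        progress: bool = False,
    ) -> "CongaResults":
        """Run the pseudo-posterior sampler and return results."""
        theta = self.theta
        if theta is None:
            theta = self.tune_theta().theta
        cfg = ChainConfig(
            iterations=iterations,
            burn_in=burn_in,
            thin=thin,
            seed=seed,
            K1=K1,
            K2=K2,
            adapt=adapt,
            store_lambda=store_lambda,
            truncation_B=self.truncation,
        )
        draws = run_chain(
            self.counts, cfg, priors=self.priors, theta=theta, progress=progress
        )
        return CongaResults(self, draws)

    def plot_theta_objective(self, ax=None):
        """Plot the covariance-matching objective over the theta grid."""
        from .plotting import plot_theta_objective

        return plot_theta_objective(self.tune_theta(), ax=ax)


class CongaResults:
    """Posterior draws plus graph summaries for a fitted model."""

    def __init__(self, model: Optional[CongaModel], draws: PosteriorDraws):
        self.model = model
        self.draws = draws

    @property
    def beta_draws(self) -> np.ndarray:
        return self.draws.beta

    @property
    def theta(self) -> float:
        return self.draws.theta

    @property
    def params(self) -> np.ndarray:
        """Posterior median edge-coefficient matrix."""
        return np.median(self.draws.beta, axis=0)

    def select_edges(self, level: float = 0.95) -> GraphEstimate:
        return select_edges(self.draws, level=level)

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        """Per-pair table: median, credible interval, S, selection flag."""
        return edge_table(self.select_edges(level=level))

    def compare(self, other: "CongaResults", level: float = 0.95):
        """Cross-condition difference test against another fit."""
        return compare_conditions(self.draws, other.draws, level=level)

    def save(self, path) -> None:
        from .io import save_draws

        save_draws(self.draws, path)

    @classmethod
    def load(cls, path) -> "CongaResults":
        from .io import load_draws

        return cls(None, load_draws(path))

    def plot_graph(self, level: float = 0.95, ax=None):
        from .plotting import plot_graph

        return plot_graph(self.select_edges(level=level), ax=ax)

    def __repr__(self) -> str:  # pragma: no cover
        d = self.draws
        return (
            f"<CongaResults: P={d.P}, draws={d.n_draws}, theta={d.theta:.3f}, "
            f"edges(0.95)={self.select_edges().n_edges}>"
        )
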