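"""Minimal plotting helpers: theta objective curve and graph rendering."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # noqa: E402 -- headless by default
import matplotlib.pyplot as plt
import networkx as nx

from .inference import GraphEstimate
from .transform import ThetaSearchResult

__all__ = ["plot_theta_objective", "plot_graph"]


def plot_theta_objective(result: ThetaSearchResult, ax=None):
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(result.grid, result.grid_values, lw=1.5)
    ax.axvline(result.theta, color="crimson", ls="--", label=f"theta*={result.theta:.3f}")
    ax.set_xscale("log")
    ax.set_xlabel("theta")
    ax.set_ylabel("|| cov(F(X)) - cov(X) ||_F")
    ax.legend()
    return ax


def plot_graph(est: GraphEstimate, ax=None):
    """Draw the selected graph; edge width scales with significance S."""
    if ax is None:
        _, ax = plt.subplots()
    names = est.node_names or [f"V{j + 1}" for j in range(est.P)]
    g = nx.Graph()
    g.add_nodes_from(names)
    widths = []
    for j, l in est.edge_list():
        g.add_edge(names[j], names[l])
        widths.append(0.5 + 3.0 * est.significance[j, l])
    pos = nx.circular_layout(g)
    nx.draw_networkx(g, pos=pos, ax=ax, width=widths or 1.0, node_color="lightsteelblue")
    ax.set_axis_off()
    return ax
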