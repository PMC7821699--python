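"""Reading and writing count matrices, draws, edge lists and manifests.

Count matrices are delimited text with node names in the first row and
an optional first column of replicate identifiers; the dialect (comma
or tab) is chosen by file extension.  Posterior draws are stored as a
compressed numpy archive next to a JSON sidecar carrying all metadata
needed to rerun the fit.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .inference import GraphEstimate, edge_table
from .sampler import PosteriorDraws
from .transform import CountMatrix

__all__ = [
    "read_counts",
    "write_counts",
    "save_draws",
    "load_draws",
    "write_edge_list",
    "write_manifest",
]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_counts(path: str | Path) -> CountMatrix:
    """Read a delimited count matrix; CSV/TSV chosen by extension."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    first = df.columns[0]
    if first == "replicate" or not pd.api.types.is_numeric_dtype(df[first]):
        df = df.set_index(first)
    vals = df.to_numpy()
    bad = ~np.isfinite(vals.astype(float)) | (vals.astype(float) != np.floor(
        vals.astype(float)
    ))
    if bad.any():
        t, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-integer entry at row {df.index[t]!r}, column {df.columns[j]!r} "
            f"in {path}"
        )
    if (vals.astype(float) < 0).any():
        t, j = np.argwhere(vals.astype(float) < 0)[0]
        raise ValueError(
            f"negative count at row {df.index[t]!r}, column {df.columns[j]!r} in {path}"
        )
    return CountMatrix(
        values=vals.astype(np.int64),
        node_names=[str(c) for c in df.columns],
        replicate_ids=[str(i) for i in df.index],
    )


def write_counts(counts: CountMatrix, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        counts.values, index=counts.replicate_ids, columns=counts.node_names
    )
    df.index.name = "replicate"
    df.to_csv(path, sep=_sep_for(path))


def save_draws(draws: PosteriorDraws, path: str | Path) -> None:
    """Store draws as <path>.npz plus a JSON sidecar <path>.json."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix == ".npz" else path
    arrays = {"beta": draws.beta}
    if draws.lam is not None:
        arrays["lam"] = draws.lam
    np.savez_compressed(base.with_suffix(".npz"), **arrays)
    sidecar = {
        "theta": draws.theta,
        "node_names": draws.node_names,
        "meta": draws.meta,
        "n_draws": draws.n_draws,
        "P": draws.P,
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))


def load_draws(path: str | Path) -> PosteriorDraws:
    path = Path(path)
    base = path.with_suffix("") if path.suffix in {".npz", ".json"} else path
    with np.load(base.with_suffix(".npz")) as z:
        beta = z["beta"]
        lam = z["lam"] if "lam" in z.files else None
    sidecar = json.loads(base.with_suffix(".json").read_text())
    return PosteriorDraws(
        beta=beta,
        theta=float(sidecar["theta"]),
        node_names=list(sidecar.get("node_names", [])),
        lam=lam,
        meta=sidecar.get("meta", {}),
    )


def write_edge_list(est: GraphEstimate, path: str | Path) -> None:
    """Tab-separated per-pair table (node_j, node_l, beta_median, CI, S)."""
    edge_table(est).to_csv(Path(path), sep="\t", index=False, float_format="%.6g")


def write_graphml(est: GraphEstimate, path: str | Path) -> None:
    import networkx as nx

    names = est.node_names or [f"V{j + 1}" for j in range(est.P)]
    g = nx.Graph()
    g.add_nodes_from(names)
    for j, l in est.edge_list():
        g.add_edge(
            names[j],
            names[l],
            beta_median=float(est.beta_median[j, l]),
            significance=float(est.significance[j, l]),
        )
    nx.write_graphml(g, str(path))


def write_manifest(
    path: str | Path,
    *,
    inputs: dict,
    config: dict,
    theta: float,
    truncation_B: int,
    acceptance: dict,
    seed,
) -> None:
    """One manifest per fit: everything needed to reproduce the run."""
    manifest = {
        "software": {"name": "conga", "version": __version__},
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "inputs": inputs,
        "config": config,
        "seed": seed,
        "theta": theta,
        "truncation_B": truncation_B,
        "acceptance": acceptance,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
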