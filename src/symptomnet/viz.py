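"""Layout coordinates and standard-format network export.

Layout uses the Fruchterman-Reingold force-directed algorithm with
attraction scaled by absolute edge weight, so strongly connected symptom
pairs land close together; coordinates are rescaled to the unit square
and are deterministic given a seed.  Figures conventionally show positive
edges only; that filter applies to exports alone — every computation in
this package uses the full signed matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .glasso import EDGE_ZERO_TOL, NetworkModel

__all__ = [
    "LayoutCoordinates",
    "layout_fruchterman_reingold",
    "to_networkx",
    "export_network",
    "weights_from_edge_list",
]


@dataclass
class LayoutCoordinates:
    """Per-node (x, y) in the unit square."""

    coords: np.ndarray  # (p, 2)
    iterations: int
    seed: int | None
    node_labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coords, index=self.node_labels, columns=["x", "y"])


def to_networkx(net: NetworkModel, positive_only: bool = False) -> nx.Graph:
    """NetworkX graph with weight and sign edge attributes."""
    g = nx.Graph()
    for i, lab in enumerate(net.node_labels):
        g.add_node(lab, index=i)
    iu, ju = np.triu_indices(net.p, k=1)
    for i, j in zip(iu, ju):
        w = net.weights[i, j]
        if abs(w) <= EDGE_ZERO_TOL:
            continue
        if positive_only and w <= 0:
            continue
        g.add_edge(
            net.node_labels[i], net.node_labels[j],
            weight=float(w), abs_weight=float(abs(w)),
            sign=1 if w > 0 else -1,
        )
    return g


def layout_fruchterman_reingold(
    net: NetworkModel, iterations: int = 500, seed: int | None = 0
) -> LayoutCoordinates:
    """Force-directed coordinates rescaled to the unit square."""
    if net.p == 1:
        coords = np.array([[0.5, 0.5]])
    else:
        g = to_networkx(net)
        pos = nx.spring_layout(
            g, iterations=iterations, seed=seed, weight="abs_weight"
        )
        coords = np.array([pos[lab] for lab in net.node_labels], dtype=float)
        span = coords.max(axis=0) - coords.min(axis=0)
        span[span == 0] = 1.0
        coords = (coords - coords.min(axis=0)) / span
    return LayoutCoordinates(
        coords=coords, iterations=iterations, seed=seed,
        node_labels=list(net.node_labels),
    )


def export_network(
    net: NetworkModel,
    path: str | Path,
    fmt: str = "graphml",
    partition=None,
    centrality_frame: pd.DataFrame | None = None,
    layout: LayoutCoordinates | None = None,
    positive_only: bool = False,
) -> Path:
    """Write the network as GraphML or a weighted edge-list CSV.

    Community ids, centrality columns, and layout coordinates become node
    attributes when supplied.  ``positive_only`` filters edges in the
    export (figure convention) without touching the model.
    """
    path = Path(path)
    g = to_networkx(net, positive_only=positive_only)
    if partition is not None:
        for lab, cid in zip(partition.node_labels, partition.assignment):
            g.nodes[lab]["community"] = int(cid)
    if centrality_frame is not None:
        for col in centrality_frame.columns:
            for lab, val in centrality_frame[col].items():
                g.nodes[lab][col] = float(val)
    if layout is not None:
        for lab, (x, y) in zip(layout.node_labels, layout.coords):
            g.nodes[lab]["x"] = float(x)
            g.nodes[lab]["y"] = float(y)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "edgelist":
        rows = [
            {"node_i": a, "node_j": b, "weight": d["weight"]}
            for a, b, d in g.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["node_i", "node_j", "weight"]).to_csv(
            path, index=False
        )
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    return path


def weights_from_edge_list(path: str | Path, node_labels: list[str]) -> np.ndarray:
    """Rebuild a weight matrix from an exported edge-list CSV."""
    df = pd.read_csv(path)
    index = {lab: i for i, lab in enumerate(node_labels)}
    w = np.zeros((len(node_labels), len(node_labels)))
    for _, row in df.iterrows():
        i, j = index[row["node_i"]], index[row["node_j"]]
        w[i, j] = w[j, i] = row["weight"]
    return w
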