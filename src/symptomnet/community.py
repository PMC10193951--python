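"""Walktrap community detection on weighted symptom networks.

Short random walks tend to stay inside densely connected groups of nodes;
the Pons-Latapy walktrap algorithm exploits this by agglomerating
communities whose t-step walk profiles are close.  Starting from
singletons, adjacent communities are merged to minimize the increase of
the mean squared walk distance; the reported partition is the dendrogram
cut with maximal Newman modularity.

Random walks need nonnegative weights, so walk probabilities and
modularity use absolute edge weights by default (``negative="absolute"``);
``negative="truncate"`` drops negative edges instead, to probe
sensitivity.  Isolated nodes become singleton communities.  All
tie-breaks are deterministic (lowest node index).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .glasso import NetworkModel

__all__ = ["Partition", "Dendrogram", "walktrap_communities", "modularity"]


@dataclass
class Partition:
    """Node-to-community assignment; community ids contiguous from 1."""

    assignment: np.ndarray
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        ids = np.unique(self.assignment)
        if not np.array_equal(ids, np.arange(1, ids.size + 1)):
            raise ValueError("community ids must be contiguous from 1")
        if not self.node_labels:
            self.node_labels = [f"V{i + 1}" for i in range(self.assignment.size)]

    @property
    def k(self) -> int:
        return int(self.assignment.max())

    @classmethod
    def from_groups(cls, groups, node_labels=None) -> "Partition":
        """Build from a list of node-index collections (one per community)."""
        size = sum(len(g) for g in groups)
        assignment = np.zeros(size, dtype=int)
        for cid, g in enumerate(groups, start=1):
            assignment[list(g)] = cid
        return cls(assignment=assignment, node_labels=list(node_labels or []))

    def members(self, cid: int) -> np.ndarray:
        return np.nonzero(self.assignment == cid)[0]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"node": self.node_labels, "community": self.assignment}
        ).to_csv(path, index=False)


@dataclass
class Dendrogram:
    """Merge sequence: (community_a, community_b, delta_sigma, modularity_after)."""

    merges: list[tuple[frozenset, frozenset, float, float]]
    modularity_by_level: list[float]  # level 0 = all singletons

    def to_json(self, path: str | Path) -> None:
        payload = {
            "merges": [
                {
                    "a": sorted(a),
                    "b": sorted(b),
                    "delta_sigma": ds,
                    "modularity_after": q,
                }
                for a, b, ds, q in self.merges
            ],
            "modularity_by_level": self.modularity_by_level,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _working_weights(net: NetworkModel, negative: str) -> np.ndarray:
    W = net.weights.copy()
    if negative == "absolute":
        W = np.abs(W)
    elif negative == "truncate":
        W = np.where(W > 0, W, 0.0)
    else:
        raise ValueError("negative must be 'absolute' or 'truncate'")
    np.fill_diagonal(W, 0.0)
    return W


def modularity(net: NetworkModel, part: Partition, negative: str = "absolute") -> float:
    """Newman weighted modularity Q = sum_c (e_c - a_c^2) on absolute weights."""
    A = _working_weights(net, negative)
    two_m = A.sum()
    if two_m <= 0:
        raise ValueError("network has zero total weight")
    d = A.sum(axis=1)
    q = 0.0
    for cid in range(1, part.k + 1):
        idx = part.members(cid)
        e_c = A[np.ix_(idx, idx)].sum() / two_m
        a_c = d[idx].sum() / two_m
        q += e_c - a_c * a_c
    return float(q)


def _labels_from_communities(comms, p, node_labels) -> Partition:
    assignment = np.zeros(p, dtype=int)
    ordered = sorted(comms, key=min)
    for cid, members in enumerate(ordered, start=1):
        assignment[sorted(members)] = cid
    return Partition(assignment=assignment, node_labels=list(node_labels))


def walktrap_communities(
    net: NetworkModel, steps: int = 4, negative: str = "absolute"
) -> tuple[Dendrogram, Partition]:
    """Pons-Latapy walktrap with modularity-based cut selection.

    Walk length ``steps`` defaults to 4.  Returns the full dendrogram and
    the partition at the modularity-maximizing level (ties toward fewer
    communities).  An all-zero network yields every node as a singleton.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    A = _working_weights(net, negative)
    p = net.p
    d = A.sum(axis=1)
    active = np.nonzero(d > 0)[0]

    communities: dict[frozenset, dict] = {}
    if active.size:
        # lazy walk (self-loops of weight d(v)): avoids parity artifacts on
        # near-bipartite subgraphs, matching the reference implementation
        P = A[np.ix_(active, active)] / d[active][:, None]
        P = 0.5 * (np.eye(active.size) + P)
        Pt = np.linalg.matrix_power(P, steps)  # t-step walk profiles
        inv_d = 1.0 / d[active]
        pos = {int(v): i for i, v in enumerate(active)}
        for v in active:
            key = frozenset([int(v)])
            communities[key] = {"profile": Pt[pos[int(v)]].copy(), "size": 1}

    def adjacent(c1: frozenset, c2: frozenset) -> bool:
        idx1 = np.fromiter(c1, dtype=int)
        idx2 = np.fromiter(c2, dtype=int)
        return bool(A[np.ix_(idx1, idx2)].sum() > 0)

    def delta_sigma(c1: frozenset, c2: frozenset) -> float:
        n1 = communities[c1]["size"]
        n2 = communities[c2]["size"]
        diff = communities[c1]["profile"] - communities[c2]["profile"]
        r2 = float(np.sum(diff * diff * inv_d))
        return (n1 * n2) / (n1 + n2) / active.size * r2

    singles = [frozenset([int(v)]) for v in range(p) if d[v] == 0]

    def snapshot_partition() -> Partition:
        return _labels_from_communities(
            list(communities.keys()) + singles, p, net.node_labels
        )

    merges = []
    levels = [snapshot_partition()]
    if not communities:  # all-zero network: every node is a singleton
        return Dendrogram(merges=[], modularity_by_level=[0.0]), levels[0]
    while len(communities) > 1:
        keys = sorted(communities.keys(), key=min)  # min(c1) < min(c2) below
        best = None
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                c1, c2 = keys[i], keys[j]
                if not adjacent(c1, c2):
                    continue
                cand = (delta_sigma(c1, c2), min(c1), min(c2))
                if best is None or cand < best[0]:
                    best = (cand, c1, c2)
        if best is None:  # disconnected: no adjacent pair left
            break
        _, c1, c2 = best
        n1, n2 = communities[c1]["size"], communities[c2]["size"]
        merged = c1 | c2
        profile = (
            n1 * communities[c1]["profile"] + n2 * communities[c2]["profile"]
        ) / (n1 + n2)
        ds = delta_sigma(c1, c2)
        del communities[c1], communities[c2]
        communities[merged] = {"profile": profile, "size": n1 + n2}
        part = snapshot_partition()
        merges.append((c1, c2, ds, modularity(net, part, negative)))
        levels.append(part)

    q_by_level = [modularity(net, lv, negative) for lv in levels]
    # maximize modularity; ties toward fewer communities (later level)
    best_level = max(range(len(levels)), key=lambda i: (q_by_level[i], i))
    dendro = Dendrogram(
        merges=[(a, b, ds, q) for (a, b, ds, q) in merges],
        modularity_by_level=q_by_level,
    )
    return dendro, levels[best_level]
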