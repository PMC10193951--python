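"""Node centrality and predictability indices for symptom networks.

Expected influence (EI) is the signed sum of a node's edge weights — the
centrality of record when networks contain negative edges, since it does
not discard sign the way strength does.  Bridge EI restricts the sum to
edges crossing community boundaries and quantifies how strongly a node
couples its own symptom cluster (e.g. PTSD) to the others (e.g.
depression).  Both are one-step indices.

Predictability is the share of a node's variance explained by its network
neighbours: for ordinal items treated numerically it is the R^2 of an OLS
regression on the neighbours; for binary items it is the normalized
classification accuracy (accuracy minus modal baseline, rescaled) of a
logistic regression.  Nodes without neighbours have predictability 0 by
definition.  This is a nodewise-regression index, labelled as such in all
outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LinearRegression, LogisticRegression

from .community import Partition
from .glasso import EDGE_ZERO_TOL, NetworkModel

__all__ = [
    "CentralityTable",
    "expected_influence",
    "standardize",
    "bridge_expected_influence",
    "node_predictability",
    "centrality_table",
]


def expected_influence(net: NetworkModel) -> np.ndarray:
    """One-step expected influence: signed row sums of the weight matrix."""
    return net.weights.sum(axis=1)


def standardize(values) -> np.ndarray:
    """z-scores (sample SD); raises on a constant vector."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to standardize")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / sd


def bridge_expected_influence(
    net: NetworkModel, part: Partition
) -> tuple[np.ndarray, pd.DataFrame]:
    """One-step bridge EI plus the per-target-community decomposition.

    Bridge EI of node v = signed sum of v's edges to nodes outside v's
    community.  The returned frame has one column per community c holding
    each node's signed edge sum into c; a node's own-community column is
    its within-community EI, so bridge EI + within EI = EI exactly.
    """
    if len(part.assignment) != net.p:
        raise ValueError("partition does not cover the network's nodes")
    labels = np.asarray(part.assignment)
    comms = np.unique(labels)
    per_comm = np.stack(
        [net.weights[:, labels == c].sum(axis=1) for c in comms], axis=1
    )
    frame = pd.DataFrame(
        per_comm,
        index=pd.Index(net.node_labels, name="node"),
        columns=[f"community_{c}" for c in comms],
    )
    own = np.searchsorted(comms, labels)
    within = per_comm[np.arange(net.p), own]
    bridge = expected_influence(net) - within
    return bridge, frame


def _neighbors(net: NetworkModel, j: int) -> np.ndarray:
    return np.nonzero(np.abs(net.weights[j]) > EDGE_ZERO_TOL)[0]


def node_predictability(rm, net: NetworkModel) -> np.ndarray:
    """Nodewise predictability in [0, 1] for every item.

    Ordinal items: OLS R^2 on network neighbours, floored at 0.  Binary
    items: (training accuracy - modal baseline) / (1 - modal baseline)
    from a logistic regression, floored at 0.  Isolated nodes score 0.
    Quasi-separated logistic fits fall back to a ridge-penalized fit.
    """
    X = rm.values.astype(float)
    out = np.zeros(net.p)
    for j in range(net.p):
        nb = _neighbors(net, j)
        if nb.size == 0:
            continue
        y = X[:, j]
        Z = X[:, nb]
        binary = len(rm.battery.items[j].levels) == 2
        if not binary:
            r2 = LinearRegression().fit(Z, y).score(Z, y)
            out[j] = max(0.0, r2)
        else:
            classes = np.unique(y)
            base = np.max([np.mean(y == c) for c in classes])
            if base >= 1.0 or classes.size < 2:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("error", ConvergenceWarning)
                try:
                    clf = LogisticRegression(C=np.inf, max_iter=500).fit(Z, y)
                except (ConvergenceWarning, Exception):
                    # separation / non-convergence: weak ridge keeps the fit finite
                    clf = LogisticRegression(C=1e4, max_iter=2000).fit(Z, y)
            acc = clf.score(Z, y)
            out[j] = max(0.0, (acc - base) / (1.0 - base))
    return out


@dataclass
class CentralityTable:
    """Per-node centralities in one frame (raw and z for each index)."""

    frame: pd.DataFrame

    def to_csv(self, path) -> None:
        self.frame.to_csv(path)


def centrality_table(
    net: NetworkModel,
    theoretical: Partition | None = None,
    detected: Partition | None = None,
    rm=None,
) -> CentralityTable:
    """Assemble EI (raw + z), bridge EI per partition scheme, predictability.

    ``theoretical`` is the instrument-defined 2-community split (PTSD vs
    depression); ``detected`` a data-driven partition; either may be None.
    Predictability needs the response matrix and is omitted without it.
    """
    ei = expected_influence(net)
    data = {"ei_raw": ei, "ei_z": standardize(ei)}
    if rm is not None:
        data["predictability"] = node_predictability(rm, net)
    frame = pd.DataFrame(data, index=pd.Index(net.node_labels, name="node"))
    for name, part in (("theoretical", theoretical), ("detected", detected)):
        if part is None:
            continue
        bridge, decomp = bridge_expected_influence(net, part)
        frame[f"bridge_ei_{name}"] = bridge
        for col in decomp.columns:
            frame[f"bridge_ei_{name}_{col}"] = decomp[col].to_numpy()
    return CentralityTable(frame=frame)
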