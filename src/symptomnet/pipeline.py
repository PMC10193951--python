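"""End-to-end estimation: responses -> correlations -> EBIC-glasso network.

A :class:`PipelineConfig` carries the knobs that every resampling layer
(bootstrap, case-dropping, permutation comparison) must replay per
resample: correlation method, EBIC gamma, and the penalty path shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .community import Partition
from .correlation import CorrelationMatrix, build_correlation_matrix
from .glasso import NetworkModel, select_network
from .scales import ResponseMatrix, ScaleBattery

__all__ = ["PipelineConfig", "estimate_network", "theoretical_partition",
           "network_from_correlation_csv"]


@dataclass(frozen=True)
class PipelineConfig:
    """Estimation settings replayed identically across resamples."""

    correlation: str = "polychoric-auto"  # or "spearman" / "pearson"
    gamma: float = 0.5
    path_count: int = 100
    path_ratio: float = 0.01


def estimate_network(rm: ResponseMatrix, config: PipelineConfig | None = None) -> NetworkModel:
    """Correlation matrix + EBIC-glasso selection in one call."""
    config = config or PipelineConfig()
    cm = build_correlation_matrix(rm, method=config.correlation)
    return select_network(
        cm,
        gamma=config.gamma,
        path_count=config.path_count,
        path_ratio=config.path_ratio,
    )


def theoretical_partition(battery: ScaleBattery) -> Partition:
    """Instrument-defined 2-community split: PTSD items vs depression items."""
    assignment = np.array(
        [1 if it.instrument == "PTSD" else 2 for it in battery.items]
    )
    return Partition(assignment=assignment, node_labels=battery.item_ids)


def network_from_correlation_csv(
    path,
    n: int,
    gamma: float = 0.5,
    path_count: int = 100,
    path_ratio: float = 0.01,
) -> NetworkModel:
    """Estimate the network from a published labeled correlation-matrix CSV.

    Entry point for reproducing results from a deposited correlation
    matrix when raw responses are unavailable.
    """
    cm = CorrelationMatrix.from_csv(path, n=n)
    return select_network(cm, gamma=gamma, path_count=path_count, path_ratio=path_ratio)
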