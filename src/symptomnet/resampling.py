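"""Bootstrap accuracy and stability diagnostics for estimated networks.

Three standard checks travel with any regularized symptom network:

* nonparametric bootstrap 95% CIs for edge weights (accuracy) — rows are
  resampled with replacement and the full estimation pipeline is re-run
  per replicate;
* bootstrapped difference tests — two edges (or two node EIs) differ when
  the percentile CI of their replicate-wise difference excludes zero;
* case-dropping bootstrap for centrality stability — increasing shares of
  respondents are dropped, expected influence is re-estimated, and the
  correlation-stability coefficient (CS-C) summarizes how much of the
  sample can be discarded while the EI correlation with the full-sample
  result stays >= 0.7 with 95% probability.  CS-C >= 0.25 is acceptable,
  >= 0.5 preferred.

All intervals are percentile intervals from empirical quantiles with
linear interpolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .centrality import expected_influence
from .correlation import DegenerateMarginError
from .pipeline import PipelineConfig, estimate_network
from .scales import ResponseMatrix

__all__ = [
    "EdgeBootstrapResult",
    "DifferenceTestResult",
    "StabilityCurve",
    "bootstrap_edge_cis",
    "bootstrapped_difference_test",
    "case_dropping_bootstrap",
    "cs_coefficient",
    "percentile_ci",
]

logger = logging.getLogger(__name__)


def percentile_ci(samples: np.ndarray, level: float = 0.95, axis: int = 0):
    """Equal-tailed percentile interval (linear-interpolation quantiles)."""
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(samples, alpha, axis=axis)
    hi = np.quantile(samples, 1.0 - alpha, axis=axis)
    return lo, hi


@dataclass
class EdgeBootstrapResult:
    """Per-edge bootstrap summary plus the raw replicate draws.

    ``edge_replicates`` is (B, n_pairs) over all unordered node pairs in
    ``pair_labels`` order; ``ei_replicates`` is (B, p).  Replicates where a
    resample produced a constant item are dropped (and counted).
    """

    pair_labels: list[tuple[str, str]]
    sample_estimates: np.ndarray
    boot_mean: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    B: int
    seed: int | None
    edge_replicates: np.ndarray
    ei_replicates: np.ndarray
    sample_ei: np.ndarray
    node_labels: list[str] = field(default_factory=list)
    dropped: int = 0

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_i": [a for a, _ in self.pair_labels],
                "node_j": [b for _, b in self.pair_labels],
                "estimate": self.sample_estimates,
                "boot_mean": self.boot_mean,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )


def bootstrap_edge_cis(
    rm: ResponseMatrix,
    config: PipelineConfig | None = None,
    B: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
) -> EdgeBootstrapResult:
    """Nonparametric bootstrap of all edge weights (full pipeline per resample).

    Resamples with a constant item are dropped and logged; more than 10%
    dropped raises.
    """
    config = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    net0 = estimate_network(rm, config)
    iu, ju = np.triu_indices(rm.p, k=1)
    pair_labels = [(net0.node_labels[i], net0.node_labels[j]) for i, j in zip(iu, ju)]
    edge_reps, ei_reps = [], []
    dropped = 0
    for b in range(B):
        rows = rng.integers(0, rm.n, size=rm.n)
        try:
            net = estimate_network(rm.subset(rows), config)
        except DegenerateMarginError as exc:
            dropped += 1
            logger.warning("bootstrap replicate %d dropped: %s", b, exc)
            continue
        edge_reps.append(net.weights[iu, ju])
        ei_reps.append(expected_influence(net))
    if dropped > 0.1 * B:
        raise RuntimeError(
            f"{dropped}/{B} bootstrap replicates dropped (constant items); "
            "sample too sparse for bootstrapping"
        )
    edge_reps = np.asarray(edge_reps)
    ei_reps = np.asarray(ei_reps)
    lo, hi = percentile_ci(edge_reps, level=level)
    return EdgeBootstrapResult(
        pair_labels=pair_labels,
        sample_estimates=net0.weights[iu, ju],
        boot_mean=edge_reps.mean(axis=0),
        ci_lower=lo,
        ci_upper=hi,
        B=B,
        seed=seed,
        edge_replicates=edge_reps,
        ei_replicates=ei_reps,
        sample_ei=expected_influence(net0),
        node_labels=list(net0.node_labels),
        dropped=dropped,
    )


@dataclass
class DifferenceTestResult:
    """Pairwise significance flags: CI of the replicate-wise difference excludes 0."""

    labels: list[str]
    significant: np.ndarray  # symmetric bool matrix, False diagonal

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.significant, index=self.labels, columns=self.labels)


def bootstrapped_difference_test(
    boot: EdgeBootstrapResult, mode: str = "edges", level: float = 0.95
) -> DifferenceTestResult:
    """Bootstrapped difference test over edges or over node EIs."""
    if mode == "edges":
        reps = boot.edge_replicates
        labels = [f"{a}--{b}" for a, b in boot.pair_labels]
    elif mode == "centrality":
        reps = boot.ei_replicates
        labels = list(boot.node_labels)
    else:
        raise ValueError("mode must be 'edges' or 'centrality'")
    k = reps.shape[1]
    sig = np.zeros((k, k), dtype=bool)
    for i in range(k):
        diff = reps[:, [i]] - reps  # (B, k)
        lo, hi = percentile_ci(diff, level=level)
        sig[i] = (lo > 0) | (hi < 0)
    sig &= sig.T  # symmetry guard against quantile asymmetries
    np.fill_diagonal(sig, False)
    return DifferenceTestResult(labels=labels, significant=sig)


@dataclass
class StabilityCurve:
    """Case-dropping record: per drop proportion, the EI correlations."""

    proportions: np.ndarray
    correlations: list[np.ndarray]  # one array of length <= B per proportion
    threshold: float = 0.7
    probability: float = 0.95
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"proportion": p, "correlation": c}
            for p, cs in zip(self.proportions, self.correlations)
            for c in cs
        ]
        return pd.DataFrame(rows)


def case_dropping_bootstrap(
    rm: ResponseMatrix,
    proportions=None,
    B: int = 50,
    seed: int | None = None,
    config: PipelineConfig | None = None,
) -> StabilityCurve:
    """Re-estimate EI on subsamples with increasing shares of cases dropped.

    Default grid: 0.05 to 0.75 in steps of 0.10.  For each proportion, B
    subsamples without replacement; records the Pearson correlation of the
    subsample EI with the full-sample EI.  Levels whose subsample would be
    smaller than p + 5 are skipped with a warning.
    """
    config = config or PipelineConfig()
    if proportions is None:
        proportions = np.arange(0.05, 0.76, 0.10)
    proportions = np.asarray(proportions, dtype=float)
    if np.any(proportions < 0) or np.any(proportions >= 0.95):
        raise ValueError("drop proportions must lie in [0, 0.95)")
    rng = np.random.default_rng(seed)
    ei0 = expected_influence(estimate_network(rm, config))
    kept_props, all_corrs = [], []
    for prop in proportions:
        m = int(round(rm.n * (1.0 - prop)))
        if m < rm.p + 5:
            logger.warning("drop proportion %.2f skipped: subsample %d too small", prop, m)
            continue
        corrs = []
        for _ in range(B):
            rows = rng.choice(rm.n, size=m, replace=False)
            try:
                ei = expected_influence(estimate_network(rm.subset(rows), config))
            except DegenerateMarginError:
                continue
            if np.std(ei) == 0 or np.std(ei0) == 0:
                corrs.append(0.0)
            else:
                corrs.append(float(np.corrcoef(ei0, ei)[0, 1]))
        kept_props.append(prop)
        all_corrs.append(np.asarray(corrs))
    return StabilityCurve(
        proportions=np.asarray(kept_props), correlations=all_corrs, seed=seed
    )


def cs_coefficient(curve: StabilityCurve) -> float:
    """Correlation-stability coefficient of a case-dropping curve.

    Largest drop proportion at which at least ``probability`` (95%) of the
    level's correlations reach ``threshold`` (0.7); 0 when no level
    qualifies.
    """
    if len(curve.proportions) == 0:
        raise ValueError("empty stability curve")
    best = 0.0
    for prop, corrs in zip(curve.proportions, curve.correlations):
        if corrs.size == 0:
            continue
        if np.mean(corrs >= curve.threshold) >= curve.probability:
            best = max(best, float(prop))
    return best
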