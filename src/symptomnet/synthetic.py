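"""Synthetic item-response data with known network structure.

The generative model is the latent Gaussian copula the polychoric stage
assumes: a sparse Gaussian graphical model produces latent multivariate
normal scores with unit variances, and each item discretizes its latent
score at thresholds derived from target category proportions.  This makes
correlation- and network-recovery checks well-posed: the ground-truth
partial correlations are known exactly.

``firefighter_like_design`` packages the study conditions this library
emulates: 25 nodes (5 dichotomous PTSD-screen items, 20 four-level
depression items) with published marginal means/SDs as discretization
targets, n = 1781 respondents, a sparse truth network (density 140/300)
with a dominant edge between the two re-experiencing/avoidance items, and
an optional two-group structure (624 vs 1157) for comparison tests.
Category proportions are moment-matched to each item's target mean and SD
(least squares on the probability simplex).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .glasso import EDGE_ZERO_TOL, NetworkModel, precision_to_partial
from .scales import ResponseMatrix, ScaleBattery, default_battery

__all__ = [
    "GroundTruthNetwork",
    "SyntheticDesign",
    "random_ggm",
    "perturb_edges",
    "match_category_probs",
    "sample_responses",
    "firefighter_like_design",
    "two_group_sample",
    "recovery_metrics",
    "TABLE1_TARGETS",
]

# Published per-item marginal targets (mean, sd) used as discretization goals.
TABLE1_TARGETS: dict[str, tuple[float, float]] = {
    "PCPTSD1": (0.07, 0.26), "PCPTSD2": (0.06, 0.24), "PCPTSD3": (0.09, 0.29),
    "PCPTSD4": (0.07, 0.26), "PCPTSD5": (0.04, 0.20),
    "SDS1": (1.25, 0.49), "SDS2": (2.74, 1.08), "SDS3": (1.08, 0.28),
    "SDS4": (1.51, 0.69), "SDS5": (2.49, 1.17), "SDS6": (2.54, 1.17),
    "SDS7": (1.26, 0.51), "SDS8": (1.16, 0.44), "SDS9": (1.14, 0.38),
    "SDS10": (1.30, 0.55), "SDS11": (2.23, 1.23), "SDS12": (2.53, 1.19),
    "SDS13": (1.21, 0.47), "SDS14": (2.02, 1.16), "SDS15": (1.25, 0.50),
    "SDS16": (2.83, 1.01), "SDS17": (2.25, 1.13), "SDS18": (2.15, 1.13),
    "SDS19": (1.06, 0.29), "SDS20": (2.21, 1.17),
}
# Two-group sizes of the emulated survey (only-child vs non-only-child).
GROUP_SIZES = {"only_child": 624, "non_only_child": 1157}


@dataclass
class GroundTruthNetwork:
    """Known sparse GGM: precision matrix, implied partial weights, provenance."""

    precision: np.ndarray
    weights: np.ndarray
    density: float
    params: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def p(self) -> int:
        return self.precision.shape[0]

    @property
    def covariance(self) -> np.ndarray:
        return np.linalg.inv(self.precision)

    def edge_mask(self) -> np.ndarray:
        return np.abs(self.weights) > EDGE_ZERO_TOL


def _standardize_precision(K: np.ndarray) -> np.ndarray:
    """Rescale so the implied covariance has unit diagonal."""
    Sigma = np.linalg.inv(K)
    s = np.sqrt(np.diag(Sigma))
    Sigma = Sigma / np.outer(s, s)
    K = np.linalg.inv(Sigma)
    return (K + K.T) / 2


def random_ggm(
    p: int,
    density: float,
    weight_range: tuple[float, float] = (0.2, 0.4),
    negative_fraction: float = 0.1,
    seed: int | None = None,
    forced_edges: list[tuple[int, int, float]] | None = None,
) -> GroundTruthNetwork:
    """Random sparse precision matrix with unit-variance implied covariance.

    ``density`` fixes the number of edges; target partial-correlation
    magnitudes are uniform in ``weight_range`` and a ``negative_fraction``
    share flips sign.  The precision matrix is built directly from the
    target partials (unit diagonal, off-diagonals = negated partials);
    when that matrix is not comfortably positive definite all partials
    are shrunk by a common factor until its smallest eigenvalue reaches
    0.05, then the matrix is rescaled to unit implied variances (a
    diagonal rescale, which leaves partial correlations unchanged).
    ``forced_edges`` pins (i, j, value) to exact final partial
    correlations via a fixed-point refinement, e.g. the dominant
    flashback-avoidance edge of the packaged design.
    """
    if not 0 <= density <= 1:
        raise ValueError("density must be in [0, 1]")
    lo, hi = weight_range
    if not (0 <= lo <= hi < 1):
        raise ValueError("weight range must lie within [0, 1)")
    rng = np.random.default_rng(seed)
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    n_edges = int(round(density * len(pairs)))
    chosen = set() if n_edges == 0 else set(
        map(tuple, np.array(pairs)[rng.choice(len(pairs), size=n_edges, replace=False)])
    )
    for i, j, _ in forced_edges or []:
        chosen.add((min(i, j), max(i, j)))
    W = np.zeros((p, p))
    for (i, j) in sorted(chosen):
        w = rng.uniform(lo, hi)
        if rng.random() < negative_fraction:
            w = -w
        W[i, j] = W[j, i] = w
    for i, j, w in forced_edges or []:
        W[i, j] = W[j, i] = w
    # precision from target partials; global shrinkage guarantees PD
    min_eig_floor = 0.05
    lam_max = np.linalg.eigvalsh(W).max() if chosen or forced_edges else 0.0
    if lam_max > 1.0 - min_eig_floor:
        W *= (1.0 - min_eig_floor) / lam_max
    K = np.eye(p) - W
    if np.linalg.eigvalsh(K).min() <= 0:
        raise ValueError("infeasible weight configuration after shrinkage repair")
    K = _standardize_precision(K)
    # pin forced edges to their exact target partial correlations
    for _ in range(100 if forced_edges else 0):
        resid = 0.0
        for i, j, w in forced_edges:
            target = -w * np.sqrt(K[i, i] * K[j, j])
            resid = max(resid, abs(K[i, j] - target))
            K[i, j] = K[j, i] = target
        if np.linalg.eigvalsh(K).min() <= 0:
            raise ValueError("infeasible forced-edge configuration")
        K = _standardize_precision(K)
        if resid < 1e-12:
            break
    if np.linalg.eigvalsh(K).min() <= 0:
        raise ValueError("infeasible weight configuration after forced-edge pinning")
    return GroundTruthNetwork(
        precision=K,
        weights=precision_to_partial(K),
        density=density,
        params={
            "weight_range": weight_range,
            "negative_fraction": negative_fraction,
            "forced_edges": forced_edges or [],
        },
        seed=seed,
    )


def perturb_edges(
    truth: GroundTruthNetwork, edges: list[tuple[int, int]], delta: float
) -> GroundTruthNetwork:
    """Second-group truth: shift named partial correlations by ``delta``."""
    K = truth.precision.copy()
    for i, j in edges:
        shift = delta * np.sqrt(K[i, i] * K[j, j])
        K[i, j] -= shift
        K[j, i] = K[i, j]
    if np.linalg.eigvalsh(K).min() <= 0:
        raise ValueError("edge perturbation breaks positive definiteness")
    K = _standardize_precision(K)
    return GroundTruthNetwork(
        precision=K,
        weights=precision_to_partial(K),
        density=truth.density,
        params={**truth.params, "perturbed_edges": edges, "delta": delta},
        seed=truth.seed,
    )


def match_category_probs(mean: float, sd: float, levels) -> np.ndarray:
    """Category proportions on ``levels`` matching a target mean and SD.

    Binary items are solved exactly from the mean; longer level sets use a
    softmax-parametrized least-squares fit of (mean, sd), with proportions
    floored at 1e-4 so every category stays attainable.
    """
    levels = np.asarray(levels, dtype=float)
    if levels.size == 2:
        q = (mean - levels[0]) / (levels[1] - levels[0])
        q = float(np.clip(q, 1e-4, 1 - 1e-4))
        return np.array([1 - q, q])

    def unpack(theta):
        z = np.concatenate(([0.0], theta))
        e = np.exp(z - z.max())
        return e / e.sum()

    def loss(theta):
        pvec = unpack(theta)
        m = float(pvec @ levels)
        v = float(pvec @ (levels - m) ** 2)
        return (m - mean) ** 2 + (np.sqrt(v) - sd) ** 2

    # multi-start: uniform, bottom-heavy, and a discretized-normal guess
    norm_probs = np.diff(
        stats.norm.cdf(
            np.concatenate(([-np.inf], levels[:-1] + 0.5, [np.inf])),
            loc=mean,
            scale=max(sd, 0.1),
        )
    )
    norm_probs = np.clip(norm_probs, 1e-6, None)
    inits = [
        np.zeros(levels.size - 1),
        -2.0 * np.arange(1, levels.size),
        np.log(norm_probs[1:] / norm_probs[0]),
    ]
    best = min(
        (
            optimize.minimize(
                loss, x0, method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 4000},
            )
            for x0 in inits
        ),
        key=lambda r: r.fun,
    )
    pvec = np.clip(unpack(best.x), 1e-4, None)
    return pvec / pvec.sum()


@dataclass
class SyntheticDesign:
    """Discretization design: battery, per-item category proportions, n."""

    battery: ScaleBattery
    category_probs: list[np.ndarray]
    n: int

    def __post_init__(self) -> None:
        if len(self.category_probs) != self.battery.p:
            raise ValueError("one probability vector per item required")
        for it, pv in zip(self.battery.items, self.category_probs):
            pv = np.asarray(pv, dtype=float)
            if pv.size != len(it.levels) or np.any(pv <= 0) or abs(pv.sum() - 1) > 1e-8:
                raise ValueError(
                    f"item {it.item_id!r}: proportions must be positive and sum to 1"
                )

    def thresholds(self) -> list[np.ndarray]:
        return [
            stats.norm.ppf(np.cumsum(pv)[:-1]) for pv in self.category_probs
        ]

    def target_means(self) -> np.ndarray:
        return np.array(
            [
                float(np.asarray(pv) @ np.asarray(it.levels, dtype=float))
                for it, pv in zip(self.battery.items, self.category_probs)
            ]
        )


def sample_responses(
    truth: GroundTruthNetwork,
    design: SyntheticDesign,
    seed: int | None = None,
    n: int | None = None,
    group: np.ndarray | None = None,
) -> ResponseMatrix:
    """Draw latent MVN scores and discretize them into item responses."""
    if truth.p != design.battery.p:
        raise ValueError("truth and design dimensions differ")
    n = int(n if n is not None else design.n)
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(truth.covariance)
    latent = rng.standard_normal((n, truth.p)) @ L.T
    values = np.empty((n, truth.p), dtype=int)
    for j, (it, tau) in enumerate(zip(design.battery.items, design.thresholds())):
        values[:, j] = np.asarray(it.levels)[np.searchsorted(tau, latent[:, j])]
    return ResponseMatrix(values=values, battery=design.battery, group=group)


def firefighter_like_design(
    n: int = 1781, seed: int | None = 42
) -> tuple[GroundTruthNetwork, SyntheticDesign]:
    """Packaged default emulating the firefighter survey conditions.

    25 nodes with published marginal targets, truth density 140/300, and a
    strong positive edge between the first two PTSD items (the published
    strongest edge, partial correlation 0.46 before rescaling).
    """
    battery = default_battery()
    probs = [
        match_category_probs(*TABLE1_TARGETS[it.item_id], it.levels)
        for it in battery.items
    ]
    truth = random_ggm(
        p=battery.p,
        density=140 / 300,
        weight_range=(0.05, 0.25),
        negative_fraction=0.1,
        seed=seed,
        forced_edges=[(0, 1, 0.46)],
    )
    return truth, SyntheticDesign(battery=battery, category_probs=probs, n=n)


def two_group_sample(
    truth: GroundTruthNetwork,
    design: SyntheticDesign,
    seed: int | None = None,
    group_sizes: dict[str, int] | None = None,
    perturbation: tuple[list[tuple[int, int]], float] | None = None,
) -> ResponseMatrix:
    """Grouped sample; the second group may use a perturbed truth network."""
    sizes = dict(group_sizes or GROUP_SIZES)
    if len(sizes) != 2:
        raise ValueError("exactly two groups required")
    (lab_a, n_a), (lab_b, n_b) = sizes.items()
    rng = np.random.default_rng(seed)
    truth_b = truth
    if perturbation is not None:
        truth_b = perturb_edges(truth, *perturbation)
    rm_a = sample_responses(truth, design, seed=int(rng.integers(2**31)), n=n_a)
    rm_b = sample_responses(truth_b, design, seed=int(rng.integers(2**31)), n=n_b)
    values = np.vstack([rm_a.values, rm_b.values])
    group = np.array([lab_a] * n_a + [lab_b] * n_b)
    return ResponseMatrix(values=values, battery=design.battery, group=group)


def recovery_metrics(truth: GroundTruthNetwork, est: NetworkModel) -> dict[str, float]:
    """Edge sensitivity/specificity, weight correlation, EI rank correlation."""
    if truth.p != est.p:
        raise ValueError("dimension mismatch between truth and estimate")
    iu = np.triu_indices(truth.p, k=1)
    true_edge = np.abs(truth.weights[iu]) > EDGE_ZERO_TOL
    est_edge = np.abs(est.weights[iu]) > EDGE_ZERO_TOL
    sens = (
        float(np.sum(true_edge & est_edge) / np.sum(true_edge))
        if true_edge.any()
        else np.nan
    )
    spec = (
        float(np.sum(~true_edge & ~est_edge) / np.sum(~true_edge))
        if (~true_edge).any()
        else np.nan
    )
    def _safe_corr(a, b, fn):
        if np.std(a) == 0 or np.std(b) == 0:
            return float("nan")  # constant input: correlation undefined
        return float(fn(a, b))

    weight_corr = _safe_corr(
        truth.weights[iu], est.weights[iu], lambda a, b: np.corrcoef(a, b)[0, 1]
    )
    ei_true = truth.weights.sum(axis=1)
    ei_est = est.weights.sum(axis=1)
    ei_rank = _safe_corr(ei_true, ei_est, lambda a, b: stats.spearmanr(a, b).statistic)
    return {
        "edge_sensitivity": sens,
        "edge_specificity": spec,
        "weight_correlation": weight_corr,
        "ei_rank_correlation": ei_rank,
    }
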