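"""Marginal correlation matrices for mixed binary/ordinal item data.

Network estimation consumes a p x p correlation matrix.  For Likert-type
items the convention is the polychoric correlation (tetrachoric when both
items are binary): the items are modelled as discretized latent bivariate
normals, thresholds are set from the marginal cumulative proportions, and
the latent correlation is estimated by one-dimensional maximum likelihood
(the classic two-step estimator).  Spearman and Pearson correlations are
available as cheaper alternatives; the chosen method travels with the
matrix so downstream outputs can record it.

The bivariate normal CDF is evaluated through Owen's T function, which is
fast, vectorized and accurate in the tails.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr, owens_t

__all__ = [
    "CorrelationMatrix",
    "DegenerateMarginError",
    "bivariate_normal_cdf",
    "estimate_pair_polychoric",
    "build_correlation_matrix",
    "nearest_positive_definite",
]

RHO_CLAMP = 0.999  # keeps downstream matrices invertible
_MIN_EIG = 1e-8


class DegenerateMarginError(ValueError):
    """An item column is constant (or a margin has no variation)."""


def bivariate_normal_cdf(h, k, rho: float):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Uses the Owen's-T identity
    ``Phi2(h, k, r) = (Phi(h) + Phi(k))/2 - T(h, a_h) - T(k, a_k) - delta``.
    Accepts array arguments (broadcast) and +-inf thresholds.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    h, k = np.broadcast_arrays(h, k)
    rho = float(np.clip(rho, -RHO_CLAMP, RHO_CLAMP))
    out = np.empty(h.shape, dtype=float)

    # infinite thresholds reduce to univariate margins
    neg_inf = np.isneginf(h) | np.isneginf(k)
    h_inf = np.isposinf(h)
    k_inf = np.isposinf(k)
    finite = ~(neg_inf | h_inf | k_inf)

    out[neg_inf] = 0.0
    out[h_inf & ~neg_inf] = ndtr(k[h_inf & ~neg_inf])
    out[k_inf & ~neg_inf & ~h_inf] = ndtr(h[k_inf & ~neg_inf & ~h_inf])

    hf = h[finite]
    kf = k[finite]
    # nudge exact zeros so the Owen's-T slopes are well defined
    eps = 1e-14
    hf = np.where(hf == 0.0, eps, hf)
    kf = np.where(kf == 0.0, eps, kf)
    s = np.sqrt(1.0 - rho * rho)
    a_h = (kf - rho * hf) / (hf * s)
    a_k = (hf - rho * kf) / (kf * s)
    delta = np.where((hf * kf > 0) | ((hf * kf == 0) & (hf + kf >= 0)), 0.0, 0.5)
    val = 0.5 * (ndtr(hf) + ndtr(kf)) - owens_t(hf, a_h) - owens_t(kf, a_k) - delta
    out[finite] = np.clip(val, 0.0, 1.0)
    return out if out.ndim else float(out)


def _thresholds(column: np.ndarray, levels) -> np.ndarray:
    """Latent-normal cut points from marginal cumulative proportions.

    Returns the p_levels - 1 interior thresholds; empty extreme categories
    get the 0.5/n continuity correction instead of infinite cuts.
    """
    levels = np.asarray(levels)
    n = column.size
    counts = np.array([(column == lv).sum() for lv in levels], dtype=float)
    if counts.max() == n:
        raise DegenerateMarginError("constant column")
    cum = np.cumsum(counts)[:-1] / n
    cum = np.clip(cum, 0.5 / n, 1.0 - 0.5 / n)
    return stats.norm.ppf(cum)


def _table(x: np.ndarray, y: np.ndarray, levels_x, levels_y) -> np.ndarray:
    ix = np.searchsorted(np.asarray(levels_x), x)
    iy = np.searchsorted(np.asarray(levels_y), y)
    table = np.zeros((len(levels_x), len(levels_y)))
    np.add.at(table, (ix, iy), 1.0)
    return table


def _cell_probabilities(tau_x: np.ndarray, tau_y: np.ndarray, rho: float) -> np.ndarray:
    ax = np.concatenate(([-np.inf], tau_x, [np.inf]))
    ay = np.concatenate(([-np.inf], tau_y, [np.inf]))
    F = bivariate_normal_cdf(ax[:, None], ay[None, :], rho)
    return np.diff(np.diff(F, axis=0), axis=1)


def polychoric_loglik(table: np.ndarray, tau_x, tau_y, rho: float) -> float:
    """Multinomial log-likelihood of the contingency table at latent rho."""
    probs = np.clip(_cell_probabilities(tau_x, tau_y, rho), 1e-300, None)
    return float(np.sum(table * np.log(probs)))


def estimate_pair_polychoric(x, y, levels_x, levels_y) -> float:
    """Two-step ML polychoric correlation of two ordinal columns.

    Thresholds come from the marginal cumulative proportions; the latent
    correlation maximizes the bivariate-normal cell likelihood over
    (-1, 1).  The estimate is clamped to [-0.999, 0.999]; boundary
    solutions (empty off-diagonal cells, duplicated items) land at the
    clamp.  Both-binary input makes this the tetrachoric correlation.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    tau_x = _thresholds(x, levels_x)
    tau_y = _thresholds(y, levels_y)
    table = _table(x, y, levels_x, levels_y)

    def neg_ll(rho: float) -> float:
        return -polychoric_loglik(table, tau_x, tau_y, rho)

    res = optimize.minimize_scalar(
        neg_ll, bounds=(-RHO_CLAMP, RHO_CLAMP), method="bounded",
        options={"xatol": 1e-6},
    )
    rho = float(res.x)
    # boundary solutions (empty off-diagonal cells): snap to the clamp
    for bound in (-RHO_CLAMP, RHO_CLAMP):
        if neg_ll(bound) <= res.fun:
            rho = bound
    return float(np.clip(rho, -RHO_CLAMP, RHO_CLAMP))


@dataclass
class CorrelationMatrix:
    """Symmetric unit-diagonal correlation matrix with provenance.

    ``method`` records how the matrix was built ("polychoric-auto",
    "spearman", "pearson", or "file" for matrices loaded from disk);
    ``n`` is the sample size it summarizes (needed by EBIC).
    """

    values: np.ndarray
    method: str
    n: int
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p = self.values.shape[0]
        if self.values.shape != (p, p):
            raise ValueError("correlation matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not self.labels:
            self.labels = [f"V{i + 1}" for i in range(p)]

    @property
    def p(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, n: int, method: str = "file") -> "CorrelationMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(
            values=df.to_numpy(dtype=float),
            method=method,
            n=n,
            labels=[str(c) for c in df.columns],
        )


def build_correlation_matrix(rm, method: str = "polychoric-auto") -> CorrelationMatrix:
    """Pairwise correlation matrix of a ResponseMatrix, PD-repaired.

    ``method``: "polychoric-auto" (polychoric/tetrachoric by item level
    sets), "spearman", or "pearson".  Constant items raise
    :class:`DegenerateMarginError` naming the item.
    """
    X = rm.values
    p = rm.p
    for j, it in enumerate(rm.battery.items):
        if np.all(X[:, j] == X[0, j]):
            raise DegenerateMarginError(f"item {it.item_id!r} is constant")
    if method == "pearson":
        M = np.corrcoef(X, rowvar=False)
    elif method == "spearman":
        M, _ = stats.spearmanr(X)
        M = np.atleast_2d(M)
    elif method == "polychoric-auto":
        M = np.eye(p)
        for i in range(p):
            for j in range(i + 1, p):
                r = estimate_pair_polychoric(
                    X[:, i], X[:, j],
                    rm.battery.items[i].levels, rm.battery.items[j].levels,
                )
                M[i, j] = M[j, i] = r
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    off = ~np.eye(p, dtype=bool)
    M[off] = np.clip(M[off], -RHO_CLAMP, RHO_CLAMP)
    np.fill_diagonal(M, 1.0)
    if np.linalg.eigvalsh(M).min() < _MIN_EIG:
        M = nearest_positive_definite(M)
    return CorrelationMatrix(values=M, method=method, n=rm.n, labels=rm.battery.item_ids)


def nearest_positive_definite(
    m: np.ndarray, min_eig: float = _MIN_EIG, tol: float = 1e-7, max_iter: int = 200
) -> np.ndarray:
    """Nearest unit-diagonal positive-definite matrix (Higham projections).

    Alternating projections with Dykstra's correction between the PSD cone
    (eigenvalues floored at ``min_eig``) and the unit-diagonal affine set.
    Already-PD input is returned unchanged.
    """
    m = np.asarray(m, dtype=float)
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("input must be symmetric")
    if np.linalg.eigvalsh(m).min() >= min_eig and np.allclose(np.diag(m), 1.0):
        return m.copy()
    Y = m.copy()
    ds = np.zeros_like(m)
    for _ in range(max_iter):
        R = Y - ds
        w, V = np.linalg.eigh((R + R.T) / 2)
        X = (V * np.maximum(w, min_eig)) @ V.T
        ds = X - R
        Y_next = X.copy()
        np.fill_diagonal(Y_next, 1.0)
        if np.max(np.abs(Y_next - Y)) < tol:
            Y = Y_next
            break
        Y = Y_next
    Y = (Y + Y.T) / 2
    w, V = np.linalg.eigh(Y)
    if w.min() < min_eig:  # final eigenvalue floor after the diagonal reset
        Y = (V * np.maximum(w, min_eig)) @ V.T
        d = np.sqrt(np.diag(Y))
        Y = Y / np.outer(d, d)
        Y = (Y + Y.T) / 2
        np.fill_diagonal(Y, 1.0)
    return Y
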