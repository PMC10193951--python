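"""Sparse Gaussian graphical model estimation: glasso + EBIC selection.

The network of interest is a regularized partial-correlation network: the
precision matrix Theta of a Gaussian graphical model is estimated by the
graphical lasso,

    max_Theta  log det Theta - tr(S Theta) - lam * sum_{i != j} |Theta_ij|,

over a decreasing penalty path, and the extended Bayesian Information
Criterion

    EBIC = -2 loglik + E log n + 4 E gamma log p

selects the penalty (gamma = 0.5 by default, the conservative convention
for symptom networks).  Edge weights are the partial correlations
``-Theta_ij / sqrt(Theta_ii Theta_jj)``.

The solver is the Friedman-Hastie-Tibshirani block coordinate descent on
the covariance (one lasso subproblem per column), with warm starts along
the path.  The diagonal is unpenalized, so the fitted covariance W
satisfies ``W_ii = S_ii`` and the off-diagonal KKT conditions
``|S_ij - W_ij| <= lam`` (zero entries) and
``S_ij - W_ij + lam sign(Theta_ij) = 0`` (active entries).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

try:  # hot loops compile with numba when present; pure-python fallback otherwise
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

__all__ = [
    "PenaltyPath",
    "NetworkModel",
    "GlassoError",
    "penalty_grid",
    "glasso_solve",
    "kkt_residual",
    "gaussian_loglik",
    "ebic_score",
    "select_network",
    "precision_to_partial",
]

EDGE_ZERO_TOL = 1e-10  # |Theta_ij| below this counts as no edge


class GlassoError(RuntimeError):
    pass


@dataclass(frozen=True)
class PenaltyPath:
    """Strictly decreasing positive penalty values."""

    lambdas: tuple[float, ...]

    def __post_init__(self) -> None:
        lam = tuple(float(v) for v in self.lambdas)
        if len(lam) < 1 or any(v <= 0 for v in lam):
            raise ValueError("penalties must be positive")
        if any(b >= a for a, b in zip(lam, lam[1:])):
            raise ValueError("penalties must be strictly decreasing")
        object.__setattr__(self, "lambdas", lam)

    @property
    def count(self) -> int:
        return len(self.lambdas)

    @property
    def ratio(self) -> float:
        return self.lambdas[-1] / self.lambdas[0]


def penalty_grid(cm, count: int = 100, ratio: float = 0.01) -> PenaltyPath:
    """Log-spaced penalty path from lam_max = max |off-diagonal| down to ratio*lam_max."""
    S = cm.values if hasattr(cm, "values") else np.asarray(cm, dtype=float)
    if count < 2 or not (0 < ratio < 1):
        raise ValueError("need count >= 2 and 0 < ratio < 1")
    off = S[~np.eye(S.shape[0], dtype=bool)]
    lam_max = float(np.max(np.abs(off)))
    if lam_max <= 0:
        raise GlassoError("all off-diagonal correlations are zero; no signal to regularize")
    lams = np.exp(np.linspace(np.log(lam_max), np.log(ratio * lam_max), count))
    return PenaltyPath(lambdas=tuple(lams))


@njit(cache=True)
def _bcd_sweeps(S, lam, W, B, tol, max_sweeps):  # pragma: no cover - numba kernel
    p = S.shape[0]
    pm1 = p - 1
    W11 = np.empty((pm1, pm1))
    s12 = np.empty(pm1)
    beta = np.empty(pm1)
    c = np.empty(pm1)
    for sweep in range(max_sweeps):
        max_delta = 0.0
        for j in range(p):
            # gather the j-th column subproblem
            a = 0
            for i in range(p):
                if i == j:
                    continue
                b = 0
                for l in range(p):
                    if l == j:
                        continue
                    W11[a, b] = W[i, l]
                    b += 1
                s12[a] = S[i, j]
                beta[a] = B[i, j]
                a += 1
            for k in range(pm1):
                c[k] = 0.0
                for l in range(pm1):
                    c[k] += W11[k, l] * beta[l]
            # lasso coordinate descent: 0.5 b'W11 b - s12'b + lam |b|_1
            for _inner in range(1000):
                dmax = 0.0
                for k in range(pm1):
                    old = beta[k]
                    r = s12[k] - (c[k] - W11[k, k] * old)
                    if r > lam:
                        new = (r - lam) / W11[k, k]
                    elif r < -lam:
                        new = (r + lam) / W11[k, k]
                    else:
                        new = 0.0
                    d = new - old
                    if d != 0.0:
                        for l in range(pm1):
                            c[l] += W11[l, k] * d
                        beta[k] = new
                        ad = abs(d)
                        if ad > dmax:
                            dmax = ad
                if dmax < tol * 0.1:
                    break
            # write back w12 = W11 @ beta (tracked in c) and the coefficients
            a = 0
            for i in range(p):
                if i == j:
                    continue
                d = abs(W[i, j] - c[a])
                if d > max_delta:
                    max_delta = d
                W[i, j] = c[a]
                W[j, i] = c[a]
                B[i, j] = beta[a]
                a += 1
        if max_delta < tol:
            return sweep + 1
    return -1


def _recover_precision(W: np.ndarray, B: np.ndarray) -> np.ndarray:
    p = W.shape[0]
    Theta = np.zeros_like(W)
    for j in range(p):
        idx = np.arange(p) != j
        beta = B[idx, j]
        w12 = W[idx, j]
        theta_jj = 1.0 / (W[j, j] - w12 @ beta)
        Theta[j, j] = theta_jj
        Theta[idx, j] = -beta * theta_jj
    Theta = (Theta + Theta.T) / 2
    Theta[np.abs(Theta) < EDGE_ZERO_TOL] = 0.0
    return Theta


def _solve_warm(S, lam, W, B, tol=1e-7, max_sweeps=500):
    sweeps = _bcd_sweeps(S, lam, W, B, tol, max_sweeps)
    if sweeps < 0:
        resid = kkt_residual(S, _recover_precision(W, B), lam)
        if resid > 1e-4:
            raise GlassoError(
                f"glasso did not converge at lam={lam:.4g} (KKT residual {resid:.2e})"
            )
    return _recover_precision(W, B)


def glasso_solve(cm, lam: float, tol: float = 1e-7, max_sweeps: int = 500) -> np.ndarray:
    """Precision matrix of the graphical lasso at one penalty value.

    Input must be a positive-definite correlation/covariance matrix (run
    PD repair first); ``lam >= 0``.  Raises :class:`GlassoError` on
    non-convergence, carrying the KKT residual.
    """
    S = np.asarray(cm.values if hasattr(cm, "values") else cm, dtype=float)
    if np.linalg.eigvalsh(S).min() <= 0:
        raise GlassoError("input matrix is not positive definite")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if lam == 0:
        return np.linalg.inv(S)
    W = S.copy()
    B = np.zeros_like(S)
    return _solve_warm(S, lam, W, B, tol=tol, max_sweeps=max_sweeps)


def kkt_residual(S: np.ndarray, Theta: np.ndarray, lam: float) -> float:
    """Maximum violation of the glasso stationarity conditions.

    For W = Theta^{-1}: zero off-diagonals require |S_ij - W_ij| <= lam;
    active ones require S_ij - W_ij + lam sign(Theta_ij) = 0.  Returns the
    largest excess over those bounds (0 at an exact solution).
    """
    W = np.linalg.inv(Theta)
    p = S.shape[0]
    off = ~np.eye(p, dtype=bool)
    G = S - W
    active = off & (np.abs(Theta) > EDGE_ZERO_TOL)
    inactive = off & ~active
    r_inactive = np.max(np.abs(G[inactive]) - lam, initial=0.0)
    r_active = np.max(np.abs(G[active] + lam * np.sign(Theta[active])), initial=0.0)
    r_diag = float(np.max(np.abs(np.diag(G))))
    return float(max(r_inactive, r_active, r_diag))


def gaussian_loglik(cm, prec: np.ndarray, n: int) -> float:
    """Profile Gaussian log-likelihood (n/2)(log det Theta - tr(S Theta)); constants dropped."""
    S = np.asarray(cm.values if hasattr(cm, "values") else cm, dtype=float)
    sign, logdet = np.linalg.slogdet(prec)
    if sign <= 0:
        raise GlassoError("precision matrix is not positive definite")
    return float(n / 2.0 * (logdet - np.sum(S * prec)))


def ebic_score(loglik: float, E: int, n: int, p: int, gamma: float = 0.5) -> float:
    """Extended BIC: -2 loglik + E log n + 4 E gamma log p."""
    if E < 0 or n < 1 or p < 1:
        raise ValueError("need E >= 0, n >= 1, p >= 1")
    return -2.0 * loglik + E * np.log(n) + 4.0 * E * gamma * np.log(p)


def _edge_count(Theta: np.ndarray) -> int:
    off = np.triu(np.abs(Theta) > EDGE_ZERO_TOL, k=1)
    return int(off.sum())


def precision_to_partial(prec: np.ndarray) -> np.ndarray:
    """Partial correlations -Theta_ij / sqrt(Theta_ii Theta_jj); zero diagonal."""
    prec = np.asarray(prec, dtype=float)
    d = np.diag(prec)
    if np.any(d <= 0):
        raise ValueError("precision diagonal must be positive")
    s = 1.0 / np.sqrt(d)
    w = -prec * np.outer(s, s)
    np.fill_diagonal(w, 0.0)
    return (w + w.T) / 2


@dataclass
class NetworkModel:
    """Estimated symptom network: signed partial-correlation weights + metadata.

    ``weights`` is symmetric with zero diagonal; ``precision`` is the
    selected precision matrix (None for networks loaded from a published
    weight matrix); the remaining fields record the EBIC selection.
    """

    weights: np.ndarray
    precision: np.ndarray | None = None
    lambda_selected: float | None = None
    ebic_value: float | None = None
    n: int | None = None
    gamma: float | None = None
    node_labels: list[str] = field(default_factory=list)
    path_report: pd.DataFrame | None = None  # lambda, edges, ebic per path point

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        p = self.weights.shape[0]
        if self.weights.shape != (p, p) or not np.allclose(
            self.weights, self.weights.T, atol=1e-8
        ):
            raise ValueError("weights must be square symmetric")
        if not np.allclose(np.diag(self.weights), 0.0):
            raise ValueError("weights diagonal must be zero")
        if not self.node_labels:
            self.node_labels = [f"V{i + 1}" for i in range(p)]

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    @property
    def edge_count(self) -> int:
        return int(np.triu(np.abs(self.weights) > EDGE_ZERO_TOL, k=1).sum())

    @property
    def potential_edge_count(self) -> int:
        return self.p * (self.p - 1) // 2

    def edges(self) -> pd.DataFrame:
        """Nonzero unordered edges sorted by |weight| descending."""
        iu, ju = np.triu_indices(self.p, k=1)
        w = self.weights[iu, ju]
        keep = np.abs(w) > EDGE_ZERO_TOL
        df = pd.DataFrame(
            {
                "node_i": [self.node_labels[i] for i in iu[keep]],
                "node_j": [self.node_labels[j] for j in ju[keep]],
                "weight": w[keep],
            }
        )
        return df.reindex(df["weight"].abs().sort_values(ascending=False).index).reset_index(
            drop=True
        )

    @classmethod
    def from_weights(cls, weights, node_labels=None, n: int | None = None) -> "NetworkModel":
        """Wrap a published/external partial-correlation weight matrix."""
        w = np.asarray(weights, dtype=float).copy()
        np.fill_diagonal(w, 0.0)
        return cls(weights=w, node_labels=list(node_labels or []), n=n)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.weights, index=self.node_labels, columns=self.node_labels).to_csv(
            path
        )

    def meta_json(self) -> str:
        return json.dumps(
            {
                "lambda": self.lambda_selected,
                "ebic": self.ebic_value,
                "n": self.n,
                "gamma": self.gamma,
                "edges": self.edge_count,
                "p": self.p,
            }
        )


def select_network(
    cm,
    n: int | None = None,
    gamma: float = 0.5,
    path: PenaltyPath | None = None,
    path_count: int = 100,
    path_ratio: float = 0.01,
) -> NetworkModel:
    """Fit the glasso along the penalty path and return the EBIC minimizer.

    Edge count E is the number of nonzero unordered off-diagonal pairs of
    the estimated precision.  Ties in EBIC resolve toward larger lambda
    (the sparser model).  Warm starts run from the sparse end of the path.
    """
    S = np.asarray(cm.values if hasattr(cm, "values") else cm, dtype=float)
    if n is None:
        n = getattr(cm, "n", None)
    if n is None:
        raise ValueError("sample size n is required for EBIC")
    labels = list(getattr(cm, "labels", []) or [])
    p = S.shape[0]
    if np.linalg.eigvalsh(S).min() <= 0:
        raise GlassoError("correlation matrix is not positive definite")
    if path is None:
        path = penalty_grid(S, count=path_count, ratio=path_ratio)
    W = S.copy()
    B = np.zeros_like(S)
    best = None
    report = []
    for lam in path.lambdas:  # decreasing: first minimum wins ties -> sparser
        Theta = _solve_warm(S, lam, W, B)
        E = _edge_count(Theta)
        ll = gaussian_loglik(S, Theta, n)
        score = ebic_score(ll, E, n, p, gamma)
        report.append((lam, E, score))
        if best is None or score < best[0]:
            best = (score, lam, Theta, E)
    score, lam_sel, Theta, E = best
    return NetworkModel(
        weights=precision_to_partial(Theta),
        precision=Theta,
        lambda_selected=float(lam_sel),
        ebic_value=float(score),
        n=int(n),
        gamma=float(gamma),
        node_labels=labels,
        path_report=pd.DataFrame(report, columns=["lambda", "edges", "ebic"]),
    )
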