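"""Graphical lasso solver, EBIC selection, and partial-correlation weights."""

import numpy as np
import pytest
from scipy import optimize

import symptomnet as sn
from symptomnet.glasso import GlassoError, _edge_count, kkt_residual
from symptomnet.synthetic import _standardize_precision


def random_correlation(p, n, seed):
    rng = np.random.default_rng(seed)
    return np.corrcoef(rng.standard_normal((n, p)), rowvar=False)


def generic_optimizer_oracle(S, lam):
    """Penalized-likelihood maximization via a generic convex optimizer.

    Parametrizes Theta through its Cholesky factor and hands the smooth+L1
    objective to Nelder-Mead polish on top of BFGS on a smoothed |.|;
    independent of the coordinate-descent implementation.
    """
    p = S.shape[0]
    tril = np.tril_indices(p)

    def unpack(theta):
        L = np.zeros((p, p))
        L[tril] = theta
        return L @ L.T

    def objective(theta, eps=1e-10):
        T = unpack(theta)
        sign, logdet = np.linalg.slogdet(T)
        if sign <= 0:
            return 1e10
        smooth_l1 = np.sum(np.sqrt(T[~np.eye(p, dtype=bool)] ** 2 + eps))
        return -(logdet - np.sum(S * T)) + lam * smooth_l1

    x0 = np.linalg.cholesky(np.linalg.inv(S))[tril]
    res = optimize.minimize(objective, x0, method="Nelder-Mead",
                            options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12})
    return unpack(res.x)


class TestPenaltyGrid:
    def test_log_spacing_example(self):
        S = np.eye(2)
        S[0, 1] = S[1, 0] = 0.5
        path = sn.penalty_grid(S, count=3, ratio=0.01)
        assert np.allclose(path.lambdas, (0.5, 0.05, 0.005))

    def test_identity_matrix_rejected(self):
        with pytest.raises(GlassoError):
            sn.penalty_grid(np.eye(3), count=10, ratio=0.01)

    def test_full_grid_endpoints(self):
        S = random_correlation(6, 500, 0)
        lam_max = np.abs(S - np.diag(np.diag(S))).max()
        path = sn.penalty_grid(S, count=100, ratio=0.01)
        assert path.count == 100
        assert path.lambdas[0] == pytest.approx(lam_max)
        assert path.lambdas[-1] == pytest.approx(0.01 * lam_max)
        assert all(a > b for a, b in zip(path.lambdas, path.lambdas[1:]))


class TestGlassoSolve:
    def test_full_shrinkage_gives_diagonal_precision(self):
        S = random_correlation(5, 400, 1)
        lam = np.abs(S - np.diag(np.diag(S))).max() + 1e-9
        Theta = sn.glasso_solve(S, lam)
        assert _edge_count(Theta) == 0
        assert np.allclose(np.diag(Theta), 1.0 / np.diag(S))

    def test_identity_with_zero_penalty(self):
        assert np.allclose(sn.glasso_solve(np.eye(4), 0.0), np.eye(4))

    @pytest.mark.parametrize("lam", [0.05, 0.1, 0.25])
    def test_three_node_agrees_with_generic_optimizer(self, lam):
        S = np.array([[1.0, 0.5, 0.4], [0.5, 1.0, 0.2], [0.4, 0.2, 1.0]])
        ours = sn.glasso_solve(S, lam)
        oracle = generic_optimizer_oracle(S, lam)
        assert np.max(np.abs(ours - oracle)) < 1e-3
        assert kkt_residual(S, ours, lam) <= 1e-4

    def test_matches_sklearn_on_random_problem(self):
        from sklearn.covariance import graphical_lasso

        S = random_correlation(8, 2000, 3)
        _, prec = graphical_lasso(S, alpha=0.1, tol=1e-10, max_iter=2000)
        assert np.max(np.abs(sn.glasso_solve(S, 0.1) - prec)) < 2e-4

    def test_non_pd_input_rejected(self):
        m = np.full((3, 3), 0.9)
        np.fill_diagonal(m, 1.0)
        m[0, 1] = m[1, 0] = -0.9
        with pytest.raises(GlassoError):
            sn.glasso_solve(m, 0.1)


class TestInformationCriteria:
    def test_loglik_identity_closed_form(self):
        p = 4
        assert sn.gaussian_loglik(np.eye(p), np.eye(p), n=2) == pytest.approx(-p)

    def test_loglik_hand_value(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        prec = np.linalg.inv(S)
        expected = 50 * (-np.log(0.75) - 2)
        assert sn.gaussian_loglik(S, prec, n=100) == pytest.approx(expected)
        assert expected == pytest.approx(-85.616, abs=5e-3)

    def test_inverse_is_the_maximizer(self):
        S = random_correlation(4, 300, 5)
        best = sn.gaussian_loglik(S, np.linalg.inv(S), n=100)
        rng = np.random.default_rng(0)
        for _ in range(10):
            d = rng.normal(scale=0.02, size=(4, 4))
            prec = np.linalg.inv(S) + (d + d.T) / 2
            if np.linalg.eigvalsh(prec).min() <= 0:
                continue
            assert sn.gaussian_loglik(S, prec, n=100) <= best + 1e-12

    def test_ebic_reductions_and_hand_value(self):
        assert sn.ebic_score(-3.0, E=0, n=50, p=4) == 6.0
        assert sn.ebic_score(-3.0, E=2, n=50, p=4, gamma=0.0) == pytest.approx(
            6.0 + 2 * np.log(50)
        )
        val = sn.ebic_score(-100.0, E=10, n=1000, p=25, gamma=0.5)
        assert val == pytest.approx(333.455, abs=5e-3)


class TestSelectNetwork:
    def test_empty_truth_recovers_empty_network(self):
        rng = np.random.default_rng(0)
        S = np.corrcoef(rng.standard_normal((1000, 6)), rowvar=False)
        net = sn.select_network(S, n=1000)
        assert net.edge_count == 0

    def test_chain_recovery_at_large_n(self):
        # two-edge chain over 4 nodes, true partial correlations 0.4
        K = np.eye(4)
        for i, j in [(0, 1), (1, 2)]:
            K[i, j] = K[j, i] = -0.4
        K = _standardize_precision(K)
        L = np.linalg.cholesky(np.linalg.inv(K))
        Z = np.random.default_rng(2).standard_normal((5000, 4)) @ L.T
        net = sn.select_network(np.corrcoef(Z, rowvar=False), n=5000)
        edges = {tuple(sorted(e)) for e in zip(*np.nonzero(np.triu(net.weights, 1)))}
        assert edges == {(0, 1), (1, 2)}
        # and across other draws the chain is always recovered, with at most
        # weak incidental extras
        for seed in range(3, 6):
            Z = np.random.default_rng(seed).standard_normal((5000, 4)) @ L.T
            net = sn.select_network(np.corrcoef(Z, rowvar=False), n=5000)
            assert abs(net.weights[0, 1]) > 0.3 and abs(net.weights[1, 2]) > 0.3
            extras = np.abs(np.triu(net.weights, 1)).copy()
            extras[0, 1] = extras[1, 2] = 0.0
            assert extras.max() < 0.1

    def test_edge_count_bounded_and_kkt_satisfied(self, study_sample):
        _, _, rm = study_sample
        cm = sn.build_correlation_matrix(rm.subset(np.arange(600)), method="spearman")
        net = sn.select_network(cm)
        assert net.edge_count <= net.potential_edge_count == 300
        assert kkt_residual(cm.values, net.precision, net.lambda_selected) <= 1e-4

    def test_edge_count_monotone_along_path(self):
        truth = sn.random_ggm(8, 0.3, seed=9)
        L = np.linalg.cholesky(truth.covariance)
        Z = np.random.default_rng(9).standard_normal((2000, 8)) @ L.T
        net = sn.select_network(np.corrcoef(Z, rowvar=False), n=2000)
        edges = net.path_report["edges"].to_numpy()
        assert np.all(np.diff(edges) >= 0)  # lambda decreases along the path

    def test_false_positive_rate_controlled(self):
        # sparse truth (10% density), gamma 0.5, n = 5000: FPR <= 0.05 over
        # 20 replicates.  At moderate densities the path-constrained EBIC
        # selection admits weak spurious edges and FPR plateaus instead of
        # vanishing; the conservative-γ guarantee concerns sparse graphs.
        truth = sn.random_ggm(10, 0.1, seed=4)
        L = np.linalg.cholesky(truth.covariance)
        mask = truth.edge_mask()[np.triu_indices(10, 1)]
        fprs = []
        for rep in range(20):
            Z = np.random.default_rng(100 + rep).standard_normal((5000, 10)) @ L.T
            net = sn.select_network(np.corrcoef(Z, rowvar=False), n=5000)
            est = np.abs(net.weights[np.triu_indices(10, 1)]) > 1e-10
            fprs.append(np.sum(est & ~mask) / np.sum(~mask))
        assert np.mean(fprs) <= 0.05


class TestPrecisionToPartial:
    def test_diagonal_precision_gives_zero_weights(self):
        assert np.allclose(sn.precision_to_partial(np.diag([2.0, 3.0, 1.0])), 0.0)

    def test_two_by_two_formula(self):
        prec = np.array([[2.0, -1.0], [-1.0, 2.0]])
        assert sn.precision_to_partial(prec)[0, 1] == pytest.approx(0.5)

    def test_agrees_with_residual_regression_oracle(self):
        # partial corr of (i, j) = correlation of the residuals from
        # regressing each on the remaining variables (computed from the
        # covariance by Schur complements, independent of the precision route)
        rng = np.random.default_rng(12)
        A = rng.normal(size=(5, 5))
        prec = A @ A.T + 5 * np.eye(5)
        Sigma = np.linalg.inv(prec)
        W = sn.precision_to_partial(prec)
        for i in range(5):
            for j in range(i + 1, 5):
                rest = [k for k in range(5) if k not in (i, j)]
                Srr = Sigma[np.ix_(rest, rest)]
                Sir = Sigma[np.ix_([i, j], rest)]
                cond = Sigma[np.ix_([i, j], [i, j])] - Sir @ np.linalg.solve(Srr, Sir.T)
                r = cond[0, 1] / np.sqrt(cond[0, 0] * cond[1, 1])
                assert W[i, j] == pytest.approx(r, abs=1e-10)

    def test_nonpositive_diagonal_rejected(self):
        with pytest.raises(ValueError):
            sn.precision_to_partial(np.array([[1.0, 0.0], [0.0, -1.0]]))
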