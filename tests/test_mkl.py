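"""Dual solver, decision function, calibration, grid search."""

import numpy as np
import pytest
from scipy.optimize import minimize

from mklfuse import (
    KernelMatrix,
    KernelSpec,
    TrainConfig,
    combine_kernels,
    compute_gram,
    decision_scores,
    fit_platt,
    grid_search,
    solve_dual,
)


def qp_oracle(K, y, C):
    """Generic constrained QP reference for the SVM dual (SLSQP)."""
    n = len(y)
    Q = np.outer(y, y) * K
    fun = lambda a: 0.5 * a @ Q @ a - a.sum()
    jac = lambda a: Q @ a - 1.0
    cons = [{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}]
    best = np.inf
    for s in range(3):
        x0 = np.clip(np.random.default_rng(s).uniform(0, min(C, 1.0), n), 0, C)
        res = minimize(
            fun, x0, jac=jac, bounds=[(0.0, C)] * n, constraints=cons,
            method="SLSQP", options={"maxiter": 1000, "ftol": 1e-14},
        )
        if res.success:
            best = min(best, res.fun)
    assert np.isfinite(best)
    return best


class TestSolveDual:
    def test_two_symmetric_points_closed_form(self):
        # x = +1 (y=+1), x = -1 (y=-1), linear kernel: alpha = (1/2, 1/2),
        # b = 0, f(x) = x
        K = np.array([[1.0, -1.0], [-1.0, 1.0]])
        y = np.array([1.0, -1.0])
        sol = solve_dual(K, y, C=10.0)
        np.testing.assert_allclose(sol.alpha, [0.5, 0.5], atol=1e-8)
        assert sol.b == pytest.approx(0.0, abs=1e-8)
        s = decision_scores(sol, np.array([[0.0, 0.0]]), y)
        assert s[0] == pytest.approx(0.0, abs=1e-8)  # boundary at x=0
        s = decision_scores(sol, np.array([[2.0, -2.0]]), y)
        assert s[0] == pytest.approx(2.0, abs=1e-7)

    def test_label_flip_negates_scores_not_alpha(self, rng):
        A = rng.standard_normal((10, 12))
        K = A @ A.T
        y = np.array([1.0] * 5 + [-1.0] * 5)
        Kc = K[:6] * 1.0
        s1 = solve_dual(K, y, 1.0)
        s2 = solve_dual(K, -y, 1.0)
        np.testing.assert_allclose(s1.alpha, s2.alpha, atol=1e-8)
        assert s2.b == pytest.approx(-s1.b, abs=1e-8)
        f1 = decision_scores(s1, Kc, y)
        f2 = decision_scores(s2, Kc, -y)
        np.testing.assert_allclose(f2, -f1, atol=1e-7)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_qp_oracle_small_instances(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(4, 13))
        A = rng.standard_normal((n, n + 2))
        K = A @ A.T
        y = np.concatenate([np.ones(n // 2), -np.ones(n - n // 2)])
        rng.shuffle(y)
        C = [0.1, 1.0, 10.0][trial % 3]
        sol = solve_dual(K, y, C, tol=1e-8)
        assert abs(sol.alpha @ y) <= 1e-8
        assert np.all(sol.alpha >= -1e-12) and np.all(sol.alpha <= C + 1e-12)
        ref = qp_oracle(K, y, C)
        assert sol.objective <= ref + 1e-5

    def test_margin_one_at_free_support_vectors(self, rng):
        n = 40
        X = rng.standard_normal((n, 3))
        y = np.where(X[:, 0] + 0.5 * rng.standard_normal(n) > 0, 1.0, -1.0)
        if len(np.unique(y)) < 2:
            pytest.skip("degenerate draw")
        K = compute_gram(X, X, KernelSpec("rbf", 0.5))
        sol = solve_dual(K, y, C=1.0, tol=1e-10)
        free = (sol.alpha > 1e-6) & (sol.alpha < 1.0 - 1e-6)
        scores = decision_scores(sol, K.values, y)
        assert free.any()
        np.testing.assert_allclose(np.abs(scores[free]), 1.0, atol=1e-6)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes|labels"):
            solve_dual(np.eye(4), np.ones(4), 1.0)

    def test_duplicate_test_row_scores_identically(self, rng):
        X = rng.standard_normal((20, 4))
        y = np.where(rng.random(20) < 0.5, 1.0, -1.0)
        if len(np.unique(y)) < 2:
            pytest.skip("degenerate draw")
        spec = KernelSpec("rbf", 0.3)
        K = compute_gram(X, X, spec)
        sol = solve_dual(K, y, 1.0)
        Kc = compute_gram(X[[3]], X, spec)
        s = decision_scores(sol, Kc.values, y)
        full = decision_scores(sol, K.values, y)
        assert s[0] == pytest.approx(full[3], abs=1e-12)


class TestUnitWeightReduction:
    @pytest.mark.parametrize("seed", range(10))
    def test_mkl_with_unit_weight_equals_single_kernel(self, seed):
        rng = np.random.default_rng(seed)
        n = 24
        ids = list(range(n))
        kernels = []
        for mod in range(3):
            X = rng.standard_normal((n, 5))
            kernels.append(
                compute_gram(X, X, KernelSpec("rbf", 0.4), ids, ids, f"m{mod}")
            )
        y = np.concatenate([np.ones(n // 2), -np.ones(n // 2)])
        rng.shuffle(y)
        for m in range(3):
            w = np.zeros(3)
            w[m] = 1.0
            combined = combine_kernels(kernels, w)
            s_mkl = solve_dual(combined.values, y, 1.0, tol=1e-10)
            s_single = solve_dual(kernels[m].values, y, 1.0, tol=1e-10)
            np.testing.assert_allclose(s_mkl.alpha, s_single.alpha, atol=1e-8)
            assert s_mkl.b == pytest.approx(s_single.b, abs=1e-8)
            sc1 = decision_scores(s_mkl, combined.values, y)
            sc2 = decision_scores(s_single, kernels[m].values, y)
            np.testing.assert_allclose(sc1, sc2, atol=1e-8)


class TestPlatt:
    def test_separable_scores_calibrate_monotone(self, rng):
        scores = np.concatenate([rng.normal(2, 0.3, 40), rng.normal(-2, 0.3, 40)])
        y = np.concatenate([np.ones(40), -np.ones(40)])
        sig = fit_platt(scores, y)
        assert sig.A < 0
        p = sig.prob(scores)
        assert np.all((p > 0) & (p < 1))
        assert np.all(p[:40] >= 0.5) and np.all(p[40:] < 0.5)
        grid = sig.prob(np.linspace(-3, 3, 50))
        assert np.all(np.diff(grid) > 0)  # strictly increasing in score

    def test_degenerate_scores_fall_back_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            sig = fit_platt(np.zeros(10), np.array([1, -1] * 5))
        assert sig.degenerate

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            fit_platt(np.arange(5.0), np.ones(5))


class TestGridSearch:
    def _kernels(self, rng, n, informative_mod=0):
        ids = list(range(n))
        y = np.concatenate([np.ones(n // 2), -np.ones(n // 2)])
        rng.shuffle(y)
        kernels = []
        for mod in range(3):
            X = rng.standard_normal((n, 6))
            if mod == informative_mod:
                X[:, :3] += 1.2 * (y == 1)[:, None]
            Z = (X - X.mean(0)) / X.std(0)
            kernels.append(compute_gram(Z, Z, KernelSpec("rbf", 1 / 12), ids, ids))
        return kernels, y

    def test_single_modality_returns_unit_weight(self, rng):
        kernels, y = self._kernels(rng, 40)
        cfg = TrainConfig(c_grid=(0.1, 1.0), weight_stride=0.5, seed=0)
        res = grid_search(kernels[:1], y, cfg)
        np.testing.assert_array_equal(res.weights, [1.0])

    def test_returned_pair_attains_table_max(self, rng):
        kernels, y = self._kernels(rng, 30)
        cfg = TrainConfig(c_grid=(0.1, 1.0, 10.0), weight_stride=0.5, seed=1)
        res = grid_search(kernels, y, cfg)
        assert res.mean_auc == pytest.approx(res.table["mean_auc"].max())

    def test_weight_concentrates_on_informative_modality(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(3000 + seed)
            kernels, y = self._kernels(rng, 60, informative_mod=0)
            cfg = TrainConfig(c_grid=(0.1, 1.0, 10.0), weight_stride=0.2, seed=seed)
            res = grid_search(kernels, y, cfg)
            if res.weights[0] >= max(res.weights[1], res.weights[2]):
                hits += 1
        assert hits >= 8

    def test_single_class_inner_fold_errors(self, rng):
        n = 8
        ids = list(range(n))
        K = compute_gram(
            rng.standard_normal((n, 3)), rng.standard_normal((n, 3)),
            KernelSpec("linear"), ids, ids,
        )
        y = np.array([1.0] * 7 + [-1.0])
        with pytest.raises(ValueError):
            grid_search([K], y, TrainConfig(inner_folds=5))
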