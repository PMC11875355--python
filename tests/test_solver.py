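import numpy as np
import pytest
from dataclasses import replace

from nfrfs import (
    SolverConfig,
    SolverState,
    fit,
    kkt_residual,
    l2p_norm_p,
    make_synthetic,
    minmax_normalize,
    objective,
    rank_features,
    residual_weights,
    update_H,
    update_W,
)
from nfrfs.graph import projected_sq_distances, update_similarity
from nfrfs.solver import _w_update_factors, objective_terms


def small_instance(n=6, d=4, l=2, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.0, 1.0, size=(n, d))
    W = rng.uniform(0.1, 1.0, size=(d, l))
    H = rng.uniform(0.1, 1.0, size=(l, d))
    return X, W, H


class TestL2pNorm:
    def test_zero_matrix(self):
        for p in (0.1, 0.5, 1, 2):
            assert l2p_norm_p(np.zeros((3, 4)), p) == 0.0

    def test_hand_computed_p1(self):
        M = np.array([[3.0, 4.0], [5.0, 12.0]])
        assert l2p_norm_p(M, 1) == pytest.approx(18.0)  # row norms 5 and 13

    def test_p2_is_squared_frobenius(self, rng):
        for _ in range(50):
            M = rng.normal(size=(4, 5))
            assert l2p_norm_p(M, 2) == pytest.approx(np.sum(M**2), abs=1e-12)

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            l2p_norm_p(np.ones((2, 2)), 2.5)
        with pytest.raises(ValueError):
            l2p_norm_p(np.ones((2, 2)), 0.0)


class TestResidualWeights:
    def test_p2_gives_unit_weights(self):
        X, W, H = small_instance()
        np.testing.assert_array_equal(residual_weights(X, W, H, p=2.0, eps=1e-12), 1.0)

    def test_hand_computed_p1(self):
        # residual row of norm 2 at p=1: u = (1/2) * 2^{-1} = 0.25
        X = np.array([[2.0, 0.0], [0.0, 2.0]])
        W = np.zeros((2, 1))
        H = np.zeros((1, 2))
        u = residual_weights(X, W, H, p=1.0, eps=0.0 + 1e-300)
        np.testing.assert_allclose(u, 0.25)

    def test_zero_residual_row_is_finite(self):
        X = np.ones((3, 2))
        W = np.array([[1.0], [0.0]])
        H = np.array([[1.0, 1.0]])  # XWH = X exactly
        u = residual_weights(X, W, H, p=1.0, eps=1e-12)
        assert np.all(np.isfinite(u)) and np.all(u > 0)
        assert u[0] == pytest.approx(0.5 * (1e-12) ** (-0.5))


class TestObjective:
    def test_vanishing_residual_leaves_graph_scale_term(self):
        X = np.ones((6, 4))
        W = np.zeros((4, 2))
        W[0, 0] = 1.0
        W[1, 1] = 1.0
        H = np.array([[1.0, 1, 1, 1], [0.0, 0, 0, 0]])  # XWH = X
        cfg = SolverConfig(alpha=0.0, beta=0.0, k=2, l=2)
        graph = update_similarity(np.ones((6, 6)) - np.eye(6), k=2)
        state = SolverState(W=W, H=H, graph=graph, U_diag=np.ones(6))
        expected = graph.gamma * np.sum(graph.S**2)
        assert objective(X, state, cfg) == pytest.approx(expected, abs=1e-10)

    def test_redundancy_term_vanishes_for_disjoint_rows(self):
        # one nonzero per row => all distinct-row inner products are zero
        W = np.diag([1.0, 2.0, 3.0])
        row_sum = W.sum(axis=0)
        assert row_sum @ row_sum - np.sum(W * W) == pytest.approx(0.0)

    def test_redundancy_term_double_loop_oracle(self, rng):
        W = rng.uniform(size=(5, 3))
        direct = sum(
            W[i] @ W[j] for i in range(5) for j in range(5) if i != j
        )
        cfg = SolverConfig(alpha=0, beta=1.0, l=3, variant="base")
        X = rng.uniform(size=(4, 5))
        state = SolverState(W=W, H=rng.uniform(size=(3, 5)), graph=None, U_diag=np.ones(4))
        terms = objective_terms(X, state, cfg)
        assert terms["redundancy"] == pytest.approx(direct, abs=1e-10)


def w_update_oracle(X, W, H, u, S, cfg):
    """Elementwise re-implementation of the multiplicative W rule with loops."""
    n, d = X.shape
    l = W.shape[1]
    U = np.diag(u)
    S_hat = (S + S.T) / 2
    D = np.diag(S_hat.sum(axis=1))
    ones = np.ones((d, d))
    num = X.T @ U @ X @ H.T + cfg.alpha * X.T @ S_hat @ X @ W + cfg.beta * W + cfg.lam * W
    den = (
        X.T @ U @ X @ W @ H @ H.T
        + cfg.alpha * X.T @ D @ X @ W
        + cfg.beta * W @ W.T @ W
        + cfg.lam * ones @ W
    )
    out = np.empty_like(W)
    for i in range(d):
        for j in range(l):
            out[i, j] = W[i, j] * num[i, j] / (den[i, j] + cfg.eps)
    return out


class TestUpdateW:
    def test_matches_independent_elementwise_oracle(self):
        X, W, H = small_instance(n=6, d=4, l=2, seed=3)
        cfg = SolverConfig(alpha=0.7, beta=0.3, p=0.5, k=2, lam=10.0, l=2)
        graph = update_similarity(projected_sq_distances(X, W), k=2)
        u = residual_weights(X, W, H, cfg.p, cfg.eps)
        expected = w_update_oracle(X, W, H, u, graph.S, cfg)
        got = update_W(X, W, H, u, graph, cfg)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_fixed_point_unchanged(self):
        X, W, H = small_instance()
        cfg = SolverConfig(alpha=0.0, beta=0.0, lam=0.0, l=2, variant="base")
        u = np.ones(X.shape[0])
        num, den = _w_update_factors(X, W, H, u, None, cfg)
        # force numerator == denominator: the multiplicative ratio is then ~1
        W_fp = W.copy()
        got = W_fp * num / (num + cfg.eps)
        np.testing.assert_allclose(got, W_fp, rtol=1e-9)

    def test_nonnegativity_preserved(self):
        for seed in range(20):
            X, W, H = small_instance(seed=seed)
            cfg = SolverConfig(alpha=1.0, beta=1.0, p=0.5, k=2, lam=100.0, l=2)
            graph = update_similarity(projected_sq_distances(X, W), k=2)
            u = residual_weights(X, W, H, cfg.p, cfg.eps)
            W2 = update_W(X, W, H, u, graph, cfg)
            assert np.all(W2 >= 0)


class TestUpdateH:
    def test_fixed_point_unchanged(self):
        X = np.ones((4, 3))
        W = np.ones((3, 2)) / 3
        # H solving the weighted LS exactly: XWH = X has a consistent solution
        H = np.ones((2, 3)) * 0.5
        cfg = SolverConfig(l=2)
        u = np.ones(4)
        H2 = update_H(X, W, H, u, cfg)
        np.testing.assert_allclose(H2, H, rtol=1e-6)

    def test_nonnegativity_preserved(self):
        for seed in range(20):
            X, W, H = small_instance(seed=seed)
            u = residual_weights(X, W, H, 0.5, 1e-12)
            H2 = update_H(X, W, H, u, SolverConfig(l=2))
            assert np.all(H2 >= 0)

    def test_descends_weighted_least_squares(self):
        # with W fixed, iterating the H rule non-increases Tr((X-XWH)^T U (X-XWH))
        X, W, H = small_instance(n=8, d=5, l=2, seed=11)
        cfg = SolverConfig(l=2)
        u = np.abs(np.random.default_rng(5).normal(size=8)) + 0.1
        def wls(Hc):
            R = X - X @ W @ Hc
            return float(np.sum(u * np.einsum("ij,ij->i", R, R)))
        prev = wls(H)
        for _ in range(50):
            H = update_H(X, W, H, u, cfg)
            cur = wls(H)
            assert cur <= prev + 1e-10 * abs(prev)
            prev = cur


class TestFit:
    def test_single_iteration_contract(self, bench):
        cfg = SolverConfig(max_iter=1, l=3)
        state = fit(bench, cfg)
        assert state.iterations_run == 1
        assert not state.converged
        assert len(state.objective_history) == 1

    def test_seed_determinism_bitwise(self, bench, small_config):
        s1 = fit(bench, small_config)
        s2 = fit(bench, small_config)
        np.testing.assert_array_equal(s1.W, s2.W)
        np.testing.assert_array_equal(s1.H, s2.H)
        assert s1.objective_history == s2.objective_history

    def test_objective_monotone_on_benchmark(self, bench):
        cfg = SolverConfig(alpha=1, beta=1, p=0.5, k=5, lam=1e4, l=5, max_iter=60, tol=0.0, seed=0)
        state = fit(bench, cfg)
        h = np.asarray(state.objective_history)
        assert np.all(np.diff(h) <= 1e-8 * np.abs(h[:-1]))

    def test_w_h_stay_nonnegative(self, bench, small_config):
        state = fit(bench, small_config)
        assert np.all(state.W >= 0) and np.all(state.H >= 0)

    def test_rejects_negative_input(self):
        dm = make_synthetic(n=20, d_informative=3, d_noise=3, c=2, seed=0)  # unnormalized
        with pytest.raises(ValueError, match="nonnegative"):
            fit(dm, SolverConfig(l=2, k=3))

    def test_p2_matches_frobenius_control_path(self):
        """A p=2 run equals an independently coded F-norm loop bitwise."""
        data = minmax_normalize(make_synthetic(n=50, d_informative=5, d_noise=35, c=2, seed=4))
        cfg = SolverConfig(alpha=1.0, beta=1.0, p=2.0, k=5, lam=100.0, l=3, max_iter=25, tol=0.0, seed=9)
        state = fit(data, cfg)

        # control path: plain weighted-Frobenius loop with U == I throughout
        X = data.X
        rng = np.random.default_rng(cfg.seed)
        W = rng.uniform(0.1, 1.0, size=(X.shape[1], cfg.l))
        H = rng.uniform(0.1, 1.0, size=(cfg.l, X.shape[1]))
        graph = update_similarity(projected_sq_distances(X, W), cfg.k, cfg.alpha)
        ones_u = np.ones(X.shape[0])
        for _ in range(cfg.max_iter):
            W = update_W(X, W, H, ones_u, graph, cfg)
            H = update_H(X, W, H, ones_u, cfg)
            graph = update_similarity(projected_sq_distances(X, W), cfg.k, cfg.alpha)
        np.testing.assert_array_equal(state.W, W)
        np.testing.assert_array_equal(state.H, H)

    def test_variant_base_ignores_alpha(self, bench):
        cfg1 = SolverConfig(alpha=0.1, variant="base", l=3, max_iter=10, seed=1)
        cfg2 = SolverConfig(alpha=99.0, variant="base", l=3, max_iter=10, seed=1)
        np.testing.assert_array_equal(fit(bench, cfg1).W, fit(bench, cfg2).W)

    def test_variant_base_graph_keeps_initial_graph(self, bench):
        cfg = SolverConfig(variant="base_graph", l=3, max_iter=5, seed=1, k=5)
        state = fit(bench, cfg)
        rng = np.random.default_rng(1)
        W0 = rng.uniform(0.1, 1.0, size=(bench.d, 3))
        expected = update_similarity(projected_sq_distances(bench.X, W0), 5, 1.0)
        np.testing.assert_array_equal(state.graph.S, expected.S)

    def test_kkt_residual_decreases_with_iterations(self, bench):
        cfg1 = SolverConfig(l=3, max_iter=20, tol=0.0, seed=0)
        cfg2 = replace(cfg1, max_iter=400)
        r1 = kkt_residual(bench.X, fit(bench, cfg1), cfg1)
        r2 = kkt_residual(bench.X, fit(bench, cfg2), cfg2)
        assert r2 < r1


class TestRankFeatures:
    @staticmethod
    def _state(W):
        return SolverState(W=W, H=np.zeros((W.shape[1], W.shape[0])), graph=None, U_diag=np.ones(2))

    def test_sorts_by_row_norm_descending(self):
        W = np.array([[0.0, 0.0], [3.0, 0.0], [1.0, 0.0]])
        r = rank_features(self._state(W), 2)
        np.testing.assert_array_equal(r.order, [1, 2, 0])
        np.testing.assert_array_equal(r.selected, [1, 2])

    def test_tie_break_by_index(self):
        W = np.ones((4, 2))
        r = rank_features(self._state(W), 4)
        np.testing.assert_array_equal(r.order, [0, 1, 2, 3])

    def test_scale_invariant_ordering(self, rng):
        W = rng.uniform(size=(6, 3))
        r1 = rank_features(self._state(W), 3)
        r2 = rank_features(self._state(W * 17.3), 3)
        np.testing.assert_array_equal(r1.order, r2.order)

    def test_m_out_of_range(self):
        with pytest.raises(ValueError):
            rank_features(self._state(np.ones((4, 2))), 5)
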