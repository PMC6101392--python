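"""Sparse squared-hinge solver: closed forms, grid oracles, descent."""

import numpy as np
import pytest

from conftest import make_matrix, random_instance
from genesel import llsvm
from genesel.llsvm import (
    SolverConfig,
    decision_score,
    fit,
    objective,
    predict,
    solve_subproblem,
    subproblem_derivatives,
)
from oracles import grid_min_objective, subproblem_grid_min


class TestObjective:
    def test_zero_weights(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(size=(6, 3)), [1, 1, 1, -1, -1, -1])
        # all margins are 1 at w=0, so the loss is C*n
        assert objective(np.zeros(3), m, C=2.5) == pytest.approx(2.5 * 6)

    def test_hand_value_1d(self, two_point_1d):
        assert objective(np.array([0.75]), two_point_1d, C=1.0) == pytest.approx(0.875)

    def test_inactive_set_leaves_only_penalty(self):
        m = make_matrix([[2.0], [-2.0]], [1, -1])
        # margins y*w*x = 2 >= 1 for w=1: empty active set
        assert objective(np.array([1.0]), m, C=10.0) == pytest.approx(1.0)

    def test_dimension_mismatch(self, two_point_1d):
        with pytest.raises(ValueError, match="gene count"):
            objective(np.zeros(2), two_point_1d, C=1.0)


class TestSubproblemDerivatives:
    def test_empty_active_set_floor(self):
        m = make_matrix([[2.0], [-2.0]], [1, -1])
        d1, d2 = subproblem_derivatives(0, np.array([1.0]), m, C=1.0)
        assert d1 == 0.0
        assert d2 == 1e-12

    def test_hand_values_1d(self, two_point_1d):
        d1, d2 = subproblem_derivatives(0, np.zeros(1), two_point_1d, C=1.0)
        assert d1 == pytest.approx(-4.0)
        assert d2 == pytest.approx(4.0)

    def test_linear_in_C(self):
        rng = np.random.default_rng(1)
        m = random_instance(rng)
        w = rng.normal(scale=0.1, size=m.n_genes)
        a1, a2 = subproblem_derivatives(0, w, m, C=1.0)
        b1, b2 = subproblem_derivatives(0, w, m, C=2.0)
        assert b1 == pytest.approx(2 * a1)
        assert b2 == pytest.approx(2 * a2)


class TestSolveSubproblem:
    @pytest.mark.parametrize(
        "w_j,d1,d2,expected",
        [
            (0.0, 0.0, 1.0, 0.0),
            (0.0, -3.0, 2.0, 1.0),
            (0.5, 0.2, 1.0, -0.5),  # snap to zero
        ],
    )
    def test_known_minimizers(self, w_j, d1, d2, expected):
        assert solve_subproblem(w_j, d1, d2) == pytest.approx(expected)

    def test_matches_grid_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            w_j = rng.uniform(-2, 2)
            d1 = rng.uniform(-5, 5)
            # keep the minimizer inside the oracle's scan range
            d2 = rng.uniform(0.8, 10)
            z = solve_subproblem(w_j, d1, d2)
            _, g_grid = subproblem_grid_min(w_j, d1, d2)
            g_closed = abs(w_j + z) + d1 * z + 0.5 * d2 * z**2
            assert g_closed <= g_grid + 1e-12
            assert g_grid - g_closed <= 1e-4

    def test_nonpositive_curvature_rejected(self):
        with pytest.raises(ValueError):
            solve_subproblem(0.0, 1.0, 0.0)


class TestFit:
    def test_1d_closed_form(self, two_point_1d):
        """min_w w + 2(1-w)^2 has the closed-form solution w* = 3/4."""
        model = fit(two_point_1d, C=1.0, cfg=SolverConfig(tol=1e-10))
        assert model.weights[0] == pytest.approx(0.75, abs=1e-8)
        assert model.objective_trace[-1] == pytest.approx(0.875, abs=1e-8)

    def test_tiny_C_gives_exact_zero(self, separable):
        model = fit(separable, C=1e-9)
        assert model.nnz() == 0

    def test_monotone_trace_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            m = random_instance(rng)
            model = fit(m, C=float(rng.choice([0.1, 1.0, 10.0])),
                        cfg=SolverConfig(max_sweeps=50))
            trace = np.array(model.objective_trace)
            assert np.all(np.diff(trace) <= 1e-10)
            assert trace[-1] <= objective(np.zeros(m.n_genes), m, model.penalty) + 1e-12

    @pytest.mark.parametrize("C", [0.1, 1.0, 10.0])
    def test_matches_grid_oracle_tiny(self, C):
        """Fitted objective agrees with dense grid search over the weight
        cube on tiny convex instances."""
        rng = np.random.default_rng(4)
        for _ in range(3):
            n = int(rng.integers(2, 6))
            d = int(rng.integers(1, 4))
            X = rng.normal(size=(n, d))
            y = np.ones(n, dtype=int)
            y[: n // 2] = -1
            m = make_matrix(X, y)
            model = fit(m, C=C, cfg=SolverConfig(tol=1e-10, max_sweeps=5000))
            oracle = grid_min_objective(X, y.astype(float), C)
            assert model.objective_trace[-1] <= oracle + 1e-4

    def test_optimality_certificate(self):
        """At convergence each coordinate satisfies the subdifferential
        condition: |d1| <= 1 at zero weights, d1 + sign(w_j) ~ 0 otherwise."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            m = random_instance(rng)
            model = fit(m, C=1.0, cfg=SolverConfig(tol=1e-10, max_sweeps=5000))
            assert model.converged
            for j in range(m.n_genes):
                d1, d2 = subproblem_derivatives(j, model.weights, m, 1.0)
                tol = 1e-6 * max(d2, 1.0)
                if model.weights[j] == 0.0:
                    assert abs(d1) <= 1.0 + tol
                else:
                    assert abs(d1 + np.sign(model.weights[j])) <= tol

    def test_separable_training_accuracy(self, separable):
        model = fit(separable, C=1.0)
        preds = predict(model, separable.values)
        assert np.mean(preds == separable.labels) == 1.0

    def test_warm_start_does_not_worsen(self, separable):
        cold = fit(separable, C=1.0)
        warm = fit(separable, C=1.0, w0=cold.weights)
        assert warm.objective_trace[-1] <= cold.objective_trace[-1] + 1e-9

    def test_one_class_rejected(self):
        m = make_matrix(np.zeros((3, 2)), [1, 1, 1])
        with pytest.raises(Exception, match="both classes"):
            fit(m, C=1.0)


class TestPredict:
    def test_sign_decision(self):
        model = llsvm.LinearModel(np.array([1.0, -1.0]), 1.0, 0, [], True)
        assert predict(model, np.array([[2.0, 0.5]]))[0] == 1

    def test_zero_weights_tie_to_plus_one(self):
        model = llsvm.LinearModel(np.zeros(2), 1.0, 0, [], True)
        preds = predict(model, np.random.default_rng(0).normal(size=(5, 2)))
        assert np.all(preds == 1)
        assert np.all(decision_score(model, np.ones((2, 2))) == 0)

    def test_positive_scaling_invariance(self):
        rng = np.random.default_rng(6)
        w = rng.normal(size=4)
        X = rng.normal(size=(10, 4))
        a = predict(llsvm.LinearModel(w, 1.0, 0, [], True), X)
        b = predict(llsvm.LinearModel(3.7 * w, 1.0, 0, [], True), X)
        np.testing.assert_array_equal(a, b)
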