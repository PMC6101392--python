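"""L1-regularized squared-hinge linear SVM trained by cyclic coordinate descent.

The model minimizes

    f(w) = ||w||_1 + C * sum_{i in I(w)} b_i(w)^2,
    b_i(w) = 1 - y_i w.x_i,      I(w) = {i : b_i(w) > 0},

a squared hinge loss with an L1 penalty: C > 0 trades loss against
sparsity, and as C shrinks more weights are driven exactly to zero.  The
decision function is the bias-free sign(w.x).  Per-gene |w_j| is the
feature-importance score consumed by recursive elimination.

Training cycles through coordinates in fixed ascending order.  For each
coordinate the one-variable piecewise-quadratic subproblem

    min_z |w_j + z| + L_j'(0;w) z + 1/2 L_j''(0;w) z^2

is solved in closed form (a soft-thresholded Newton step), where

    L_j'(0;w)  = -2C sum_{i in I(w)} y_i x_{ij} b_i(w)
    L_j''(0;w) = max(2C sum_{i in I(w)} x_{ij}^2, 1e-12).

Because the loss is only once differentiable the Newton step can
overshoot, so each step is safeguarded by Armijo backtracking on the true
objective; the per-sweep objective trace is therefore non-increasing by
construction.  Margins b_i are maintained incrementally (O(n_samples) per
coordinate) and recomputed in full periodically to bound float drift.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .dataset import LabeledMatrix

HESSIAN_FLOOR = 1e-12


@dataclass
class SolverConfig:
    """Coordinate-descent controls.

    max_sweeps
        Upper bound on full passes over the coordinates.
    tol
        Stop when the largest per-coordinate step magnitude within a sweep
        falls below this.
    linesearch_beta, linesearch_sigma
        Armijo backtracking: try steps beta^t * z (t = 0..max_backtracks)
        and accept the first satisfying the sufficient-decrease condition
        with slope fraction sigma.
    hessian_floor
        Lower bound on the second derivative of the smooth part.
    recompute_every
        Fully recompute cached margins every this many sweeps.
    """

    max_sweeps: int = 1000
    tol: float = 1e-6
    linesearch_beta: float = 0.5
    linesearch_sigma: float = 0.01
    max_backtracks: int = 30
    hessian_floor: float = HESSIAN_FLOOR
    recompute_every: int = 50


@dataclass
class LinearModel:
    """Fitted sparse linear model: weights, penalty, and solver trace."""

    weights: np.ndarray
    penalty: float
    n_sweeps_run: int
    objective_trace: list[float]
    converged: bool
    gene_ids: list[str] | None = None

    def nnz(self) -> int:
        return int(np.count_nonzero(self.weights))

    def to_json(self) -> str:
        return json.dumps(
            {
                "gene_ids": self.gene_ids,
                "weights": [float(w) for w in self.weights],
                "C": self.penalty,
                "n_sweeps_run": self.n_sweeps_run,
                "converged": self.converged,
                "final_objective": self.objective_trace[-1]
                if self.objective_trace
                else None,
            }
        )


def _margins(w: np.ndarray, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    return 1.0 - y * (X @ w)


def objective(w: np.ndarray, m: LabeledMatrix, C: float) -> float:
    """f(w) = ||w||_1 + C * sum of squared positive margins."""
    w = np.asarray(w, dtype=float)
    if w.shape[0] != m.n_genes:
        raise ValueError(f"weight length {w.shape[0]} != gene count {m.n_genes}")
    b = _margins(w, m.values, m.labels.astype(float))
    return float(np.abs(w).sum() + C * np.sum(np.maximum(b, 0.0) ** 2))


def subproblem_derivatives(
    j: int, w: np.ndarray, m: LabeledMatrix, C: float
) -> tuple[float, float]:
    """First and floored second derivative of the smooth loss at z = 0,
    restricted to the active set (samples with positive margin)."""
    y = m.labels.astype(float)
    b = _margins(np.asarray(w, dtype=float), m.values, y)
    active = b > 0
    xj = m.values[active, j]
    d1 = -2.0 * C * float(np.dot(y[active] * xj, b[active]))
    d2 = max(2.0 * C * float(np.dot(xj, xj)), HESSIAN_FLOOR)
    return d1, d2


def solve_subproblem(w_j: float, d1: float, d2: float) -> float:
    """Exact minimizer of |w_j + z| + d1*z + (d2/2)*z^2.

    Subdifferential optimality of the piecewise quadratic gives three
    cases: step to the positive branch, step to the negative branch, or
    snap the coordinate to zero.
    """
    if d2 <= 0:
        raise ValueError("second derivative must be positive")
    if d1 + 1.0 <= d2 * w_j:
        return -(d1 + 1.0) / d2
    if d1 - 1.0 >= d2 * w_j:
        return -(d1 - 1.0) / d2
    return -w_j


def fit(
    m: LabeledMatrix,
    C: float,
    cfg: SolverConfig | None = None,
    w0: np.ndarray | None = None,
) -> LinearModel:
    """Train by cyclic coordinate descent with Armijo-backtracked steps.

    Coordinates are visited in fixed ascending order each sweep; the run
    stops when the largest accepted step in a sweep is below ``cfg.tol``
    or after ``cfg.max_sweeps`` sweeps.  ``w0`` enables warm starts across
    elimination iterations.
    """
    cfg = cfg or SolverConfig()
    if C <= 0:
        raise ValueError("penalty C must be > 0")
    m.require_two_classes()
    X = m.values
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in training matrix")
    y = m.labels.astype(float)
    n, d = X.shape
    # row j of YXT is the j-th gene column times the labels, contiguous for
    # fast per-coordinate access; note (y*x)^2 = x^2 since y = +-1
    YXT = np.ascontiguousarray((X * y[:, None]).T)
    w = np.zeros(d) if w0 is None else np.asarray(w0, dtype=float).copy()
    if w.shape[0] != d:
        raise ValueError("w0 length does not match gene count")
    b = _margins(w, X, y)
    loss = C * float(np.sum(np.maximum(b, 0.0) ** 2))
    beta, sigma = cfg.linesearch_beta, cfg.linesearch_sigma
    trace: list[float] = []
    converged = False
    sweeps = 0
    for sweep in range(cfg.max_sweeps):
        sweeps = sweep + 1
        max_step = 0.0
        for j in range(d):
            yxj = YXT[j]
            active = b > 0.0
            bact = b[active]
            v = yxj[active]
            d1 = -2.0 * C * float(np.dot(v, bact))
            d2 = max(2.0 * C * float(np.dot(v, v)), cfg.hessian_floor)
            z = solve_subproblem(w[j], d1, d2)
            if z == 0.0:
                continue
            # sufficient-decrease slope: directional derivative upper bound
            gamma = d1 * z + abs(w[j] + z) - abs(w[j])
            step = z
            scale = 1.0
            accepted = False
            for _ in range(cfg.max_backtracks + 1):
                b_new = b - yxj * step
                loss_new = C * float(np.sum(np.maximum(b_new, 0.0) ** 2))
                delta = (abs(w[j] + step) - abs(w[j])) + (loss_new - loss)
                if delta <= sigma * scale * gamma:
                    accepted = True
                    break
                scale *= beta
                step = z * scale
            if not accepted:
                continue
            w[j] += step
            b = b_new
            loss = loss_new
            max_step = max(max_step, abs(step))
        if (sweep + 1) % cfg.recompute_every == 0:
            b = _margins(w, X, y)
            loss = C * float(np.sum(np.maximum(b, 0.0) ** 2))
        trace.append(float(np.abs(w).sum() + loss))
        if max_step < cfg.tol:
            converged = True
            break
    return LinearModel(
        weights=w,
        penalty=C,
        n_sweeps_run=sweeps,
        objective_trace=trace,
        converged=converged,
        gene_ids=list(m.gene_ids),
    )


def decision_score(model: LinearModel, X: np.ndarray) -> np.ndarray:
    """Raw decision values w.x (used for AUC)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(model.weights):
        raise ValueError(
            f"feature count {X.shape[1]} != model dimension {len(model.weights)}"
        )
    return X @ model.weights


def predict(model: LinearModel, X: np.ndarray) -> np.ndarray:
    """sign(w.x) with the tie sign(0) -> +1."""
    s = decision_score(model, X)
    return np.where(s >= 0.0, 1, -1)


def weight_estimator(C: float, cfg: SolverConfig | None = None):
    """Adapt :func:`fit` to the (matrix -> weights) estimator contract
    used by recursive feature elimination."""

    def estimate(m: LabeledMatrix) -> np.ndarray:
        return fit(m, C=C, cfg=cfg).weights

    return estimate
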