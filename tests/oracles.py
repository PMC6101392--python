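"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the objective oracle
is a dense (coarse-to-fine) grid search, the subproblem oracle is a 1-D
grid scan, and the schedule simulator is a stand-alone re-derivation of
the halving rule.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_objective(W: np.ndarray, X: np.ndarray, y: np.ndarray, C: float) -> np.ndarray:
    """Objective ||w||_1 + C*sum(max(1-y w.x,0)^2) for each candidate row of W."""
    B = 1.0 - y[:, None] * (X @ W.T)  # (n, K)
    return np.abs(W).sum(axis=1) + C * np.sum(np.maximum(B, 0.0) ** 2, axis=0)


def grid_min_objective(
    X: np.ndarray, y: np.ndarray, C: float, lo: float = -3.0, hi: float = 3.0
) -> float:
    """Minimum of the L1 squared-hinge objective over the weight cube,
    by dense grid search refined around the coarse argmin (sound because
    the objective is convex)."""
    d = X.shape[1]
    axes = [np.arange(lo, hi + 1e-9, 0.05)] * d
    W = np.array(list(itertools.product(*axes)))
    vals = brute_objective(W, X, y, C)
    best = W[np.argmin(vals)]
    axes = [np.arange(b - 0.06, b + 0.06 + 1e-12, 0.002) for b in best]
    W2 = np.array(list(itertools.product(*axes)))
    vals2 = brute_objective(W2, X, y, C)
    return float(min(vals.min(), vals2.min()))


def subproblem_grid_min(w_j: float, d1: float, d2: float) -> tuple[float, float]:
    """1-D grid-search minimizer of |w_j+z| + d1 z + d2 z^2/2 over
    z in [-10, 10] at resolution 1e-4; returns (z, value)."""
    z = np.arange(-10.0, 10.0 + 1e-9, 1e-4)
    g = np.abs(w_j + z) + d1 * z + 0.5 * d2 * z**2
    i = int(np.argmin(g))
    return float(z[i]), float(g[i])


def independent_schedule(n_total: int, n_selected: int, s_initial: int) -> list[int]:
    """Stand-alone simulation of the variable-step deletion schedule:
    clamp to the target, then halve the step each time the survivor count
    has halved since the last halving point."""
    counts: list[int] = []
    remaining = n_total
    step = s_initial
    halving_ref = n_total
    while remaining > n_selected:
        c = step if remaining - step >= n_selected else remaining - n_selected
        remaining -= c
        counts.append(c)
        while step > 1 and 2 * remaining <= halving_ref:
            halving_ref = remaining
            step //= 2
    return counts
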