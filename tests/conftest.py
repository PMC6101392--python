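import numpy as np
import pytest

from genesel.dataset import LabeledMatrix


def make_matrix(values, labels, gene_ids=None, codes=None) -> LabeledMatrix:
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{j}" for j in range(values.shape[1])]
    return LabeledMatrix(
        values=values,
        gene_ids=gene_ids,
        sample_ids=[f"s{i}" for i in range(values.shape[0])],
        labels=np.asarray(labels),
        label_codes=codes or {-1: "neg", +1: "pos"},
    )


@pytest.fixture
def two_point_1d() -> LabeledMatrix:
    """The minimal 1-D dataset {(x=+1, y=+1), (x=-1, y=-1)}."""
    return make_matrix([[1.0], [-1.0]], [1, -1])


@pytest.fixture
def separable() -> LabeledMatrix:
    """Two Gaussian clouds shifted 3 sigma apart on every gene: n=40, d=50."""
    rng = np.random.default_rng(7)
    X = rng.normal(0, 1, size=(40, 50))
    y = np.repeat([-1, 1], 20)
    X += 1.5 * y[:, None]
    return make_matrix(X, y)


@pytest.fixture
def planted16() -> LabeledMatrix:
    """16 genes: gene 0 separates the classes by construction, genes 1..15
    are pure low-amplitude noise, so |w_0| dominates any linear fit."""
    rng = np.random.default_rng(3)
    y = np.repeat([-1, 1], 10)
    X = rng.normal(0, 0.3, size=(20, 16))
    X[:, 0] = 2.0 * y + rng.normal(0, 0.05, size=20)
    return make_matrix(X, y)


def random_instance(rng: np.random.Generator, max_n=8, max_d=6) -> LabeledMatrix:
    """Small random two-class instance for solver property tests."""
    n = int(rng.integers(2, max_n + 1))
    d = int(rng.integers(1, max_d + 1))
    X = rng.normal(0, 1, size=(n, d))
    y = np.ones(n, dtype=int)
    y[: n // 2] = -1
    if np.all(y == y[0]):
        y[0] = -y[0]
    return make_matrix(X, y)
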