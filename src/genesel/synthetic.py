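"""Synthetic microarray-like datasets with planted informative genes.

Real expression studies in this problem regime have tens of samples,
thousands of genes, a handful of genes whose mean expression shifts with
class, and moderate class imbalance (imbalance ratios roughly 1.1-1.9).
The generator emulates exactly that structure: noise genes are
Normal(0, sd^2) in both classes, informative genes are Normal(-effect/2)
in class 1 and Normal(+effect/2) in class 2.  With effect around 2 and
unit noise the classes are linearly separable with overwhelming
probability in the overparameterized regime (d >> n), matching the
working assumption that such data suits linear models.

Ground truth (the planted gene indices) is returned separately from the
matrix, so selection code cannot peek at it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import LabeledMatrix

#: (name, n_class1, n_class2, n_genes) of six canonical dataset shapes used
#: throughout the microarray feature-selection literature.
CANONICAL_SHAPES: tuple[tuple[str, int, int, int], ...] = (
    ("colon", 22, 40, 2000),
    ("cns", 21, 39, 7129),
    ("leukemia", 25, 47, 7129),
    ("ovarian", 91, 162, 15154),
    ("prostate", 59, 77, 12600),
    ("breast", 46, 51, 24481),
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic two-class expression matrix.

    ``effect`` is the between-class mean shift on each informative gene,
    in the same (arbitrary) expression units as ``noise_sd``, the
    within-class standard deviation.  Defaults (effect 2, sd 1, 10
    informative genes) give a planted signal strong enough for linear
    separation yet weak enough that single-gene tests are noisy — the
    regime backward elimination is meant for.
    """

    n_class1: int
    n_class2: int
    n_genes: int
    informative_ids: tuple[int, ...] = tuple(range(10))
    effect: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if self.n_class1 < 1 or self.n_class2 < 1 or self.n_genes < 1:
            raise ValueError("counts must be positive")
        ids = tuple(self.informative_ids)
        if any(not (0 <= g < self.n_genes) for g in ids):
            raise ValueError("informative_ids must lie in [0, n_genes)")
        if len(set(ids)) != len(ids):
            raise ValueError("informative_ids must be unique")
        if self.effect < 0 or self.noise_sd <= 0:
            raise ValueError("need effect >= 0 and noise_sd > 0")
        object.__setattr__(self, "informative_ids", ids)


def generate(spec: SyntheticSpec) -> tuple[LabeledMatrix, set[str]]:
    """Draw a matrix from the spec; returns (matrix, informative gene ids).

    Class 1 rows come first.  Labels are mapped minority -> -1 (class 1 on
    a tie).  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n1, n2, d = spec.n_class1, spec.n_class2, spec.n_genes
    values = rng.normal(0.0, spec.noise_sd, size=(n1 + n2, d))
    info = np.asarray(spec.informative_ids, dtype=int)
    if len(info):
        values[:n1, info] -= spec.effect / 2.0
        values[n1:, info] += spec.effect / 2.0
    if (n1, "class1") <= (n2, "class2"):
        labels = np.concatenate([np.full(n1, -1), np.full(n2, +1)])
        codes = {-1: "class1", +1: "class2"}
    else:
        labels = np.concatenate([np.full(n1, +1), np.full(n2, -1)])
        codes = {-1: "class2", +1: "class1"}
    gene_ids = [f"g{j}" for j in range(d)]
    sample_ids = [f"c1_{i}" for i in range(n1)] + [f"c2_{i}" for i in range(n2)]
    m = LabeledMatrix(values, gene_ids, sample_ids, labels, codes)
    return m, {f"g{j}" for j in spec.informative_ids}


def table4_shapes(
    effect: float = 2.0, noise_sd: float = 1.0, seed: int = 0
) -> list[SyntheticSpec]:
    """Six specs matching the canonical dataset shapes (class counts and
    gene counts), with default planted-signal settings."""
    return [
        SyntheticSpec(
            n_class1=n1,
            n_class2=n2,
            n_genes=d,
            effect=effect,
            noise_sd=noise_sd,
            seed=seed + i,
            name=name,
        )
        for i, (name, n1, n2, d) in enumerate(CANONICAL_SHAPES)
    ]
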