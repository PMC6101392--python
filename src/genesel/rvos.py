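"""Random value-based oversampling (RVOS) for two-class imbalance.

RVOS synthesizes new minority-class samples by drawing, for every gene
independently, one observed value from that gene's minority-class column
(uniformly, with replacement).  Unlike SMOTE-style interpolation no new
expression value is ever invented: every value in a synthetic sample was
measured in some real minority sample, which preserves the biological
meaning of each entry while equalizing class sizes.

The assumption is that minority samples are i.i.d. per gene; gene-gene
correlation within a sample is deliberately broken by the independent
per-column draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import LabeledMatrix


@dataclass(frozen=True)
class RvosConfig:
    """Number of synthetic samples to draw and the RNG seed."""

    k: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be >= 0")


def rvos_generate(minority: np.ndarray, cfg: RvosConfig) -> np.ndarray:
    """Draw ``cfg.k`` synthetic rows from a one-class matrix.

    Each output entry (r, j) is an element of column j of ``minority``,
    drawn uniformly with replacement; draws are independent across columns
    and across synthetic samples.  Reproducible under a fixed seed: a single
    generator is consumed column-major within each new sample.

    Returns an array of shape (k, n_genes); (0, n_genes) when k == 0.
    """
    minority = np.asarray(minority, dtype=float)
    if minority.ndim != 2 or minority.shape[0] < 1:
        raise ValueError("minority matrix must have at least one sample")
    n, d = minority.shape
    rng = np.random.default_rng(cfg.seed)
    out = np.empty((cfg.k, d), dtype=float)
    for r in range(cfg.k):
        rows = rng.integers(0, n, size=d)
        out[r] = minority[rows, np.arange(d)]
    return out


def rvos_balance(m: LabeledMatrix, seed: int = 0) -> LabeledMatrix:
    """Balance a two-class matrix by oversampling the minority class.

    k = |majority| - |minority| synthetic minority samples are appended
    after the original rows (which are preserved verbatim), so the output
    has equal class counts and imbalance ratio exactly 1.0.  Synthetic rows
    get sample ids suffixed ``_rvos<i>`` so downstream code can tell them
    from measured samples.
    """
    m.require_two_classes()
    n_minority, n_majority = m.class_counts()
    k = n_majority - n_minority
    if k == 0:
        return m
    minority_rows = m.values[m.labels == -1]
    synth = rvos_generate(minority_rows, RvosConfig(k=k, seed=seed))
    values = np.vstack([m.values, synth])
    labels = np.concatenate([m.labels, np.full(k, -1, dtype=m.labels.dtype)])
    sample_ids = list(m.sample_ids) + [f"synthetic_rvos{i}" for i in range(k)]
    return LabeledMatrix(
        values=values,
        gene_ids=list(m.gene_ids),
        sample_ids=sample_ids,
        labels=labels,
        label_codes=dict(m.label_codes),
    )
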