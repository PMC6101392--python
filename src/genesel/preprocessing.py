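"""Per-gene standardization and three-level expression discretization.

Expression matrices mix genes whose raw scales differ by orders of
magnitude, so each gene is centered and scaled to zero mean / unit variance
before model fitting.  For mutual-information-based selectors a coarse
discretization into under- / normal- / over-expression is used:

    +2  if x > mu + sigma/2      (over-expressed)
    -2  if x < mu - sigma/2      (under-expressed)
     0  otherwise                (normal expression)

with strict inequalities, so boundary values map to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import LabeledMatrix


@dataclass(frozen=True)
class StandardizationParams:
    """Per-gene mean and standard deviation, as fitted on a training matrix.

    ``ddof`` records whether sigma is the population (0) or sample (1)
    standard deviation; the default is population, the common
    machine-scaler convention.
    """

    mu: np.ndarray
    sigma: np.ndarray
    ddof: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))
        if self.mu.shape != self.sigma.shape:
            raise ValueError("mu and sigma must have equal length")
        if np.any(self.sigma < 0):
            raise ValueError("sigma entries must be >= 0")

    @property
    def n_genes(self) -> int:
        return len(self.mu)


def fit_standardizer(m: LabeledMatrix, ddof: int = 0) -> StandardizationParams:
    """Fit per-gene mean and standard deviation on a training matrix.

    Requires at least two samples (a standard deviation over one sample is
    meaningless, and with ddof=1 undefined).
    """
    if m.n_samples < 2:
        raise ValueError("standardization requires >= 2 samples")
    mu = m.values.mean(axis=0)
    sigma = m.values.std(axis=0, ddof=ddof)
    return StandardizationParams(mu=mu, sigma=sigma, ddof=ddof)


def apply_standardizer(m: LabeledMatrix, p: StandardizationParams) -> LabeledMatrix:
    """Center and scale each gene by the fitted (mu, sigma).

    Constant genes (sigma == 0) map to all-zeros rather than raising:
    a constant gene carries no class information and should not crash a
    pipeline.  Train/test separation is the caller's responsibility — fit
    on training rows, apply to both.
    """
    if p.n_genes != m.n_genes:
        raise ValueError(
            f"params fitted on {p.n_genes} genes, matrix has {m.n_genes}"
        )
    safe_sigma = np.where(p.sigma == 0, 1.0, p.sigma)
    z = (m.values - p.mu) / safe_sigma
    z[:, p.sigma == 0] = 0.0
    return LabeledMatrix(
        values=z,
        gene_ids=list(m.gene_ids),
        sample_ids=list(m.sample_ids),
        labels=m.labels.copy(),
        label_codes=dict(m.label_codes),
    )


def standardize(m: LabeledMatrix, ddof: int = 0) -> LabeledMatrix:
    """Convenience: fit on `m` and apply to `m`."""
    return apply_standardizer(m, fit_standardizer(m, ddof=ddof))


def discretize(m: LabeledMatrix, p: StandardizationParams) -> LabeledMatrix:
    """Three-level discretization into {-2, 0, +2} per gene.

    Strict thresholds: x > mu + sigma/2 maps to +2, x < mu - sigma/2 to -2,
    everything else (including exact boundary values) to 0.  Thresholds come
    from the fitted params, so composition order (raw vs. standardized
    input) is up to the pipeline; the documented default is to discretize
    the standardized matrix, where mu = 0 and sigma = 1 per gene.
    """
    if p.n_genes != m.n_genes:
        raise ValueError(
            f"params fitted on {p.n_genes} genes, matrix has {m.n_genes}"
        )
    hi = p.mu + p.sigma / 2.0
    lo = p.mu - p.sigma / 2.0
    out = np.zeros_like(m.values)
    out[m.values > hi] = +2.0
    out[m.values < lo] = -2.0
    return LabeledMatrix(
        values=out,
        gene_ids=list(m.gene_ids),
        sample_ids=list(m.sample_ids),
        labels=m.labels.copy(),
        label_codes=dict(m.label_codes),
    )
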