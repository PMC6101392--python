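"""Classification metrics, stratified cross-validation, and grid search.

Metrics are the standard two-class set: accuracy, Matthews correlation
coefficient (MCC), true/false positive rates, and the rank-based
(Mann-Whitney) AUC.  MCC uses the standard numerator TP*TN - FP*FN, which
is the form consistent with MCC in [-1, +1], +1 at perfect prediction and
sign flip under inverted predictions.

Cross-validation is stratified k-fold with shuffled-within-class
round-robin fold assignment, so per-fold class proportions match the full
dataset within one sample per class.  By convention the minority class
(internal code -1) is the positive class for TP/FN accounting.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .dataset import LabeledMatrix


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Per-evaluation metric bundle; ``counts`` holds the 2x2 table."""

    acc: float
    mcc: float
    auc: float
    tpr: float
    fpr: float
    counts: ConfusionCounts

    def to_dict(self) -> dict:
        return {
            "acc": self.acc,
            "mcc": self.mcc,
            "auc": self.auc,
            "tpr": self.tpr,
            "fpr": self.fpr,
            "counts": {
                "tp": self.counts.tp,
                "fp": self.counts.fp,
                "tn": self.counts.tn,
                "fn": self.counts.fn,
            },
        }


def confusion(
    true_labels: Sequence, predicted_labels: Sequence, positive_class
) -> ConfusionCounts:
    """2x2 confusion counts with an explicitly declared positive class."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    seen = set(np.unique(t).tolist()) | set(np.unique(p).tolist())
    if positive_class not in seen and len(t):
        raise ValueError(f"positive class {positive_class!r} not among labels {seen}")
    tpos = t == positive_class
    ppos = p == positive_class
    return ConfusionCounts(
        tp=int(np.sum(tpos & ppos)),
        fp=int(np.sum(~tpos & ppos)),
        tn=int(np.sum(~tpos & ~ppos)),
        fn=int(np.sum(tpos & ~ppos)),
    )


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise ValueError("empty confusion counts")
    return (c.tp + c.tn) / c.total


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def tpr(c: ConfusionCounts) -> float:
    return c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0


def fpr(c: ConfusionCounts) -> float:
    return c.fp / (c.fp + c.tn) if (c.fp + c.tn) else 0.0


def auc(scores: Sequence[float], true_labels: Sequence, positive_class) -> float:
    """Mann-Whitney AUC: P(random positive scores above random negative),
    ties counted half.  Equals the trapezoidal area under the ROC curve."""
    s = np.asarray(scores, dtype=float)
    t = np.asarray(true_labels)
    pos = t == positive_class
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(s)  # average ranks give 0.5 credit per tie
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def metrics_report(
    true_labels: Sequence,
    predicted_labels: Sequence,
    scores: Sequence[float],
    positive_class=-1,
) -> MetricsReport:
    """Bundle all metrics; ``scores`` must be oriented so larger means
    more positive-class."""
    c = confusion(true_labels, predicted_labels, positive_class)
    return MetricsReport(
        acc=accuracy(c),
        mcc=mcc(c),
        auc=auc(scores, true_labels, positive_class),
        tpr=tpr(c),
        fpr=fpr(c),
        counts=c,
    )


@dataclass(frozen=True)
class CvPlan:
    """Fold assignment per sample for stratified k-fold CV."""

    k: int
    assignment: np.ndarray  # fold index in [0, k) per sample
    seed: int

    def folds(self) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        for f in range(self.k):
            test = np.flatnonzero(self.assignment == f)
            train = np.flatnonzero(self.assignment != f)
            yield train, test


def stratified_kfold(labels: Sequence, k: int = 5, seed: int = 0) -> CvPlan:
    """Shuffled-within-class round-robin fold assignment.

    Each class's samples are shuffled (seeded) and dealt to folds 0..k-1 in
    turn, so per-fold class counts differ from exact proportion by at most
    one sample per class.  Deterministic under the seed.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(labels), dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            raise ValueError(
                f"class {cls!r} has {len(idx)} samples, fewer than k={k} folds"
            )
        idx = rng.permutation(idx)
        assignment[idx] = np.arange(len(idx)) % k
    return CvPlan(k=k, assignment=assignment, seed=seed)


PipelineFactory = Callable[[], "Pipeline"]


class Pipeline:
    """Trainer + predictor contract for cross-validation.

    Implementations must fit all preprocessing and model state from the
    training LabeledMatrix only, then predict on bare value matrices.
    """

    def fit(self, m: LabeledMatrix) -> "Pipeline":  # pragma: no cover
        raise NotImplementedError

    def predict(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Raw scores, larger meaning more +1-class; default: predictions."""
        return self.predict(X).astype(float)


def cross_validate(
    m: LabeledMatrix,
    pipeline_factory: PipelineFactory,
    plan: CvPlan,
    positive_class: int = -1,
) -> tuple[MetricsReport, list[MetricsReport]]:
    """Fit a fresh pipeline per fold on training rows only; evaluate held-out.

    Returns the unweighted mean over folds (counts summed) and the per-fold
    reports.  Scores for AUC are re-oriented toward the declared positive
    class.
    """
    m.require_two_classes()
    fold_reports: list[MetricsReport] = []
    for f, (train, test) in enumerate(plan.folds()):
        try:
            pipe = pipeline_factory()
            pipe.fit(m.subset_samples(train))
            X_test = m.values[test]
            preds = pipe.predict(X_test)
            scores = pipe.decision_scores(X_test)
        except Exception as exc:
            raise RuntimeError(f"pipeline failed on fold {f}: {exc}") from exc
        if positive_class == -1:
            scores = -np.asarray(scores, dtype=float)
        fold_reports.append(
            metrics_report(m.labels[test], preds, scores, positive_class)
        )
    mean = MetricsReport(
        acc=float(np.mean([r.acc for r in fold_reports])),
        mcc=float(np.mean([r.mcc for r in fold_reports])),
        auc=float(np.mean([r.auc for r in fold_reports])),
        tpr=float(np.mean([r.tpr for r in fold_reports])),
        fpr=float(np.mean([r.fpr for r in fold_reports])),
        counts=ConfusionCounts(
            tp=sum(r.counts.tp for r in fold_reports),
            fp=sum(r.counts.fp for r in fold_reports),
            tn=sum(r.counts.tn for r in fold_reports),
            fn=sum(r.counts.fn for r in fold_reports),
        ),
    )
    return mean, fold_reports


def grid_search(
    m: LabeledMatrix,
    pipeline_factory: Callable[..., Pipeline],
    grid: Mapping[str, Sequence],
    plan: CvPlan,
    positive_class: int = -1,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive grid search scored by mean cross-validated accuracy.

    ``pipeline_factory(**params)`` must return a fresh pipeline.  Ties are
    broken by declared grid order (first wins), for reproducibility.
    Returns the best parameter dict and the full score table.
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be non-empty")
    names = list(grid.keys())
    rows = []
    best_params: dict | None = None
    best_acc = -np.inf
    for combo in itertools.product(*(grid[n] for n in names)):
        params = dict(zip(names, combo))
        mean, _ = cross_validate(
            m, lambda: pipeline_factory(**params), plan, positive_class
        )
        rows.append({**params, "mean_acc": mean.acc, "mean_auc": mean.auc,
                     "mean_mcc": mean.mcc})
        if mean.acc > best_acc:
            best_acc = mean.acc
            best_params = params
    return best_params, pd.DataFrame(rows)
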