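"""Recursive feature elimination with a variable (halving) step size.

Classic RFE trains a weight-producing model, deletes the single
lowest-|weight| gene, and repeats — robust but needing one fit per deleted
gene.  With tens of thousands of genes and only a handful wanted, most
early deletions remove genes that are obviously irrelevant, so the
variable-step variant starts with a large per-iteration deletion count
``s_initial`` and halves it each time the surviving gene count has halved,
reaching step 1 for the final, careful eliminations.  The step schedule:

* delete ``min(S, N - n_selected)`` genes per iteration (clamped so the
  run terminates at exactly ``n_selected`` survivors);
* after each deletion, while ``N <= temp/2`` and ``S > 1``:
  ``temp <- N``, ``S <- floor(S/2)`` (``temp`` starts at the total count).

With ``s_initial = 1`` the procedure degenerates to classic RFE.

The elimination order defines a full ranking: the later a gene is deleted
the more important it is.  Survivors are ranked by their final |weight|;
eliminated genes follow in reverse elimination order, within a batch
ordered by |weight|.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .dataset import LabeledMatrix

Estimator = Callable[[LabeledMatrix], np.ndarray]


@dataclass
class EliminationSchedule:
    """Mutable step-size state of a variable-step elimination run."""

    n_total: int
    n_selected: int
    s_initial: int
    current_S: int = field(init=False)
    current_N: int = field(init=False)
    temp: int = field(init=False)

    def __post_init__(self) -> None:
        if not (1 <= self.n_selected < self.n_total):
            raise ValueError(
                f"need 1 <= n_selected < n_total, got {self.n_selected}, {self.n_total}"
            )
        if self.s_initial < 1:
            raise ValueError("s_initial must be >= 1")
        self.current_S = self.s_initial
        self.current_N = self.n_total
        self.temp = self.n_total

    @property
    def done(self) -> bool:
        return self.current_N == self.n_selected


def next_deletion_count(s: EliminationSchedule) -> int:
    """Advance the schedule one iteration and return the deletion count.

    The count is ``min(S, N - n_selected)``; N is decremented by that same
    count, then the halving rule fires repeatedly while ``N <= temp/2`` and
    ``S > 1``.  Raises if the schedule is already done.
    """
    if s.done:
        raise ValueError("schedule exhausted: current_N == n_selected")
    count = min(s.current_S, s.current_N - s.n_selected)
    s.current_N -= count
    while s.current_N <= s.temp / 2 and s.current_S > 1:
        s.temp = s.current_N
        s.current_S //= 2
    return count


def schedule_counts(n_total: int, n_selected: int, s_initial: int) -> list[int]:
    """Full list of per-iteration deletion counts for a run (no fitting)."""
    sched = EliminationSchedule(n_total, n_selected, s_initial)
    counts = []
    while not sched.done:
        counts.append(next_deletion_count(sched))
    return counts


@dataclass(frozen=True)
class IterationRecord:
    """One elimination iteration: what was removed and what remained."""

    step_size: int
    removed_gene_ids: tuple[str, ...]
    remaining_count: int


@dataclass(frozen=True)
class EliminationTrace:
    """Outcome of an elimination run.

    ``ranking`` maps every original gene id to a rank in 1..n_total
    (1 = most important); ``selected`` is the ordered tuple of the
    n_selected surviving gene ids, best first.
    """

    iterations: tuple[IterationRecord, ...]
    ranking: dict[str, int]
    selected: tuple[str, ...]

    @property
    def n_fits(self) -> int:
        return len(self.iterations)

    def ranked_gene_ids(self) -> list[str]:
        return sorted(self.ranking, key=self.ranking.__getitem__)


def _order_by_importance(absw: np.ndarray, orig_index: Sequence[int]) -> list[int]:
    """Positions sorted most- to least-important.

    Primary key |w| descending; ties broken by original column index
    ascending, so among tied genes the higher index is deleted first.
    """
    return sorted(
        range(len(absw)), key=lambda p: (-absw[p], orig_index[p])
    )


def vssrfe_select(
    m: LabeledMatrix,
    estimator: Estimator,
    n_selected: int,
    s_initial: int,
    seed: int = 0,
) -> EliminationTrace:
    """Variable-step recursive elimination down to ``n_selected`` genes.

    ``estimator`` maps a LabeledMatrix to one finite weight per gene; it is
    refit from scratch on the surviving columns each iteration.  The run is
    deterministic given a deterministic estimator (``seed`` is reserved for
    stochastic estimators and not used otherwise).
    """
    del seed  # deterministic with the bundled estimators
    d = m.n_genes
    if not (1 <= n_selected < d):
        raise ValueError(f"need 1 <= n_selected < n_genes, got {n_selected}, {d}")
    sched = EliminationSchedule(n_total=d, n_selected=n_selected, s_initial=s_initial)
    surviving = list(range(d))
    records: list[IterationRecord] = []
    eliminated_batches: list[list[tuple[str, float]]] = []  # (gene_id, |w|)
    last_absw: dict[str, float] = {}
    it = 0
    while not sched.done:
        it += 1
        sub = m.subset_genes(np.asarray(surviving))
        w = np.asarray(estimator(sub), dtype=float)
        if w.shape != (len(surviving),):
            raise ValueError(
                f"iteration {it}: estimator returned {w.shape}, "
                f"expected ({len(surviving)},)"
            )
        if not np.all(np.isfinite(w)):
            raise ValueError(f"iteration {it}: estimator returned non-finite weights")
        absw = np.abs(w)
        last_absw = {m.gene_ids[g]: float(a) for g, a in zip(surviving, absw)}
        count = next_deletion_count(sched)
        order = _order_by_importance(absw, surviving)
        doomed = order[len(surviving) - count:]
        batch = [(m.gene_ids[surviving[p]], float(absw[p])) for p in doomed]
        eliminated_batches.append(batch)
        doomed_set = set(doomed)
        surviving = [g for p, g in enumerate(surviving) if p not in doomed_set]
        records.append(
            IterationRecord(
                step_size=count,
                removed_gene_ids=tuple(gid for gid, _ in batch),
                remaining_count=len(surviving),
            )
        )
    # survivors ranked by final |weight| (from the last fit), then batches
    # in reverse elimination order, within a batch by |weight|
    survivors_sorted = sorted(
        (m.gene_ids[g] for g in surviving),
        key=lambda gid: (-last_absw[gid], m.gene_ids.index(gid)),
    )
    ranking: dict[str, int] = {}
    rank = 1
    for gid in survivors_sorted:
        ranking[gid] = rank
        rank += 1
    for batch in reversed(eliminated_batches):
        for gid, _ in sorted(batch, key=lambda t: -t[1]):
            ranking[gid] = rank
            rank += 1
    return EliminationTrace(
        iterations=tuple(records),
        ranking=ranking,
        selected=tuple(survivors_sorted),
    )


def svm_rfe_select(
    m: LabeledMatrix, estimator: Estimator, n_selected: int
) -> EliminationTrace:
    """Classic one-gene-per-iteration RFE (step size fixed at 1)."""
    return vssrfe_select(m, estimator, n_selected=n_selected, s_initial=1)
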