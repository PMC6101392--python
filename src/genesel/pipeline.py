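"""End-to-end workflow: load/simulate -> balance -> standardize -> select
-> evaluate, with artifact outputs and a run log.

Stage order follows the usual protocol for imbalanced expression data:
oversample first (on raw values, so synthetic entries are real observed
expression values), then standardize, then run backward elimination, and
finally cross-validate a classifier on the selected genes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import llsvm
from .dataset import LabeledMatrix, load_matrix, summarize, write_matrix, write_selection
from .evaluation import cross_validate, stratified_kfold
from .pipelines import make_pipeline
from .preprocessing import apply_standardizer, discretize, fit_standardizer
from .rvos import rvos_balance
from .synthetic import SyntheticSpec, generate
from .vssrfe import svm_rfe_select, vssrfe_select

logger = logging.getLogger("genesel")


@dataclass
class RunConfig:
    """Validated parameters for a full pipeline run."""

    input_path: str | None = None
    input_format: str = "delimited"
    label_column: str | int = "label"
    simulate: SyntheticSpec | None = None
    seed: int = 0
    rvos: bool = True
    standardize_ddof: int = 0
    discretize: bool = False
    method: str = "vssrfe"  # or "rfe"
    estimator_C: float = 1.0
    s_initial: int = 100
    n_selected: int = 4
    classifier: str = "llsvm"
    classifier_params: dict | None = None
    folds: int = 5
    output_dir: str = "genesel_run"

    def validate(self) -> None:
        if self.input_path is None and self.simulate is None:
            raise ValueError("either input_path or simulate must be given")
        if self.method not in ("vssrfe", "rfe"):
            raise ValueError(f"unknown selection method {self.method!r}")
        if self.n_selected < 1 or self.s_initial < 1:
            raise ValueError("n_selected and s_initial must be >= 1")
        if self.estimator_C <= 0:
            raise ValueError("estimator C must be > 0")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")

    def config_hash(self) -> str:
        blob = {k: v for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(blob, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full workflow; returns paths of the emitted artifacts.

    Artifacts: ``ranking.tsv`` (full gene ranking), ``selected.csv`` (the
    selected submatrix), ``metrics.json`` (cross-validated metrics plus
    dataset summaries), ``run.log``.  All stamped with a config hash and
    the seed.
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(cfg, out)
    except Exception:
        # remove partial outputs, keep the log for diagnosis
        for name in ("ranking.tsv", "selected.csv", "metrics.json"):
            (out / name).unlink(missing_ok=True)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(cfg: RunConfig, out: Path) -> dict:
    chash = cfg.config_hash()
    logger.info("run start config=%s seed=%d", chash, cfg.seed)
    if cfg.simulate is not None:
        m, truth = generate(cfg.simulate)
        logger.info("simulated %dx%d matrix (%d informative genes)",
                    m.n_samples, m.n_genes, len(truth))
    else:
        m = load_matrix(cfg.input_path, cfg.input_format, cfg.label_column)
        logger.info("loaded %s: %dx%d", cfg.input_path, m.n_samples, m.n_genes)
    raw_summary = summarize(m)
    warning = None
    if cfg.rvos:
        m = rvos_balance(m, seed=cfg.seed)
        logger.info("rvos balanced to %s samples", m.n_samples)
    elif raw_summary.ir > 1.0:
        warning = f"input imbalanced (IR={raw_summary.ir:.2f}) and rvos is off"
        logger.warning(warning)
    params = fit_standardizer(m, ddof=cfg.standardize_ddof)
    m_std = apply_standardizer(m, params)
    work = discretize(m_std, fit_standardizer(m_std)) if cfg.discretize else m_std
    estimator = llsvm.weight_estimator(
        cfg.estimator_C, llsvm.SolverConfig(tol=1e-4, max_sweeps=200)
    )
    if cfg.method == "vssrfe":
        trace = vssrfe_select(work, estimator, cfg.n_selected, cfg.s_initial,
                              seed=cfg.seed)
    else:
        trace = svm_rfe_select(work, estimator, cfg.n_selected)
    for i, rec in enumerate(trace.iterations, 1):
        logger.info("elimination %d: deleted=%d remaining=%d",
                    i, rec.step_size, rec.remaining_count)
    ranked = trace.ranked_gene_ids()
    write_selection(
        ranked,
        [trace.ranking[g] for g in ranked],
        out / "ranking.tsv",
        elimination_iteration=_elimination_iterations(trace, ranked),
    )
    sel_cols = [m.gene_ids.index(g) for g in trace.selected]
    selected_matrix = m.subset_genes(np.asarray(sel_cols))
    write_matrix(selected_matrix, out / "selected.csv")
    plan = stratified_kfold(selected_matrix.labels, k=cfg.folds, seed=cfg.seed)
    mean, folds = cross_validate(
        selected_matrix,
        lambda: make_pipeline(cfg.classifier, **(cfg.classifier_params or {})),
        plan,
    )
    report = {
        "config_hash": chash,
        "seed": cfg.seed,
        "dataset_summary": json.loads(raw_summary.to_json()),
        "balanced_summary": json.loads(summarize(m).to_json()),
        "selected_genes": list(trace.selected),
        "n_estimator_fits": trace.n_fits,
        "mean": mean.to_dict(),
        "folds": [r.to_dict() for r in folds],
    }
    if warning:
        report["warning"] = warning
    (out / "metrics.json").write_text(json.dumps(report, indent=2))
    logger.info("run done: mean ACC=%.4f AUC=%.4f MCC=%.4f",
                mean.acc, mean.auc, mean.mcc)
    return {
        "ranking": str(out / "ranking.tsv"),
        "selected": str(out / "selected.csv"),
        "metrics": str(out / "metrics.json"),
        "log": str(out / "run.log"),
        "report": report,
    }


def _elimination_iterations(trace, ranked: list[str]) -> list[int]:
    by_gene = {}
    for i, rec in enumerate(trace.iterations, 1):
        for g in rec.removed_gene_ids:
            by_gene[g] = i
    return [by_gene.get(g, -1) for g in ranked]  # -1: survived to the end
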