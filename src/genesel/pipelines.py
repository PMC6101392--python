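"""Concrete train/predict pipelines for cross-validation.

Two families: the package's own sparse linear SVM, and thin adapters over
scikit-learn classifiers (kNN, Gaussian naive Bayes, L2 logistic
regression, linear SVM).  Each pipeline optionally balances the training
fold with RVOS and standardizes genes — both fitted on training rows only,
so cross-validation never leaks held-out information.
"""

from __future__ import annotations

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import LinearSVC

from . import llsvm
from .dataset import LabeledMatrix
from .evaluation import Pipeline
from .preprocessing import StandardizationParams, apply_standardizer, fit_standardizer
from .rvos import rvos_balance


class _PreprocessingMixin:
    balance: bool
    standardize: bool
    seed: int
    _params: StandardizationParams | None

    def _prepare(self, m: LabeledMatrix) -> LabeledMatrix:
        if self.balance:
            m = rvos_balance(m, seed=self.seed)
        if self.standardize:
            self._params = fit_standardizer(m)
            m = apply_standardizer(m, self._params)
        else:
            self._params = None
        return m

    def _transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self._params is None:
            return X
        p = self._params
        safe = np.where(p.sigma == 0, 1.0, p.sigma)
        Z = (X - p.mu) / safe
        Z[:, p.sigma == 0] = 0.0
        return Z


class LlsvmPipeline(Pipeline, _PreprocessingMixin):
    """RVOS (optional) + standardization + the package's L1 squared-hinge SVM."""

    def __init__(
        self,
        C: float = 1.0,
        cfg: llsvm.SolverConfig | None = None,
        balance: bool = False,
        standardize: bool = True,
        seed: int = 0,
    ):
        self.C = C
        self.cfg = cfg
        self.balance = balance
        self.standardize = standardize
        self.seed = seed
        self.model: llsvm.LinearModel | None = None
        self._params = None

    def fit(self, m: LabeledMatrix) -> "LlsvmPipeline":
        m = self._prepare(m)
        self.model = llsvm.fit(m, C=self.C, cfg=self.cfg)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return llsvm.predict(self.model, self._transform(X))

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return llsvm.decision_score(self.model, self._transform(X))


_SKLEARN_FACTORIES = {
    "knn": lambda **kw: KNeighborsClassifier(n_neighbors=kw.get("k", 5)),
    "nb": lambda **kw: GaussianNB(),
    "lr": lambda **kw: LogisticRegression(C=kw.get("C", 1.0), max_iter=5000),
    "svm": lambda **kw: LinearSVC(C=kw.get("C", 1.0)),
}


class SklearnPipeline(Pipeline, _PreprocessingMixin):
    """Adapter exposing a scikit-learn classifier through the pipeline
    contract; scores come from decision_function or P(class=+1)."""

    def __init__(
        self,
        classifier: str,
        balance: bool = False,
        standardize: bool = True,
        seed: int = 0,
        **params,
    ):
        if classifier not in _SKLEARN_FACTORIES:
            raise ValueError(
                f"unknown classifier {classifier!r}; "
                f"choose from {sorted(_SKLEARN_FACTORIES)}"
            )
        self.classifier = classifier
        self.params = params
        self.balance = balance
        self.standardize = standardize
        self.seed = seed
        self.est = None
        self._params = None

    def fit(self, m: LabeledMatrix) -> "SklearnPipeline":
        m = self._prepare(m)
        self.est = _SKLEARN_FACTORIES[self.classifier](**self.params)
        self.est.fit(m.values, m.labels)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.est.predict(self._transform(X)), dtype=int)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        Z = self._transform(X)
        if hasattr(self.est, "decision_function"):
            return np.asarray(self.est.decision_function(Z), dtype=float)
        proba = self.est.predict_proba(Z)
        pos_col = list(self.est.classes_).index(1)
        return np.asarray(proba[:, pos_col], dtype=float)


def make_pipeline(classifier: str = "llsvm", **kwargs) -> Pipeline:
    """Factory by name: 'llsvm' or one of the scikit-learn-backed
    classifiers ('knn', 'nb', 'lr', 'svm')."""
    if classifier == "llsvm":
        return LlsvmPipeline(**kwargs)
    return SklearnPipeline(classifier, **kwargs)
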