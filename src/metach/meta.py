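"""Logistic-regression meta-classifier producing the final S_Meta score.

The stacker sees only the three base-classifier probabilities per variant:

    S_Meta = sigma(alpha * S_cfDNA + beta * S_Seq1 + gamma * S_Seq2 + b)

fit by unregularized maximum likelihood.  Training inputs must be
out-of-fold (never produced by a base model that saw the variant), and the
meta-level cross-validation reuses the exact fold assignments recorded by
the cfDNA classifier, so both stages see identical train/validation splits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression

from .errors import LabelError, LeakageError, StateError
from .metrics import compute_aupr, compute_auroc


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


class MetaClassifier(BaseEstimator, ClassifierMixin):
    """Unregularized logistic regression over (S_cfDNA, S_Seq1, S_Seq2).

    Attributes (fitted): ``alpha_``, ``beta_``, ``gamma_``, ``intercept_``;
    ``fold_assignments_``, ``oof_scores_`` and ``cv_metrics_`` when folds are
    inherited from the cfDNA classifier.
    """

    def __init__(self, max_iter: int = 1000):
        self.max_iter = max_iter

    @staticmethod
    def _lr(max_iter):
        # C = inf: plain maximum likelihood, no regularization
        return LogisticRegression(C=np.inf, solver="lbfgs", max_iter=max_iter)

    def fit(self, X, y, folds=None, provenance=None) -> "MetaClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("meta-features must be an (n, 3) score matrix")
        if provenance is not None and not np.all(np.asarray(provenance, dtype=bool)):
            raise LeakageError("meta-features include in-fold (leaky) base scores")
        if len(np.unique(y)) < 2:
            raise LabelError("meta training labels contain a single class")
        if folds is not None:
            folds = np.asarray(folds, dtype=int)
            oof = np.empty(len(y))
            for k in np.unique(folds):
                train = folds != k
                lr = self._lr(self.max_iter).fit(X[train], y[train])
                oof[~train] = lr.predict_proba(X[~train])[:, 1]
            per_fold = [{
                "fold": int(k),
                "auroc": compute_auroc(oof[folds == k], y[folds == k]),
                "aupr": compute_aupr(oof[folds == k], y[folds == k]),
            } for k in np.unique(folds)]
            self.fold_assignments_ = folds
            self.oof_scores_ = oof
            self.cv_metrics_ = {
                "per_fold": per_fold,
                "pooled_auroc": compute_auroc(oof, y),
                "pooled_aupr": compute_aupr(oof, y),
            }
        lr = self._lr(self.max_iter).fit(X, y)
        self.alpha_, self.beta_, self.gamma_ = (float(c) for c in lr.coef_[0])
        self.intercept_ = float(lr.intercept_[0])
        self.classes_ = np.array([0, 1])
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "alpha_"):
            raise StateError("MetaClassifier is not fitted")

    def decision_function(self, X) -> np.ndarray:
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        return (self.alpha_ * X[:, 0] + self.beta_ * X[:, 1]
                + self.gamma_ * X[:, 2] + self.intercept_)

    def predict_proba(self, X) -> np.ndarray:
        pos = _sigmoid(self.decision_function(X))
        return np.column_stack([1.0 - pos, pos])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def save(self, path) -> None:
        self._check_fitted()
        manifest = {"kind": "meta_classifier", "alpha": self.alpha_,
                    "beta": self.beta_, "gamma": self.gamma_,
                    "intercept": self.intercept_}
        Path(path).write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path) -> "MetaClassifier":
        manifest = json.loads(Path(path).read_text())
        obj = cls()
        obj.alpha_ = manifest["alpha"]
        obj.beta_ = manifest["beta"]
        obj.gamma_ = manifest["gamma"]
        obj.intercept_ = manifest["intercept"]
        obj.classes_ = np.array([0, 1])
        return obj


def train_meta(oof_triples, labels, fold_assignments, provenance=None) -> MetaClassifier:
    """Fit the stacker on out-of-fold score triples with inherited folds."""
    X = np.asarray([t.as_array() if hasattr(t, "as_array") else t
                    for t in oof_triples], dtype=float)
    return MetaClassifier().fit(X, labels, folds=fold_assignments,
                                provenance=provenance)


def predict_meta(triple, model: MetaClassifier) -> float:
    """S_Meta for one score triple via the closed-form sigmoid link."""
    arr = triple.as_array() if hasattr(triple, "as_array") else np.asarray(triple, dtype=float)
    z = model.alpha_ * arr[0] + model.beta_ * arr[1] + model.gamma_ * arr[2] + model.intercept_
    return float(_sigmoid(z))
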