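"""Base classifiers: gradient-boosted trees with a deterministic CV grid.

Each base classifier is a LightGBM binary model chosen from a small fixed
grid (learning rate x tree count x depth) by pooled out-of-fold auPR under
stratified 5-fold cross-validation.  The winning configuration's out-of-fold
scores are kept — every training variant is scored only by fold models that
never saw it — and a final model is refit on all data for inference.  Class
imbalance is handled by inverse-frequency class weights, keeping the
out-of-fold probabilities interpretable.

For the cfDNA classifier, folds are additionally grouped by patient (as
closely as stratification permits) because the patient-level embedding
blocks would otherwise leak a patient's identity across folds.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import lightgbm as lgb
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .errors import FoldError, LabelError, SchemaError, StateError
from .metrics import compute_aupr, compute_auroc

DEFAULT_GRID = {
    "learning_rate": [0.1],
    "n_estimators": [50, 150],
    "max_depth": [3, 6],
}


@dataclass
class ScoreTriple:
    """Base-classifier probabilities of blood (CH) origin for one variant."""

    s_cfdna: float
    s_seq1: float
    s_seq2: float

    def as_array(self) -> np.ndarray:
        return np.array([self.s_cfdna, self.s_seq1, self.s_seq2])


def _proba_pos(model, X) -> np.ndarray:
    # lightgbm 4.x warns about feature names even for plain ndarrays
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="X does not have valid feature names")
        return model.predict_proba(X)[:, 1]


def _lgbm(params: dict, seed: int) -> lgb.LGBMClassifier:
    depth = params["max_depth"]
    return lgb.LGBMClassifier(
        objective="binary",
        learning_rate=params["learning_rate"],
        n_estimators=params["n_estimators"],
        max_depth=depth,
        num_leaves=min(31, 2 ** depth - 1) if depth > 0 else 31,
        min_child_samples=10,
        class_weight="balanced",
        n_jobs=1,
        deterministic=True,
        force_row_wise=True,
        random_state=seed,
        verbose=-1,
    )


class GradientBoostedClassifierCV(BaseEstimator, ClassifierMixin):
    """Binary GBM selected by pooled out-of-fold auPR over a fixed grid.

    Attributes (fitted): ``oof_scores_`` (leak-free P(CH) per training row),
    ``fold_assignments_`` (fold id per row), ``best_params_``,
    ``cv_metrics_`` (per-fold and pooled auROC/auPR for the winner),
    ``grid_results_`` and the refit ``model_``.
    """

    def __init__(self, param_grid: dict | None = None, n_splits: int = 5,
                 seed: int = 0):
        self.param_grid = param_grid
        self.n_splits = n_splits
        self.seed = seed

    def _folds(self, X, y, groups, folds):
        if folds is not None:
            folds = np.asarray(folds, dtype=int)
            if len(folds) != len(y):
                raise FoldError("fold assignment length mismatch")
            return folds
        if groups is not None:
            splitter = StratifiedGroupKFold(n_splits=self.n_splits, shuffle=True,
                                            random_state=self.seed)
            split = splitter.split(X, y, groups=groups)
        else:
            splitter = StratifiedKFold(n_splits=self.n_splits, shuffle=True,
                                       random_state=self.seed)
            split = splitter.split(X, y)
        out = np.empty(len(y), dtype=int)
        for k, (_, test_idx) in enumerate(split):
            out[test_idx] = k
        return out

    def fit(self, X, y, groups=None, folds=None) -> "GradientBoostedClassifierCV":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise LabelError("training labels contain a single class")
        if counts.min() < self.n_splits:
            raise FoldError(
                f"smallest class has {counts.min()} examples; need >= {self.n_splits}")
        grid = self.param_grid or DEFAULT_GRID
        self.fold_assignments_ = self._folds(X, y, groups, folds)
        configs = [dict(zip(grid, values))
                   for values in itertools.product(*grid.values())]
        self.grid_results_ = []
        best = None
        for params in configs:
            oof = np.empty(len(y))
            for k in np.unique(self.fold_assignments_):
                train = self.fold_assignments_ != k
                model = _lgbm(params, self.seed).fit(X[train], y[train])
                oof[~train] = _proba_pos(model, X[~train])
            aupr = compute_aupr(oof, y)
            self.grid_results_.append({**params, "oof_aupr": aupr})
            if best is None or aupr > best[0]:
                best = (aupr, params, oof)
        _, self.best_params_, self.oof_scores_ = best
        per_fold = []
        for k in np.unique(self.fold_assignments_):
            mask = self.fold_assignments_ == k
            per_fold.append({
                "fold": int(k),
                "auroc": compute_auroc(self.oof_scores_[mask], y[mask]),
                "aupr": compute_aupr(self.oof_scores_[mask], y[mask]),
            })
        self.cv_metrics_ = {
            "per_fold": per_fold,
            "pooled_auroc": compute_auroc(self.oof_scores_, y),
            "pooled_aupr": compute_aupr(self.oof_scores_, y),
        }
        self.model_ = _lgbm(self.best_params_, self.seed).fit(X, y)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "best_params_"):
            raise StateError("GradientBoostedClassifierCV is not fitted")

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise SchemaError(
                f"feature width {X.shape[1]} does not match training width "
                f"{self.n_features_in_}")
        if hasattr(self, "model_"):
            pos = _proba_pos(self.model_, X)
        else:
            pos = self._booster_.predict(X)
        return np.column_stack([1.0 - pos, pos])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def save(self, outdir) -> None:
        self._check_fitted()
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "model.txt").write_text(self.model_.booster_.model_to_string())
        manifest = {
            "kind": "gbm_classifier", "best_params": self.best_params_,
            "n_splits": self.n_splits, "seed": self.seed,
            "n_features": int(self.n_features_in_),
            "cv_metrics": self.cv_metrics_, "grid_results": self.grid_results_,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        np.savetxt(outdir / "oof_scores.tsv", self.oof_scores_, delimiter="\t")
        np.savetxt(outdir / "fold_assignments.tsv", self.fold_assignments_,
                   fmt="%d", delimiter="\t")

    @classmethod
    def load(cls, outdir) -> "GradientBoostedClassifierCV":
        outdir = Path(outdir)
        manifest = json.loads((outdir / "manifest.json").read_text())
        obj = cls(n_splits=manifest["n_splits"], seed=manifest["seed"])
        obj.best_params_ = manifest["best_params"]
        obj.cv_metrics_ = manifest["cv_metrics"]
        obj.grid_results_ = manifest["grid_results"]
        obj.n_features_in_ = manifest["n_features"]
        obj._booster_ = lgb.Booster(model_str=(outdir / "model.txt").read_text())
        obj.classes_ = np.array([0, 1])
        obj.oof_scores_ = np.loadtxt(outdir / "oof_scores.tsv", delimiter="\t")
        obj.fold_assignments_ = np.loadtxt(outdir / "fold_assignments.tsv",
                                           dtype=int, delimiter="\t")
        return obj
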