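"""Bagged decision-tree emotion classification with balanced leave-one-out CV.

Three predictor sets are compared: M1 (the 8 intrapersonal features), M2
(the 12 interpersonal features) and M3 (all 20).  An ensemble of unpruned
CART trees is fit on bootstrap resamples and predicts by majority vote;
per-predictor importance is the impurity decrease summed over splits,
averaged over trees and normalized to sum 1.

Cross-validation leaves one scene per category out per fold, so every fold
tests exactly one scene of each emotion and the folds partition the scene
set.  Missing predictor values (degenerate correlation features) are imputed
with the training-fold median.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from dyadkin.intra_features import INTRA_FEATURES
from dyadkin.inter_features import INTER_FEATURES

__all__ = [
    "ModelSpec",
    "CvReport",
    "model_spec",
    "BaggedTrees",
    "fit_bagged_trees",
    "cross_validate",
    "compare_models",
]

_PREDICTOR_SETS = {
    "M1": tuple(INTRA_FEATURES),
    "M2": tuple(INTER_FEATURES),
    "M3": tuple(INTRA_FEATURES) + tuple(INTER_FEATURES),
}


@dataclass(frozen=True)
class ModelSpec:
    name: str
    predictors: tuple[str, ...]
    n_trees: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not self.predictors:
            raise ValueError("predictor list must not be empty")


def model_spec(name: str, n_trees: int = 200, seed: int = 0) -> ModelSpec:
    """The canonical M1/M2/M3 predictor sets."""
    if name not in _PREDICTOR_SETS:
        raise ValueError(f"unknown model {name!r}; expected one of {sorted(_PREDICTOR_SETS)}")
    return ModelSpec(name=name, predictors=_PREDICTOR_SETS[name], n_trees=n_trees, seed=seed)


@dataclass
class CvReport:
    model: str
    fold_predictions: dict[str, str]  # scene_id -> predicted emotion
    fold_of_scene: dict[str, int]
    overall_accuracy: float
    per_class_accuracy: dict[str, float]
    importance_mean: dict[str, float]
    importance_std: dict[str, float]
    n_folds: int = 0


class BaggedTrees:
    """Bootstrap-aggregated unpruned CART trees with majority-vote prediction."""

    def __init__(self, n_trees: int = 200, seed: int | np.random.SeedSequence = 0):
        self.n_trees = n_trees
        self.seed = seed
        self.trees_: list[DecisionTreeClassifier] = []
        self.classes_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BaggedTrees":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training data must contain more than one class")
        self.classes_ = classes
        rng = np.random.default_rng(self.seed)
        n = len(y)
        self.trees_ = []
        for _ in range(self.n_trees):
            idx = rng.integers(0, n, size=n)
            tree = DecisionTreeClassifier(
                criterion="gini", random_state=int(rng.integers(2**31 - 1))
            )
            tree.fit(X[idx], y[idx])
            self.trees_.append(tree)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Majority vote over trees; ties resolved by class order."""
        X = np.asarray(X, dtype=float)
        votes = np.stack([t.predict(X) for t in self.trees_], axis=1)
        out = []
        for row in votes:
            counts = Counter(row)
            best = max(counts.values())
            winners = sorted(c for c, v in counts.items() if v == best)
            out.append(winners[0])
        return np.array(out)

    @property
    def importances_(self) -> np.ndarray:
        """Nonnegative per-predictor importances, normalized to sum 1."""
        imp = np.mean([t.feature_importances_ for t in self.trees_], axis=0)
        total = imp.sum()
        return imp / total if total > 0 else imp


def fit_bagged_trees(
    features: pd.DataFrame, labels: pd.Series | np.ndarray, spec: ModelSpec
) -> BaggedTrees:
    """Fit one ensemble on the full table restricted to the spec's predictors."""
    missing = set(spec.predictors) - set(features.columns)
    if missing:
        raise ValueError(f"feature table lacks predictors {sorted(missing)}")
    X = features[list(spec.predictors)].to_numpy(dtype=float)
    X = _impute_median(X, X)
    return BaggedTrees(spec.n_trees, spec.seed).fit(X, np.asarray(labels))


def _impute_median(train: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Replace NaNs in X by the per-column median of the training block."""
    out = X.copy()
    for j in range(X.shape[1]):
        col = train[:, j]
        med = np.nanmedian(col) if np.isfinite(col).any() else 0.0
        mask = ~np.isfinite(out[:, j])
        out[mask, j] = med
    return out


def cross_validate(
    features: pd.DataFrame, labels: pd.Series, spec: ModelSpec
) -> CvReport:
    """Leave-one-scene-per-category cross-validation.

    ``features`` is indexed by scene id; ``labels`` aligns with it.  Classes
    must be balanced; fold k tests the k-th scene of every class (in stable
    index order) and trains on the rest.
    """
    labels = pd.Series(np.asarray(labels), index=features.index)
    classes = list(dict.fromkeys(labels))
    per_class = {c: list(labels.index[labels == c]) for c in classes}
    sizes = {c: len(v) for c, v in per_class.items()}
    if len(set(sizes.values())) != 1:
        raise ValueError(f"classes must be balanced, got counts {sizes}")
    n_folds = next(iter(sizes.values()))

    missing = set(spec.predictors) - set(features.columns)
    if missing:
        raise ValueError(f"feature table lacks predictors {sorted(missing)}")
    X_all = features[list(spec.predictors)].to_numpy(dtype=float)
    pos = {sid: i for i, sid in enumerate(features.index)}

    seeds = np.random.SeedSequence(spec.seed).spawn(n_folds)
    predictions: dict[str, str] = {}
    fold_of_scene: dict[str, int] = {}
    importances = []
    for k in range(n_folds):
        test_ids = [per_class[c][k] for c in classes]
        test_idx = np.array([pos[s] for s in test_ids])
        train_mask = np.ones(len(features), dtype=bool)
        train_mask[test_idx] = False
        X_train = _impute_median(X_all[train_mask], X_all[train_mask])
        X_test = _impute_median(X_all[train_mask], X_all[test_idx])
        model = BaggedTrees(spec.n_trees, seeds[k]).fit(
            X_train, labels.to_numpy()[train_mask]
        )
        for sid, pred in zip(test_ids, model.predict(X_test)):
            predictions[sid] = str(pred)
            fold_of_scene[sid] = k
        importances.append(model.importances_)

    imp = np.stack(importances)
    truth = labels.to_dict()
    correct = {sid: predictions[sid] == truth[sid] for sid in predictions}
    per_class_acc = {
        c: float(np.mean([correct[sid] for sid in per_class[c]])) for c in classes
    }
    return CvReport(
        model=spec.name,
        fold_predictions=predictions,
        fold_of_scene=fold_of_scene,
        overall_accuracy=float(np.mean(list(correct.values()))),
        per_class_accuracy=per_class_acc,
        importance_mean=dict(zip(spec.predictors, imp.mean(axis=0).astype(float))),
        importance_std=dict(zip(spec.predictors, imp.std(axis=0).astype(float))),
        n_folds=n_folds,
    )


def compare_models(
    features: pd.DataFrame,
    labels: pd.Series,
    specs: list[ModelSpec] | None = None,
    n_trees: int = 200,
    seed: int = 0,
) -> dict[str, CvReport]:
    """Cross-validate each spec (default M1, M2, M3) on the same folds."""
    if specs is None:
        specs = [model_spec(name, n_trees=n_trees, seed=seed) for name in ("M1", "M2", "M3")]
    return {spec.name: cross_validate(features, labels, spec) for spec in specs}
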