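"""Uniform interface over the four classifier families with grid search.

Supported algorithms: k-nearest neighbours (``knn``), RBF support vector
machine (``svm``), random forest (``rfc``) and gradient-boosted trees
(``xgboost``).  Hyperparameters are chosen by exhaustive grid search under
stratified k-fold cross-validation with accuracy as the criterion; ties are
broken by declaration order of the grid points.  All stochastic components
(fold shuffling, tree subsampling) are driven by the single ``seed`` of the
:class:`ClassifierSpec` so a retrain is bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import LabelEncoder
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierSpec",
    "TrainedModel",
    "DEFAULT_GRIDS",
    "train",
    "predict",
    "predict_proba",
]

ALGORITHMS = ("knn", "svm", "rfc", "xgboost")

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "knn": {"n_neighbors": [1, 5, 15, 31]},
    "svm": {"C": [0.1, 1.0, 10.0], "gamma": ["scale"]},
    "rfc": {"n_estimators": [100, 500], "max_depth": [None, 10]},
    "xgboost": {
        "n_estimators": [100, 300],
        "max_depth": [3, 6],
        "learning_rate": [0.1, 0.3],
    },
}


@dataclass
class ClassifierSpec:
    """One classifier family plus its hyperparameter search grid."""

    algorithm: str
    grid: dict[str, list] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}"
            )
        if not self.grid:
            self.grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.algorithm].items()}

    def grid_points(self) -> list[dict]:
        """Grid points in declaration order (first key varies slowest)."""
        keys = list(self.grid)
        return [dict(zip(keys, vals)) for vals in product(*(self.grid[k] for k in keys))]


@dataclass
class TrainedModel:
    """A fitted classifier bound to an ordered feature-gene list."""

    spec: ClassifierSpec
    chosen_params: dict
    feature_gene_ids: list[str]
    classes: list[str]
    cv_accuracy: float
    _estimator: object
    _encoder: LabelEncoder


def _make_estimator(algorithm: str, params: dict, seed: int):
    if algorithm == "knn":
        return KNeighborsClassifier(**params)
    if algorithm == "svm":
        # probabilities come from the decision margins (softmax) so they can
        # never disagree with the hard decision rule
        return SVC(kernel="rbf", random_state=seed, **params)
    if algorithm == "rfc":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if algorithm == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(
            random_state=seed, n_jobs=1, tree_method="hist",
            eval_metric="mlogloss", verbosity=0,
            **params,
        )
    raise ValueError(algorithm)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _proba(estimator, algorithm: str, X: np.ndarray, n_classes: int) -> np.ndarray:
    if algorithm == "svm":
        df = estimator.decision_function(X)
        if df.ndim == 1:  # binary: one margin column → two-class softmax
            df = np.column_stack([-df, df])
        return _softmax(df)
    return estimator.predict_proba(X)


def train(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray,
          feature_gene_ids: list[str] | None = None, folds: int = 5
          ) -> TrainedModel:
    """Grid-search hyperparameters by stratified CV accuracy and refit on all data.

    Parameters
    ----------
    spec
        Algorithm, grid and seed.
    X
        Cells × selected-genes matrix with fixed column order.
    y
        Per-cell class labels.
    feature_gene_ids
        Column names of ``X``; positional names are generated when omitted.
    folds
        Stratified CV fold count; every class needs at least ``folds`` cells.

    Returns
    -------
    TrainedModel
        With ``chosen_params`` maximising mean CV accuracy (first grid point
        in declaration order on ties) and the final estimator refitted on all
        of ``X``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if feature_gene_ids is None:
        feature_gene_ids = [f"g{j}" for j in range(X.shape[1])]
    classes, class_counts = np.unique(y, return_counts=True)
    if class_counts.min() < folds:
        small = classes[class_counts.argmin()]
        raise ValueError(
            f"class {small!r} has {class_counts.min()} cells, fewer than "
            f"folds={folds}; reduce the fold count"
        )
    enc = LabelEncoder().fit(y)
    y_enc = enc.transform(y)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=spec.seed)
    fold_indices = list(skf.split(X, y_enc))

    best_params, best_acc = None, -np.inf
    for params in spec.grid_points():
        accs = []
        for tr, va in fold_indices:
            est = _make_estimator(spec.algorithm, params, spec.seed)
            est.fit(X[tr], y_enc[tr])
            accs.append(float((est.predict(X[va]) == y_enc[va]).mean()))
        mean_acc = float(np.mean(accs))
        if mean_acc > best_acc:  # strict >: declaration order wins ties
            best_acc, best_params = mean_acc, params

    final = _make_estimator(spec.algorithm, best_params, spec.seed)
    final.fit(X, y_enc)
    logger.debug("train %s: chose %s (CV acc %.4f)", spec.algorithm,
                 best_params, best_acc)
    return TrainedModel(
        spec=spec, chosen_params=best_params,
        feature_gene_ids=list(feature_gene_ids),
        classes=[str(c) for c in enc.classes_],
        cv_accuracy=best_acc, _estimator=final, _encoder=enc,
    )


def _check_columns(model: TrainedModel, feature_gene_ids: list[str] | None,
                   n_cols: int) -> None:
    if feature_gene_ids is None:
        if n_cols != len(model.feature_gene_ids):
            raise ValueError(
                f"expected {len(model.feature_gene_ids)} feature columns, got {n_cols}"
            )
        return
    if list(feature_gene_ids) != model.feature_gene_ids:
        missing = set(model.feature_gene_ids) - set(feature_gene_ids)
        extra = set(feature_gene_ids) - set(model.feature_gene_ids)
        raise ValueError(
            "feature columns do not match the model's gene list "
            f"(missing: {sorted(missing)[:5]}, extra: {sorted(extra)[:5]}, "
            "or wrong order)"
        )


def predict(model: TrainedModel, X: np.ndarray,
            feature_gene_ids: list[str] | None = None) -> np.ndarray:
    """Hard class-label predictions (always argmax of :func:`predict_proba`)."""
    proba = predict_proba(model, X, feature_gene_ids)
    idx = proba.argmax(axis=1)
    return np.asarray([model.classes[i] for i in idx], dtype=object)


def predict_proba(model: TrainedModel, X: np.ndarray,
                  feature_gene_ids: list[str] | None = None) -> np.ndarray:
    """Per-cell class-probability rows (non-negative, each summing to 1)."""
    X = np.asarray(X, dtype=float)
    _check_columns(model, feature_gene_ids, X.shape[1])
    proba = _proba(model._estimator, model.spec.algorithm, X, len(model.classes))
    return proba / proba.sum(axis=1, keepdims=True)
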