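"""Model-object facade over the full marker-selection workflow.

:class:`CellStateClassifier` is constructed from a labelled expression matrix
plus the selection configuration; its :meth:`~CellStateClassifier.fit` runs
gene scoring for every requested method, the incremental-feature-selection
sweep over every scorer × classifier combination, and a final refit of the
winning combination on the full training data.  The returned
:class:`CellStateResults` carries the rankings, the IFS curves, the fitted
winner and a ``summary()`` table, and knows how to ``predict`` and
``evaluate`` on held-out data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import classifiers as clf
from . import evaluation as ev
from . import ifs as ifs_mod
from . import scoring
from .io import LabelledExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["CellStateClassifier", "CellStateResults"]


class CellStateClassifier:
    """Supervised marker-gene selection and cell-state classification model.

    Parameters
    ----------
    data
        Labelled training matrix (cells × genes).
    scorers
        Gene-importance methods to rank with (subset of
        ``{"fscore", "cv2", "pca"}``).
    algorithms
        Classifier families to sweep (subset of
        ``{"knn", "svm", "rfc", "xgboost"}``); alternatively pass fully
        configured :class:`~genesieve.classifiers.ClassifierSpec` objects via
        ``specs``.
    schedule
        IFS subset sizes; defaults to a geometric grid per ranking.
    folds, patience
        Cross-validation folds and IFS early-stopping patience.
    seed
        Single seed driving fold shuffling and every stochastic learner.
    """

    def __init__(self, data: LabelledExpressionMatrix,
                 scorers: list[str] = ("fscore", "cv2", "pca"),
                 algorithms: list[str] = ("knn", "svm", "rfc", "xgboost"),
                 specs: list[clf.ClassifierSpec] | None = None,
                 grids: dict[str, dict] | None = None,
                 schedule: list[int] | None = None,
                 folds: int = 5, patience: int = 3, seed: int = 0):
        if data.labels is None:
            raise ValueError("training data must carry labels")
        self.data = data
        self.scorers = list(scorers)
        unknown = set(self.scorers) - set(scoring.SCORERS)
        if unknown:
            raise ValueError(f"unknown scorers: {sorted(unknown)}")
        if specs is not None:
            self.specs = list(specs)
        else:
            grids = grids or {}
            self.specs = [
                clf.ClassifierSpec(a, grid=grids.get(a, {}), seed=seed)
                for a in algorithms
            ]
        self.schedule = schedule
        self.folds = folds
        self.patience = patience
        self.seed = seed

    @classmethod
    def from_dataframe(cls, counts: pd.DataFrame, labels: pd.Series | np.ndarray,
                       **kwargs) -> "CellStateClassifier":
        """Build from a cells × genes DataFrame plus aligned labels."""
        labels = np.asarray(labels, dtype=object)
        data = LabelledExpressionMatrix(
            counts=counts.to_numpy(dtype=float),
            gene_ids=list(counts.columns),
            cell_ids=list(counts.index.astype(str)),
            labels=labels,
        )
        return cls(data, **kwargs)

    def fit(self) -> "CellStateResults":
        """Rank genes, sweep IFS, refit the winner; return the results object."""
        rankings = {s: scoring.rank_genes(self.data, s) for s in self.scorers}
        results, best = ifs_mod.sweep(
            self.data, list(rankings.values()), self.specs,
            schedule=self.schedule, folds=self.folds, patience=self.patience,
        )
        best_spec = next(s for s in self.specs if s.algorithm == best.algorithm)
        final_data = self.data.subset_genes(best.optimal_gene_ids)
        final_model = clf.train(
            best_spec, final_data.dense(), np.asarray(self.data.labels),
            feature_gene_ids=best.optimal_gene_ids, folds=self.folds,
        )
        return CellStateResults(self, rankings, results, best, final_model)


@dataclass
class CellStateResults:
    """Fitted results: rankings, IFS curves, the winning model."""

    model: CellStateClassifier
    rankings: dict[str, scoring.FeatureRanking]
    ifs_results: list[ifs_mod.IFSResult]
    best: ifs_mod.IFSResult
    final_model: clf.TrainedModel

    @property
    def optimal_gene_ids(self) -> list[str]:
        return self.best.optimal_gene_ids

    def summary(self) -> pd.DataFrame:
        """One row per scorer × classifier combination, winner first-ranked."""
        rows = [
            {
                "scorer": r.scoring_method,
                "algorithm": r.algorithm,
                "optimal_size": r.optimal_size,
                "optimal_cv_accuracy": r.optimal_accuracy,
                "winner": r is self.best,
            }
            for r in self.ifs_results
        ]
        return pd.DataFrame(rows).sort_values(
            ["optimal_cv_accuracy", "optimal_size"],
            ascending=[False, True], kind="stable",
        ).reset_index(drop=True)

    def _align(self, data: LabelledExpressionMatrix) -> np.ndarray:
        sub = data.subset_genes(self.final_model.feature_gene_ids)
        return sub.dense()

    def predict(self, data: LabelledExpressionMatrix) -> np.ndarray:
        """Predicted labels; genes are subset/reordered to the model's list."""
        return clf.predict(self.final_model, self._align(data),
                           self.final_model.feature_gene_ids)

    def predict_proba(self, data: LabelledExpressionMatrix) -> np.ndarray:
        return clf.predict_proba(self.final_model, self._align(data),
                                 self.final_model.feature_gene_ids)

    def evaluate(self, data: LabelledExpressionMatrix) -> ev.EvaluationReport:
        """Full evaluation report on labelled held-out data."""
        if data.labels is None:
            raise ValueError("evaluation data must carry labels")
        proba = self.predict_proba(data)
        pred = np.asarray(
            [self.final_model.classes[i] for i in proba.argmax(axis=1)],
            dtype=object,
        )
        return ev.evaluate(np.asarray(data.labels), pred, proba,
                           class_names=self.final_model.classes)

    def plot_ifs(self, ax=None):
        """IFS accuracy-vs-size curves, one line per combination."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4.5))
        for r in self.ifs_results:
            style = "-" if r is self.best else "--"
            ax.plot(r.subset_sizes, r.cv_accuracy, style, marker="o",
                    label=f"{r.scoring_method}+{r.algorithm}")
        ax.set_xscale("log")
        ax.set_xlabel("number of top-ranked genes")
        ax.set_ylabel("mean CV accuracy")
        ax.legend(fontsize=7)
        return ax
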