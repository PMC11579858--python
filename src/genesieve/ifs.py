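"""Incremental feature selection (IFS) over ranked gene lists.

IFS evaluates nested prefixes of a descending importance ranking with a
classifier under stratified cross-validation and picks the smallest prefix
whose CV accuracy reaches the running maximum.  "No further improvement" is
made operational as patience-based early stopping: after ``patience``
consecutive schedule steps without a new maximum the sweep over subset sizes
halts.  CV folds are re-drawn identically (same seed) at every subset size so
the accuracy curve is comparable size-to-size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .classifiers import ClassifierSpec, train
from .io import LabelledExpressionMatrix
from .scoring import FeatureRanking

logger = logging.getLogger(__name__)

__all__ = ["IFSResult", "default_schedule", "run_ifs", "sweep", "select_best"]


@dataclass
class IFSResult:
    """Accuracy-vs-subset-size curve for one (scorer, classifier) pair."""

    scoring_method: str
    algorithm: str
    subset_sizes: list[int]          # sizes actually evaluated, increasing
    cv_accuracy: list[float]         # mean CV accuracy per evaluated size
    optimal_size: int
    optimal_gene_ids: list[str]
    chosen_params_at_optimum: dict

    @property
    def method_pair(self) -> tuple[str, str]:
        return (self.scoring_method, self.algorithm)

    @property
    def optimal_accuracy(self) -> float:
        return self.cv_accuracy[self.subset_sizes.index(self.optimal_size)]


def default_schedule(n_ranked: int, n_points: int = 10, start: int = 10
                     ) -> list[int]:
    """Geometric grid of subset sizes from ``start`` to the ranking length."""
    if n_ranked < 1:
        raise ValueError("empty ranking")
    start = min(start, n_ranked)
    if start == n_ranked or n_points == 1:
        return [n_ranked]
    raw = np.geomspace(start, n_ranked, num=n_points)
    sizes = sorted({int(round(s)) for s in raw})
    return sizes


def run_ifs(ranking: FeatureRanking, spec: ClassifierSpec,
            m: LabelledExpressionMatrix, schedule: list[int] | None = None,
            folds: int = 5, patience: int = 3) -> IFSResult:
    """Evaluate ranking prefixes with one classifier and locate the optimum.

    Parameters
    ----------
    ranking
        Descending gene ranking (exclusions already applied).
    spec
        Classifier family, grid and seed; grid search runs at every size.
    m
        Labelled training matrix.
    schedule
        Strictly increasing subset sizes; defaults to a geometric grid over
        the ranking length.
    folds
        Stratified CV folds.
    patience
        Consecutive non-improving sizes tolerated before early stopping.

    Returns
    -------
    IFSResult
        ``optimal_size`` is the smallest evaluated size achieving the maximum
        CV accuracy; ``optimal_gene_ids`` is exactly that ranking prefix.
    """
    if schedule is None:
        schedule = default_schedule(len(ranking))
    if not schedule:
        raise ValueError("schedule must be non-empty")
    if any(b <= a for a, b in zip(schedule, schedule[1:])):
        raise ValueError("schedule must be strictly increasing")
    if schedule[-1] > len(ranking):
        raise ValueError(
            f"max schedule size {schedule[-1]} exceeds ranking length {len(ranking)}"
        )
    y = np.asarray(m.labels)
    full = m.subset_genes(ranking.ranked_gene_ids)
    Xfull = full.dense()

    sizes: list[int] = []
    accs: list[float] = []
    params: list[dict] = []
    best_acc, stall = -np.inf, 0
    for s in schedule:
        model = train(spec, Xfull[:, :s], y,
                      feature_gene_ids=ranking.ranked_gene_ids[:s], folds=folds)
        sizes.append(s)
        accs.append(model.cv_accuracy)
        params.append(model.chosen_params)
        logger.info("IFS %s/%s size=%d cv_acc=%.4f", ranking.method,
                    spec.algorithm, s, model.cv_accuracy)
        if model.cv_accuracy > best_acc:
            best_acc, stall = model.cv_accuracy, 0
        else:
            stall += 1
            if stall >= patience:
                logger.info("IFS early stop after %d non-improving sizes", stall)
                break

    opt_idx = int(np.argmax(accs))  # first maximum wins
    return IFSResult(
        scoring_method=ranking.method,
        algorithm=spec.algorithm,
        subset_sizes=sizes,
        cv_accuracy=accs,
        optimal_size=sizes[opt_idx],
        optimal_gene_ids=ranking.ranked_gene_ids[: sizes[opt_idx]],
        chosen_params_at_optimum=params[opt_idx],
    )


def select_best(results: list[IFSResult]) -> IFSResult:
    """Pick the winning combination.

    Highest optimal CV accuracy wins; ties prefer the smaller optimal subset
    (a simpler model), then earlier declaration order.
    """
    if not results:
        raise ValueError("no IFS results")
    best = results[0]
    for r in results[1:]:
        if (r.optimal_accuracy, -r.optimal_size) > (best.optimal_accuracy,
                                                    -best.optimal_size):
            best = r
    return best


def sweep(m: LabelledExpressionMatrix, rankings: list[FeatureRanking],
          specs: list[ClassifierSpec], schedule: list[int] | None = None,
          folds: int = 5, patience: int = 3
          ) -> tuple[list[IFSResult], IFSResult]:
    """Run IFS for every scorer × classifier combination.

    Returns all ``len(rankings) × len(specs)`` results plus the winner per
    :func:`select_best`.  A schedule size exceeding a particular ranking's
    length is truncated for that ranking only.
    """
    if not rankings or not specs:
        raise ValueError("need at least one ranking and one classifier spec")
    results: list[IFSResult] = []
    for ranking in rankings:
        sched = schedule
        if sched is not None:
            sched = [s for s in sched if s <= len(ranking)] or [len(ranking)]
        for spec in specs:
            results.append(run_ifs(ranking, spec, m, sched, folds, patience))
    return results, select_best(results)
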