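"""Incremental feature selection: plateau rule, oracle re-execution, sweep."""

import numpy as np
import pytest

from genesieve import (ClassifierSpec, IFSResult, default_schedule, fscore_rank,
                       run_ifs, select_best, sweep, train)
from genesieve.scoring import FeatureRanking

from conftest import make_matrix


def planted_matrix(n_classes=5, n_per=12, n_genes=120, seed=0):
    """First ``n_classes`` genes are noiseless one-hot class indicators."""
    rng = np.random.default_rng(seed)
    labels = np.repeat([f"c{i}" for i in range(n_classes)], n_per)
    X = rng.normal(10, 1, size=(len(labels), n_genes))
    for j in range(n_classes):
        X[:, j] = 10.0 * (labels == f"c{j}")
    return make_matrix(X, labels=labels)


class TestRunIfs:
    def test_single_size_schedule_is_optimal_by_construction(self, tiny_labelled):
        r = fscore_rank(tiny_labelled)
        spec = ClassifierSpec("knn", grid={"n_neighbors": [3]})
        res = run_ifs(r, spec, tiny_labelled, schedule=[5], folds=3)
        assert res.optimal_size == 5
        assert res.optimal_gene_ids == r.top(5)

    def test_plateau_on_planted_indicators(self):
        """5 noiseless indicator genes: accuracy saturates at size 5."""
        m = planted_matrix(n_classes=5, n_per=12, n_genes=120, seed=1)
        r = fscore_rank(m)
        assert set(r.top(5)) == {f"G{j}" for j in range(5)}
        spec = ClassifierSpec("knn", grid={"n_neighbors": [1]}, seed=0)
        res = run_ifs(r, spec, m, schedule=[1, 5, 50, 100], folds=4, patience=3)
        assert res.optimal_size == 5
        assert res.optimal_accuracy == pytest.approx(1.0)
        assert res.cv_accuracy[0] < 1.0  # one gene cannot separate 5 classes

    def test_curve_matches_reexecution_oracle(self, tiny_labelled):
        """Each curve point equals an independent train() at that prefix."""
        r = fscore_rank(tiny_labelled)
        spec = ClassifierSpec("knn", grid={"n_neighbors": [1, 3]}, seed=5)
        schedule = [2, 5, 10]
        res = run_ifs(r, spec, tiny_labelled, schedule=schedule, folds=3,
                      patience=10)
        y = np.asarray(tiny_labelled.labels)
        for size, acc in zip(res.subset_sizes, res.cv_accuracy):
            sub = tiny_labelled.subset_genes(r.top(size))
            oracle = train(spec, sub.dense(), y, folds=3)
            assert acc == pytest.approx(oracle.cv_accuracy, abs=1e-12)

    def test_early_stopping_respects_patience(self):
        m = planted_matrix(seed=2)
        r = fscore_rank(m)
        spec = ClassifierSpec("knn", grid={"n_neighbors": [1]}, seed=0)
        res = run_ifs(r, spec, m, schedule=[5, 10, 20, 40, 80, 100],
                      folds=4, patience=2)
        # accuracy is 1.0 from size 5; two non-improving sizes then stop
        assert res.subset_sizes == [5, 10, 20]
        assert res.optimal_size == 5

    def test_validation_errors(self, tiny_labelled):
        r = fscore_rank(tiny_labelled)
        spec = ClassifierSpec("knn", grid={"n_neighbors": [1]})
        with pytest.raises(ValueError, match="non-empty"):
            run_ifs(r, spec, tiny_labelled, schedule=[], folds=3)
        with pytest.raises(ValueError, match="increasing"):
            run_ifs(r, spec, tiny_labelled, schedule=[5, 5], folds=3)
        with pytest.raises(ValueError, match="exceeds"):
            run_ifs(r, spec, tiny_labelled, schedule=[10_000], folds=3)

    def test_accuracies_bounded_and_sizes_increasing(self, tiny_labelled):
        r = fscore_rank(tiny_labelled)
        spec = ClassifierSpec("knn", grid={"n_neighbors": [3]})
        res = run_ifs(r, spec, tiny_labelled, schedule=[2, 4, 8], folds=3)
        assert all(0 <= a <= 1 for a in res.cv_accuracy)
        assert res.subset_sizes == sorted(set(res.subset_sizes))


class TestDefaultSchedule:
    def test_geometric_grid_shape(self):
        sched = default_schedule(2000, n_points=10, start=10)
        assert sched[0] == 10 and sched[-1] == 2000
        assert sched == sorted(set(sched))

    def test_short_ranking_collapses(self):
        assert default_schedule(5) == [5]


def _fake_result(scorer, algo, acc, size):
    return IFSResult(scoring_method=scorer, algorithm=algo,
                     subset_sizes=[size], cv_accuracy=[acc],
                     optimal_size=size, optimal_gene_ids=["g"] * size,
                     chosen_params_at_optimum={})


class TestSelectBest:
    def test_highest_accuracy_wins(self):
        best = select_best([_fake_result("a", "x", 0.90, 10),
                            _fake_result("b", "y", 0.95, 100)])
        assert best.method_pair == ("b", "y")

    def test_tie_prefers_smaller_subset(self):
        """Equal accuracy at sizes 360 vs 20,000: the small model wins."""
        best = select_best([_fake_result("pca", "xgboost", 0.99, 20_000),
                            _fake_result("fscore", "xgboost", 0.99, 360)])
        assert best.optimal_size == 360

    def test_full_tie_prefers_declaration_order(self):
        best = select_best([_fake_result("a", "x", 0.9, 10),
                            _fake_result("b", "y", 0.9, 10)])
        assert best.method_pair == ("a", "x")


class TestSweep:
    def test_single_pair_reduces_to_run_ifs(self, tiny_labelled):
        r = fscore_rank(tiny_labelled)
        spec = ClassifierSpec("knn", grid={"n_neighbors": [3]}, seed=1)
        results, best = sweep(tiny_labelled, [r], [spec], schedule=[3, 6],
                              folds=3)
        solo = run_ifs(r, spec, tiny_labelled, schedule=[3, 6], folds=3)
        assert len(results) == 1
        assert results[0].cv_accuracy == solo.cv_accuracy
        assert best.method_pair == solo.method_pair

    def test_determinism_end_to_end(self, tiny_labelled):
        r = fscore_rank(tiny_labelled)
        specs = [ClassifierSpec("knn", grid={"n_neighbors": [1, 3]}, seed=2),
                 ClassifierSpec("rfc", grid={"n_estimators": [20]}, seed=2)]
        out1 = sweep(tiny_labelled, [r], specs, schedule=[3, 6], folds=3)
        out2 = sweep(tiny_labelled, [r], specs, schedule=[3, 6], folds=3)
        for a, b in zip(out1[0], out2[0]):
            assert a.cv_accuracy == b.cv_accuracy
        assert out1[1].method_pair == out2[1].method_pair

    def test_empty_inputs_rejected(self, tiny_labelled):
        with pytest.raises(ValueError, match="at least one"):
            sweep(tiny_labelled, [], [], schedule=[2])
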