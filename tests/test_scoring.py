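"""Feature scoring: F-score, CV² baseline fit, PCA importance, overlap."""

import numpy as np
import pytest

from genesieve import (cv2_rank, fscore_rank, pca_rank, rank_genes,
                       topk_overlap, SyntheticConfig, generate)
from genesieve.scoring import fit_cv2_baseline

from conftest import make_matrix

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def fscore_binary_oracle(x, pos_mask):
    """Two-class F-score by direct formula evaluation (scalar loops)."""
    x = np.asarray(x, dtype=float)
    xp, xn = x[pos_mask], x[~pos_mask]
    xbar, pbar, nbar = x.mean(), xp.mean(), xn.mean()
    num = (pbar - xbar) ** 2 + (nbar - xbar) ** 2
    den = (sum((v - pbar) ** 2 for v in xp) / (len(xp) - 1)
           + sum((v - nbar) ** 2 for v in xn) / (len(xn) - 1))
    return num / (den + 1e-12)


def fscore_multiclass_oracle(X, labels):
    """One-vs-rest averaged F-score, one gene at a time."""
    labels = np.asarray(labels)
    classes = list(dict.fromkeys(labels))
    out = []
    for j in range(X.shape[1]):
        per_class = [fscore_binary_oracle(X[:, j], labels == c) for c in classes]
        out.append(np.mean(per_class))
    return np.array(out)


class TestFScore:
    def test_hand_worked_binary_example(self):
        """[1,3] vs [-1,-3]: F = ((2-0)² + (-2-0)²) / (2+2) = 2."""
        m = make_matrix(np.array([[1.0], [3.0], [-1.0], [-3.0]]),
                        labels=["p", "p", "n", "n"])
        r = fscore_rank(m)
        assert r.scores[0] == pytest.approx(2.0, abs=1e-9)

    def test_identical_values_scores_zero_and_excluded(self):
        m = make_matrix(np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0],
                                  [5.0, 9.0]]),
                        labels=["p", "p", "n", "n"])
        r = fscore_rank(m)
        assert r.scores[0] == 0.0
        assert "G0" not in r.ranked_gene_ids
        assert r.n_excluded >= 1

    @pytest.mark.parametrize("n_classes", [2, 3, 4])
    def test_matches_brute_force_oracle(self, n_classes):
        rng = np.random.default_rng(10 + n_classes)
        labels = np.repeat([f"c{i}" for i in range(n_classes)], 4)
        X = rng.normal(size=(len(labels), 6))
        m = make_matrix(X, labels=labels)
        expected = fscore_multiclass_oracle(X, labels)
        np.testing.assert_allclose(fscore_rank(m).scores, expected, atol=1e-10)

    def test_shift_invariant_and_scale_invariant(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 4))
        labels = ["a"] * 6 + ["b"] * 6
        base = fscore_rank(make_matrix(X, labels=labels)).scores
        shifted = fscore_rank(make_matrix(X + 17.0, labels=labels)).scores
        scaled = fscore_rank(make_matrix(X * 3.5, labels=labels)).scores
        np.testing.assert_allclose(shifted, base, rtol=1e-6)
        np.testing.assert_allclose(scaled, base, rtol=1e-6)

    def test_single_class_rejected(self):
        m = make_matrix(np.ones((4, 2)), labels=["a"] * 4)
        with pytest.raises(ValueError, match="two classes"):
            fscore_rank(m)

    def test_perfectly_separating_gene_gets_finite_top_score(self):
        """Zero within-class variance must yield a large finite score."""
        X = np.array([[0.0, 1.0], [0.0, 2.0], [1.0, 1.5], [1.0, 2.5]])
        m = make_matrix(X, labels=["a", "a", "b", "b"])
        r = fscore_rank(m)
        assert np.isfinite(r.scores[0])
        assert r.ranked_gene_ids[0] == "G0"


class TestCV2:
    def test_two_gene_exact_solve(self):
        """(μ, CV²) = (1, 1.1), (10, 0.2) → a1 = 1, a0 = 0.1 exactly."""
        a1, a0 = fit_cv2_baseline(np.array([1.0, 10.0]),
                                  np.array([1.1, 0.2]))
        assert a1 == pytest.approx(1.0, abs=1e-8)
        assert a0 == pytest.approx(0.1, abs=1e-8)

    def test_observed_cv2_matches_two_pass_oracle(self, tiny_labelled):
        _, fit = cv2_rank(tiny_labelled)
        X = tiny_labelled.dense()
        for j in range(X.shape[1]):
            col = X[:, j]
            mu = sum(col) / len(col)
            var = sum((v - mu) ** 2 for v in col) / (len(col) - 1)
            if mu > 0:
                assert fit.cv2[j] == pytest.approx(var / mu**2, abs=1e-10)
                assert fit.mean[j] == pytest.approx(mu, abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_parameter_recovery(self, seed):
        """500 simulated genes at a1=1, a0=0.1 recovered within 10%."""
        rng = np.random.default_rng(seed)
        mu = np.exp(rng.uniform(np.log(0.1), np.log(50), size=500))
        true = 1.0 / mu + 0.1
        shape = 100.0  # ~10% multiplicative gamma noise
        cv2 = true * rng.gamma(shape, 1.0 / shape, size=500)
        a1, a0 = fit_cv2_baseline(mu, cv2)
        assert a1 == pytest.approx(1.0, rel=0.10)
        assert a0 == pytest.approx(0.1, rel=0.10)

    def test_constant_gene_excluded(self):
        rng = np.random.default_rng(2)
        X = rng.poisson(4.0, size=(20, 5)).astype(float)
        X[:, 0] = 3.0
        m = make_matrix(X)
        r, _ = cv2_rank(m)
        assert "G0" not in r.ranked_gene_ids

    def test_zero_mean_gene_skipped_with_warning(self):
        rng = np.random.default_rng(3)
        X = rng.poisson(4.0, size=(20, 5)).astype(float)
        X[:, 1] = 0.0
        with pytest.warns(UserWarning, match="zero-mean"):
            r, _ = cv2_rank(make_matrix(X))
        assert "G1" not in r.ranked_gene_ids

    def test_identical_means_degenerate(self):
        with pytest.raises(ValueError, match="degenerate|identical"):
            fit_cv2_baseline(np.array([2.0, 2.0, 2.0]),
                             np.array([0.5, 0.6, 0.7]))


def pca_importance_oracle(X, n_components):
    """Eigendecomposition of the correlation matrix, no sklearn."""
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    ok = sd > 0
    Z = np.zeros_like(X)
    Z[:, ok] = (X[:, ok] - mu[ok]) / sd[ok]
    C = Z.T @ Z / Z.shape[0]
    w, v = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    evr = w / w.sum()
    return (np.abs(v[:, :n_components]) * evr[:n_components]).sum(axis=1)


class TestPCA:
    def test_constant_gene_scores_zero_and_excluded(self, tiny_labelled):
        X = tiny_labelled.dense().copy()
        X[:, 2] = 8.0
        r = pca_rank(make_matrix(X), n_components=3)
        assert r.scores[2] == 0.0
        assert "G2" not in r.ranked_gene_ids

    def test_dominant_axis_gene_ranked_first(self):
        """The gene most aligned with the dominant latent factor ranks first."""
        rng = np.random.default_rng(8)
        n = 200
        factor = rng.normal(size=n)
        X = rng.normal(0, 1.0, size=(n, 6))
        for j, noise in enumerate([0.05, 0.5, 1.0]):
            X[:, j] = factor + rng.normal(0, noise, n)
        r = pca_rank(make_matrix(X), n_components=1)
        assert r.ranked_gene_ids[:3] == ["G0", "G1", "G2"]

    @pytest.mark.parametrize("n_components", [2, 4])
    def test_matches_eigendecomposition_oracle(self, n_components):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(25, 8)) @ np.diag([3, 2, 1, 1, 0.5, 0.5, 0.2, 0.2])
        expected = pca_importance_oracle(X, n_components)
        got = pca_rank(make_matrix(X), n_components=n_components).scores
        np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_cell_duplication_invariance(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(15, 6))
        r1 = pca_rank(make_matrix(X), n_components=3)
        r2 = pca_rank(make_matrix(np.vstack([X, X]), cell_prefix="D"),
                      n_components=3)
        assert r1.ranked_gene_ids == r2.ranked_gene_ids
        np.testing.assert_allclose(r1.scores, r2.scores, atol=1e-8)

    def test_invalid_component_counts(self, tiny_labelled):
        with pytest.raises(ValueError, match="≥ 1"):
            pca_rank(tiny_labelled, n_components=0)
        with pytest.raises(ValueError, match="min"):
            pca_rank(tiny_labelled, n_components=10_000)


class TestExclusionRule:
    @pytest.mark.parametrize("method", ["fscore", "cv2", "pca"])
    def test_no_ranked_gene_has_nonpositive_score(self, method):
        """Shared rule: every ranked score > 0, on many random inputs."""
        rng = np.random.default_rng(100)
        for _ in range(35):
            n_cells = rng.integers(8, 16)
            n_genes = rng.integers(3, 10)
            X = rng.poisson(rng.uniform(0.5, 6.0), size=(n_cells, n_genes))
            X = X.astype(float)
            labels = np.array(["a", "b"])[rng.integers(0, 2, n_cells)]
            if len(set(labels)) < 2 or min(
                    (labels == "a").sum(), (labels == "b").sum()) < 2:
                continue
            m = make_matrix(X, labels=labels)
            try:
                r = rank_genes(m, method)
            except ValueError:
                continue  # degenerate draw (e.g. identical means)
            pos = {g: i for i, g in enumerate(r.gene_ids)}
            ranked_scores = [r.scores[pos[g]] for g in r.ranked_gene_ids]
            assert all(s > 0 for s in ranked_scores)
            assert ranked_scores == sorted(ranked_scores, reverse=True)

    def test_planted_genes_outrank_null_genes(self):
        """Strong planted markers land above the null-gene 95th percentile."""
        cfg = SyntheticConfig(n_classes=3, cells_per_class=[60] * 3,
                              n_genes=400, n_informative=12,
                              effect_log2fc=2.0, dispersion=5.0, seed=123)
        m, truth = generate(cfg)
        r = fscore_rank(m)
        pos = {g: i for i, g in enumerate(r.gene_ids)}
        planted = set(truth.informative_gene_ids)
        null_scores = [r.scores[pos[g]] for g in r.gene_ids if g not in planted]
        cutoff = np.percentile(null_scores, 95)
        assert all(r.scores[pos[g]] > cutoff for g in planted)


class TestTopkOverlap:
    def _rank(self, method, genes):
        from genesieve.scoring import FeatureRanking
        n = len(genes)
        return FeatureRanking(method=method, gene_ids=list(genes),
                              scores=np.linspace(n, 1, n),
                              ranked_gene_ids=list(genes), n_excluded=0)

    def test_identical_and_disjoint(self):
        genes = [f"g{i}" for i in range(30)]
        same = topk_overlap([self._rank("a", genes), self._rank("b", genes)], 10)
        assert same["pairwise"][("a", "b")] == 10
        other = [f"h{i}" for i in range(30)]
        none = topk_overlap([self._rank("a", genes), self._rank("b", other)], 10)
        assert none["pairwise"][("a", "b")] == 0

    def test_random_permutations_match_set_oracle(self):
        rng = np.random.default_rng(55)
        genes = [f"g{i}" for i in range(1000)]
        ranks = [self._rank(m, list(rng.permutation(genes)))
                 for m in ("x", "y", "z")]
        out = topk_overlap(ranks, 100)
        tops = {r.method: set(r.ranked_gene_ids[:100]) for r in ranks}
        for (a, b), v in out["pairwise"].items():
            assert v == len(tops[a] & tops[b])
        assert out["all"] == len(tops["x"] & tops["y"] & tops["z"])

    def test_validation(self):
        genes = [f"g{i}" for i in range(5)]
        with pytest.raises(ValueError, match="two rankings"):
            topk_overlap([self._rank("a", genes)], 3)
        with pytest.raises(ValueError, match="shortest"):
            topk_overlap([self._rank("a", genes), self._rank("b", genes)], 9)
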