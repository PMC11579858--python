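"""Per-gene importance scoring: F-score, CV² excess variability, PCA loadings.

Each scorer returns a :class:`FeatureRanking` in which genes are sorted by
descending score and every gene with a score ≤ 0 (or an undefined score) has
been excluded — the global exclusion rule all three methods share.

Scores
------
``fscore``
    Ratio of between-class separation of a gene's class means to its summed
    within-class sample variances.  Defined for two classes; for K > 2 classes
    each class is scored one-vs-rest and the per-class scores are averaged
    (``multiclass="mean"``) or maximised (``multiclass="max"``).
``cv2``
    Squared coefficient of variation (variance/mean²) compared against a
    technical-noise baseline CV²(μ) = a1/μ + a0 fitted across genes by a
    gamma GLM with identity link; the importance score is
    log2(observed CV² / fitted CV²), so genes at or below the baseline drop
    out under the exclusion rule.
``pca``
    Sum over leading principal components of |loading| weighted by the
    component's explained-variance ratio, computed on the standardised matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import scipy.sparse as sp

from .io import LabelledExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureRanking",
    "CV2Fit",
    "fscore_rank",
    "cv2_rank",
    "pca_rank",
    "rank_genes",
    "topk_overlap",
    "SCORERS",
]

_EPS = 1e-12  # guards zero within-class variance for perfectly separating genes


@dataclass
class FeatureRanking:
    """Descending per-gene importance ranking from one scoring method."""

    method: str
    gene_ids: list[str]          # all input genes, original order
    scores: np.ndarray           # aligned to gene_ids; NaN = undefined
    ranked_gene_ids: list[str]   # descending score, exclusions applied
    n_excluded: int

    def __len__(self) -> int:
        return len(self.ranked_gene_ids)

    def top(self, k: int) -> list[str]:
        return self.ranked_gene_ids[:k]

    def to_frame(self):
        import pandas as pd

        pos = {g: i for i, g in enumerate(self.gene_ids)}
        return pd.DataFrame({
            "gene_id": self.ranked_gene_ids,
            "score": [self.scores[pos[g]] for g in self.ranked_gene_ids],
            "rank": np.arange(1, len(self.ranked_gene_ids) + 1),
            "method": self.method,
        })


@dataclass
class CV2Fit:
    """Fitted technical-noise baseline CV²(μ) = a1/μ + a0 with per-gene stats."""

    a1: float
    a0: float
    mean: np.ndarray       # per-gene μ
    cv2: np.ndarray        # per-gene observed CV² (NaN where undefined)

    def predict(self, mu: np.ndarray) -> np.ndarray:
        mu = np.asarray(mu, dtype=float)
        return self.a1 / mu + self.a0


def _finalize(method: str, gene_ids: list[str], scores: np.ndarray
              ) -> FeatureRanking:
    """Apply the shared exclusion rule (score ≤ 0 or NaN) and sort descending.

    Ties are broken by input gene order (stable sort) for reproducibility.
    """
    scores = np.asarray(scores, dtype=float)
    valid = np.isfinite(scores) & (scores > 0)
    order = np.argsort(-scores[valid], kind="stable")
    kept = np.where(valid)[0][order]
    return FeatureRanking(
        method=method,
        gene_ids=list(gene_ids),
        scores=scores,
        ranked_gene_ids=[gene_ids[i] for i in kept],
        n_excluded=int((~valid).sum()),
    )


# ---------------------------------------------------------------------------
# F-score
# ---------------------------------------------------------------------------

def _binary_fscores(X: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Vectorised two-class F-score for every gene (column) at once."""
    Xp, Xn = X[pos], X[~pos]
    gmean = X.mean(axis=0)
    mp, mn = Xp.mean(axis=0), Xn.mean(axis=0)
    num = (mp - gmean) ** 2 + (mn - gmean) ** 2
    den = Xp.var(axis=0, ddof=1) + Xn.var(axis=0, ddof=1)
    return num / (den + _EPS)


def fscore_rank(m: LabelledExpressionMatrix, multiclass: str = "mean"
                ) -> FeatureRanking:
    """Rank genes by F-score (one-vs-rest averaged for K > 2 classes).

    Requires at least two classes with at least two cells each.  A gene that
    is constant everywhere scores 0 and is excluded.
    """
    if m.labels is None:
        raise ValueError("labels must be set")
    classes = m.class_names
    if len(classes) < 2:
        raise ValueError("F-score needs at least two classes")
    labels = np.asarray(m.labels)
    for cls in classes:
        if (labels == cls).sum() < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 cells")
    if multiclass not in {"mean", "max"}:
        raise ValueError("multiclass must be 'mean' or 'max'")
    X = m.dense()
    if len(classes) == 2:
        scores = _binary_fscores(X, labels == classes[0])
    else:
        per_class = np.stack([
            _binary_fscores(X, labels == cls) for cls in classes
        ])
        scores = per_class.mean(axis=0) if multiclass == "mean" else per_class.max(axis=0)
    return _finalize("fscore", m.gene_ids, scores)


# ---------------------------------------------------------------------------
# CV²
# ---------------------------------------------------------------------------

def fit_cv2_baseline(mean: np.ndarray, cv2: np.ndarray) -> tuple[float, float]:
    """Fit CV² = a1/μ + a0 across genes with a gamma GLM (identity link).

    Only genes with μ > 0 and CV² > 0 enter the fit.  Falls back to ordinary
    least squares if the IRLS iterations fail on a pathological input.
    """
    import statsmodels.api as sm

    ok = (mean > 0) & np.isfinite(cv2) & (cv2 > 0)
    if ok.sum() < 2:
        raise ValueError("CV² fit needs at least two genes with positive mean and CV²")
    recip = 1.0 / mean[ok]
    if np.allclose(recip, recip[0]):
        raise ValueError("CV² fit is degenerate: all gene means are identical")
    Xd = sm.add_constant(recip)  # columns: [1, 1/μ] → params [a0, a1]
    y = cv2[ok]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, Xd, family=sm.families.Gamma(sm.families.links.Identity())
                         ).fit()
        a0, a1 = float(fit.params[0]), float(fit.params[1])
        if not (np.isfinite(a0) and np.isfinite(a1)):
            raise ValueError("non-finite GLM estimate")
    except Exception:  # pragma: no cover - IRLS failure path
        coef, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        a0, a1 = float(coef[0]), float(coef[1])
    return a1, a0


def cv2_rank(m: LabelledExpressionMatrix) -> tuple[FeatureRanking, CV2Fit]:
    """Rank genes by excess CV² over the fitted technical baseline.

    Importance score = log2(observed CV² / fitted CV²); genes at or below the
    baseline (score ≤ 0), zero-mean genes and constant genes are excluded.
    """
    X = m.dense()
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv2 = np.where(mean > 0, var / np.maximum(mean, 1e-300) ** 2, np.nan)
    n_zero_mean = int((mean <= 0).sum())
    if n_zero_mean:
        warnings.warn(f"{n_zero_mean} zero-mean genes skipped", stacklevel=2)
    a1, a0 = fit_cv2_baseline(mean, cv2)
    fitted = np.full_like(mean, np.nan)
    pos = mean > 0
    fitted[pos] = a1 / mean[pos] + a0
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(
            np.isfinite(cv2) & np.isfinite(fitted) & (cv2 > 0) & (fitted > 0),
            cv2 / fitted, np.nan,
        )
        scores = np.log2(ratio)
    ranking = _finalize("cv2", m.gene_ids, scores)
    return ranking, CV2Fit(a1=a1, a0=a0, mean=mean, cv2=cv2)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_rank(m: LabelledExpressionMatrix, n_components: int | None = None,
             variance_target: float = 0.90) -> FeatureRanking:
    """Rank genes by explained-variance-weighted absolute PCA loadings.

    The matrix is standardised gene-wise (constant genes are zeroed rather
    than propagating a 0/0); importance of gene *i* is
    Σ_j |loading_ij| × EVR_j over the first ``n_components`` components, which
    default to the smallest number covering ``variance_target`` of the
    variance.  Constant genes score 0 and are excluded.
    """
    from sklearn.decomposition import PCA

    if n_components is not None and n_components < 1:
        raise ValueError("n_components must be ≥ 1")
    X = m.dense()
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    constant = sd == 0
    Z = np.zeros_like(X)
    nz = ~constant
    Z[:, nz] = (X[:, nz] - mu[nz]) / sd[nz]
    max_comp = min(m.n_cells, m.n_genes)
    if n_components is not None and n_components > max_comp:
        raise ValueError(f"n_components must be ≤ min(cells, genes) = {max_comp}")
    pca = PCA(n_components=max_comp if n_components is None else n_components,
              svd_solver="full")
    pca.fit(Z)
    evr = pca.explained_variance_ratio_
    if n_components is None:
        n_use = int(np.searchsorted(np.cumsum(evr), variance_target) + 1)
        n_use = min(n_use, len(evr))
    else:
        n_use = n_components
    load = np.abs(pca.components_[:n_use])          # (comps, genes)
    scores = (load * evr[:n_use, None]).sum(axis=0)
    scores[constant] = 0.0
    return _finalize("pca", m.gene_ids, scores)


SCORERS = {"fscore": fscore_rank, "cv2": lambda m: cv2_rank(m)[0], "pca": pca_rank}


def rank_genes(m: LabelledExpressionMatrix, method: str) -> FeatureRanking:
    """Dispatch to one of the registered scorers by name."""
    try:
        fn = SCORERS[method]
    except KeyError:
        raise ValueError(f"unknown scoring method {method!r}; "
                         f"choose from {sorted(SCORERS)}") from None
    return fn(m)


# ---------------------------------------------------------------------------
# top-k overlap
# ---------------------------------------------------------------------------

def topk_overlap(rankings: list[FeatureRanking], k: int) -> dict:
    """Pairwise |top-k ∩ top-k| counts plus the all-way intersection size."""
    if len(rankings) < 2:
        raise ValueError("need at least two rankings")
    if any(k > len(r) for r in rankings):
        raise ValueError("k exceeds the shortest ranking")
    tops = {r.method: set(r.top(k)) for r in rankings}
    out: dict = {"k": k, "pairwise": {}, "all": 0}
    for a, b in combinations(tops, 2):
        out["pairwise"][(a, b)] = len(tops[a] & tops[b])
    inter = set.intersection(*tops.values())
    out["all"] = len(inter)
    return out
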