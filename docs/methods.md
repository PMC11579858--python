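# Methods

## Problem setting

Given a cells × genes count matrix with one class label per cell (a cell
subpopulation annotation), the package selects a compact marker-gene panel
and a classifier that together predict the class of unseen cells. The
workflow is: cell-level quality control → stratified train/test split →
per-gene importance ranking (three scorers) → incremental feature selection
over every scorer × classifier combination → final refit and held-out
evaluation.

## Quality control

A cell is kept when all three hold: detected genes strictly greater than
`min_genes_per_cell` (default 200), total UMIs strictly greater than
`min_umis_per_cell` (default 250), and mitochondrial count fraction strictly
below `max_mito_fraction` (default 0.20). The strict inequalities follow the
conventional reading of "more than … / below …" thresholds; all three are
parameters. Mitochondrial genes are recognised by a case-insensitive gene-id
prefix (default `MT-`) since annotation conventions vary; the prefix is a
parameter. QC is idempotent and never touches the gene set.

The container type accepts any finite numeric matrix, not only counts:
F-score and PCA scoring are well defined on normalised or standardised
expression (which can be negative), and an optional CPM + log1p transform is
offered in the pipeline (`normalize: true`). Non-negativity is enforced where
count semantics genuinely apply — the raw-matrix readers. Raw counts are the
default input to every stage.

## Train/test split

Stratified by class: per-class test counts are `round(class_size ×
test_fraction)` with `test_fraction = 0.2` by default, permutation within
class drawn from a seeded generator. The split seed is derived from the
pipeline seed by a fixed offset (+1) so one seed drives the whole run.

## Gene importance scores

**F-score.** For two classes, the ratio of between-class squared deviations
of the class means from the global mean to the summed within-class sample
variances (1/(n±−1) normalisation). With K > 2 classes each class is scored
one-vs-rest and the K scores averaged; the per-class maximum is available via
`multiclass="max"`. A constant ε = 1e-12 is added to the denominator so a
gene with zero within-class variance but nonzero separation receives a large
finite score instead of dividing by zero. The score is invariant to adding a
constant to a gene and to rescaling it.

**CV² excess variability.** Observed CV² = s²/μ̄² per gene (sample variance,
ddof = 1). The technical baseline CV²(μ) = a₁/μ + a₀ is fitted across genes
by a gamma GLM with identity link (`statsmodels`), the model family used by
the mean–CV² fitting tradition in single-cell work; genes with zero mean or
zero variance are excluded from the fit and from the ranking, with a warning
for zero-mean genes. If the IRLS iterations fail on a pathological input the
fit falls back to ordinary least squares on the same design. The importance
score is log₂(observed/fitted CV²): a gene at or below the technical baseline
scores ≤ 0 and is excluded, so the shared exclusion rule doubles as the
highly-variable-gene cut. All-identical gene means make the design singular
and raise an error naming the condition.

**PCA loading importance.** Genes are standardised (z-score, population SD);
a constant gene would make the z-score 0/0, so its column is set to zero and
its final score to 0 (hence excluded). Importance of gene *i* is
Σⱼ |loadingᵢⱼ| · EVRⱼ over the first n components — by default the smallest
number of components covering 90 % of the variance, otherwise the
`n_components` argument. Duplicating every cell leaves the correlation
structure, and therefore the ranking, unchanged.

**Shared exclusion and ordering.** Every scorer drops genes with score ≤ 0
or undefined, sorts the rest descending, and breaks ties by input gene order
(stable sort) for reproducibility.

## Classifiers and grid search

Four families: k-nearest neighbours, RBF-kernel SVM, random forest, and
gradient-boosted trees (xgboost). Hyperparameters are chosen by exhaustive
grid search under stratified k-fold CV (default 5) with mean accuracy as the
criterion — accuracy because it is the selection target throughout the
workflow; ties go to the first grid point in declaration order. Default
grids (all overridable):

| family  | grid |
|---------|------|
| knn     | k ∈ {1, 5, 15, 31} |
| svm     | C ∈ {0.1, 1, 10}, γ = scale |
| rfc     | trees ∈ {100, 500}, depth ∈ {∞, 10} |
| xgboost | trees ∈ {100, 300}, depth ∈ {3, 6}, η ∈ {0.1, 0.3} |

SVM class probabilities are the softmax of the one-vs-rest decision-function
margins rather than Platt scaling: this guarantees the probability argmax
never disagrees with the uncalibrated decision rule, at the cost of
probabilities that are monotone transforms of margins rather than calibrated
frequencies. Hard predictions for every family are defined as the argmax of
`predict_proba`, making the probability/prediction consistency contract hold
by construction. A single seed drives fold shuffling and all tree
randomness; retraining with the same seed is bit-reproducible
(`n_jobs = 1`, deterministic histogram tree method).

## Incremental feature selection

For each (ranking, classifier) pair, prefixes of the ranking at the sizes in
`schedule` are evaluated by the grid-searched CV accuracy above; folds are
re-drawn identically at every size (same seed, same labels) so curve points
are comparable. "Accuracy no longer improves" is operationalised as patience
stopping: after `patience` (default 3) consecutive sizes without a new
running maximum the size sweep halts. The optimal size is the smallest
evaluated size achieving the maximum (first-maximum rule), and the optimal
gene set is exactly that prefix. The default schedule is a 10-point geometric
grid from 10 to the ranking length; any strictly increasing list can be
passed, and published IFS analyses typically use hand-chosen non-uniform
grids. The sweep over all scorer × classifier pairs returns every result and
a winner: highest optimal CV accuracy, ties resolved toward the smaller
optimal panel (model simplicity), then declaration order.

## Evaluation

Metrics come from the K × K confusion matrix via per-class one-vs-rest
counts: recall = TP/(TP+FN), precision = TP/(TP+FP),
F1 = 2PR/(P+R), macro averages are unweighted class means (macro-F1 is the
mean of per-class F1, not the harmonic mean of macro-P and macro-R), micro
averages are reported alongside. Any 0/0 (e.g. an absent class) is reported
as 0 with a warning so reports never carry NaN. ROC curves are threshold
sweeps on each class's predicted probability; AUC is the trapezoidal area,
which under the implemented tie handling equals the Mann–Whitney
pair-counting probability with ties counted ½. The headline AUC is the macro
(unweighted mean) one-vs-rest AUC.

## Synthetic data generator

Counts are negative-binomial with gene-wise baseline means drawn log-uniform
over `baseline_mean_range` (default 0.1–10, spanning lowly to moderately
expressed genes) and variance μ + μ²/`dispersion` (default size 5, i.e.
strong overdispersion typical of UMI counts). Defaults mirror the structure
of a five-subpopulation breast-tumour atlas: class sizes 773 / 1,184 / 897 /
1,020 / 1,000. `n_informative` genes (default 50) are assigned to classes
round-robin so every class has markers, and each has its mean multiplied by
2^`effect_log2fc` (default 2, a 4-fold shift — a strong but realistic marker
effect) in its class. Optional extra zero-inflation (`dropout_extra`)
thins counts to mimic dropout. Three named fixtures (`tiny`, `default`,
`stress` — the last at full-transcriptome width, 29,733 genes) write the
on-disk triplet format.

The generator deliberately omits gene–gene correlation, batch effects and
doublets; tests passing on it demonstrate the pipeline's mechanics
(ranking, selection, plateau detection, evaluation) and its ability to
recover planted signal under NB noise, not performance on real tissue.

## Numerical and design choices

- F-score denominator ε = 1e-12; CV² fit restricted to genes with μ > 0 and
  CV² > 0; PCA constant-gene score pinned to 0.
- Score ties broken by input order everywhere (stable sorts).
- Orientation of on-disk matrices is auto-detected by matching the barcode
  count; square matrices require an explicit flag.
- Test-set sizes use banker's-free `round()` of class_size × fraction.
- The problem sizes exercised by the test suite and the acceptance script
  (hundreds of cells, hundreds to a few thousand genes) were chosen as the
  smallest scales at which planted-marker recovery is stable across seeds.

## Known limitations

- IFS explores only prefixes of a fixed ranking, not arbitrary subsets; a
  gene that is informative only jointly with another can be missed.
- CV accuracy both selects the subset size and reports performance for the
  sweep; only the final held-out evaluation is unbiased.
- The CV² score presumes count-scale data; applying it after log transforms
  changes its meaning.
- Probability outputs of the SVM are ordinal, not calibrated.
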