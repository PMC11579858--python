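# genesieve

Marker-gene selection and cell-state classification for single-cell
RNA-seq.

Annotating the cell subpopulations of a labelled scRNA-seq atlas — and doing
it with a *small* gene panel rather than the whole transcriptome — is a
recurring need in tumour biology and immunology. `genesieve` addresses it
with a three-stage recipe:

1. **Rank every gene** by one of three importance scores:
   - **F-score** — for gene *i* with class means x̄ᵢ⁺, x̄ᵢ⁻ and global mean
     x̄ᵢ,

     Fᵢ = [ (x̄ᵢ⁺ − x̄ᵢ)² + (x̄ᵢ⁻ − x̄ᵢ)² ] / [ s²ᵢ⁺ + s²ᵢ⁻ ]

     where s²ᵢ± are the within-class sample variances; K > 2 classes are
     handled one-vs-rest and averaged.
   - **CV²** — each gene's squared coefficient of variation σ²/μ² is compared
     with a technical-noise baseline CV²(μ) = a₁/μ + a₀ fitted across genes
     by a gamma GLM (identity link); the score is
     log₂(observed CV² / fitted CV²).
   - **PCA loadings** — Σⱼ |loadingᵢⱼ| · EVRⱼ over the leading principal
     components of the standardised matrix.

   Genes scoring ≤ 0 are excluded from every ranking.
2. **Incremental feature selection (IFS)**: nested prefixes of each ranking
   are evaluated with four classifier families (KNN, RBF-SVM, random forest,
   gradient-boosted trees) under stratified 5-fold cross-validation with
   per-family grid search; the smallest prefix reaching the maximum CV
   accuracy is that combination's optimal gene set, and the sweep over all
   scorer × classifier pairs picks the overall winner (ties favour the
   smaller panel).
3. **Evaluate** the winner on a held-out stratified split: confusion matrix,
   macro precision/recall/F1, one-vs-rest ROC and AUC.

A negative-binomial simulator with planted class-specific markers makes the
whole pipeline testable without downloading any dataset.

## Worked example

```python
import numpy as np
from genesieve import (CellStateClassifier, SplitSpec, SyntheticConfig,
                       generate, split)

# five cell classes × 100 cells, 2,000 genes, 50 planted markers (log2FC 2)
cfg = SyntheticConfig(n_classes=5, cells_per_class=[100] * 5, n_genes=2000,
                      n_informative=50, effect_log2fc=2.0, dispersion=5.0,
                      seed=0)
data, truth = generate(cfg)
train_data, test_data = split(data, SplitSpec(test_fraction=0.2, seed=1))

model = CellStateClassifier(
    train_data, scorers=["fscore"], algorithms=["xgboost"],
    grids={"xgboost": {"n_estimators": [100], "max_depth": [3],
                       "learning_rate": [0.3]}},
    schedule=[10, 50, 250, 1000, 2000], folds=5, seed=0,
)
results = model.fit()
print(results.summary().to_string(index=False))

report = results.evaluate(test_data)
print(report.summary())

recovered = set(results.optimal_gene_ids) & set(truth.informative_gene_ids)
print(f"planted markers recovered: {len(recovered)}/50")
```

Output:

```
scorer algorithm  optimal_size  optimal_cv_accuracy  winner
fscore   xgboost            50               0.9875    True
accuracy        0.9900
macro precision 0.9905
macro recall    0.9900
macro F1        0.9900
macro AUC       0.9991
planted markers recovered: 49/50
```

The IFS curve plateaus at a 50-gene panel (98.75 % CV accuracy on the
training split); that panel contains 49 of the 50 planted markers and
classifies the held-out 100 cells with 99 % accuracy and a macro one-vs-rest
AUC of 0.999.

## Command line

Each stage is also a subcommand of the `genesieve` CLI:

```bash
genesieve simulate --name tiny --out data/           # synthetic fixture
genesieve qc --matrix data --out data_qc             # cell filtering
genesieve rank --matrix data_qc --method fscore --out ranks.tsv
genesieve ifs  --matrix data_qc --method fscore --algorithm xgboost \
               --out curve.tsv
genesieve run-all --config config.yaml               # the whole pipeline
genesieve predict --model run/model_archive --matrix new_data --out pred.tsv
```

`run-all` executes QC → stratified 8:2 split → ranking → IFS sweep → final
refit → held-out evaluation, and writes rankings, IFS curves, the evaluation
report, a serialized model archive and a run manifest; identical
config + seed reproduces every numeric output byte-for-byte.

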