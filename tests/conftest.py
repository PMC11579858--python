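import numpy as np
import pytest

from genesieve import LabelledExpressionMatrix, SyntheticConfig, generate


def make_matrix(counts, labels=None, gene_prefix="G", cell_prefix="C"):
    counts = np.asarray(counts, dtype=float)
    n_cells, n_genes = counts.shape
    return LabelledExpressionMatrix(
        counts=counts,
        gene_ids=[f"{gene_prefix}{j}" for j in range(n_genes)],
        cell_ids=[f"{cell_prefix}{i}" for i in range(n_cells)],
        labels=None if labels is None else np.asarray(labels, dtype=object),
    )


@pytest.fixture
def tiny_labelled():
    """Small 3-class random count matrix, deterministic."""
    rng = np.random.default_rng(42)
    counts = rng.poisson(3.0, size=(30, 20))
    labels = np.repeat(["a", "b", "c"], 10)
    return make_matrix(counts, labels)


@pytest.fixture
def tiny_synthetic():
    """Tiny generator output: 5 classes × 20 cells × 200 genes, 20 planted."""
    cfg = SyntheticConfig(n_classes=5, cells_per_class=[20] * 5, n_genes=200,
                          n_informative=20, effect_log2fc=2.0, dispersion=5.0,
                          seed=7)
    return generate(cfg)
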