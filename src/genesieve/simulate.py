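"""Synthetic scRNA-seq count generator with planted class-discriminative genes.

Counts are negative-binomial: gene-wise baseline means are drawn log-uniform
over ``baseline_mean_range`` and each gene's counts have variance
μ + μ²/dispersion (the size/dispersion parameterisation).  A chosen number of
informative genes is assigned to classes round-robin — so every class carries
markers — and each informative gene's mean is multiplied by
``2**effect_log2fc`` in its assigned class.  Optional extra zero-inflation
mimics dropout.  Everything is deterministic per seed.

This is a test harness emulating the broad structure of labelled tumour
scRNA-seq atlases (a handful of cell classes of several hundred to a thousand
cells, sparse non-negative counts, a minority of class-discriminative genes);
it makes no claim to realistic gene–gene correlation, batch structure or
doublets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .io import LabelledExpressionMatrix, write_matrix

__all__ = ["SyntheticConfig", "GroundTruth", "generate", "make_fixture",
           "FIXTURES"]

# class inventory mirroring a five-subpopulation breast-tumour atlas
_DEFAULT_CELLS = [773, 1184, 897, 1020, 1000]
_DEFAULT_CLASS_NAMES = ["B-cells", "CancerEpithelial", "Myeloid",
                        "Plasmablasts", "T-cells"]


@dataclass
class SyntheticConfig:
    """Full parameterisation of the ground-truth generator."""

    n_classes: int = 5
    cells_per_class: list[int] = field(default_factory=lambda: list(_DEFAULT_CELLS))
    n_genes: int = 2000
    n_informative: int = 50
    effect_log2fc: float = 2.0
    baseline_mean_range: tuple[float, float] = (0.1, 10.0)
    dispersion: float = 5.0
    dropout_extra: float = 0.0
    seed: int = 0
    class_names: list[str] | None = None

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be ≥ 2")
        if len(self.cells_per_class) != self.n_classes:
            raise ValueError("cells_per_class length must equal n_classes")
        if any(c < 1 for c in self.cells_per_class):
            raise ValueError("cells_per_class entries must be ≥ 1")
        if not 0 < self.n_genes:
            raise ValueError("n_genes must be positive")
        if not 0 <= self.n_informative <= self.n_genes:
            raise ValueError("n_informative must be in [0, n_genes]")
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc must be ≥ 0")
        lo, hi = self.baseline_mean_range
        if not 0 < lo <= hi:
            raise ValueError("baseline_mean_range must be a positive interval")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not 0 <= self.dropout_extra < 1:
            raise ValueError("dropout_extra must be in [0, 1)")
        if self.class_names is None:
            if self.n_classes == len(_DEFAULT_CLASS_NAMES):
                self.class_names = list(_DEFAULT_CLASS_NAMES)
            else:
                self.class_names = [f"class{i}" for i in range(self.n_classes)]
        elif len(self.class_names) != self.n_classes:
            raise ValueError("class_names length must equal n_classes")


@dataclass
class GroundTruth:
    """What the generator planted: which genes discriminate which class."""

    informative_gene_ids: list[str]
    class_of_gene: dict[str, str]
    true_labels: np.ndarray


def generate(cfg: SyntheticConfig | None = None
             ) -> tuple[LabelledExpressionMatrix, GroundTruth]:
    """Draw one labelled count matrix plus its ground truth."""
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    n_cells = sum(cfg.cells_per_class)
    gene_ids = [f"GENE{j:05d}" for j in range(cfg.n_genes)]
    cell_ids = [f"CELL{i:05d}" for i in range(n_cells)]
    labels = np.repeat(cfg.class_names, cfg.cells_per_class).astype(object)

    lo, hi = cfg.baseline_mean_range
    base_mean = np.exp(rng.uniform(np.log(lo), np.log(hi), size=cfg.n_genes))

    # round-robin class assignment of informative genes
    informative = list(range(cfg.n_informative))
    class_of = {gene_ids[j]: cfg.class_names[j % cfg.n_classes]
                for j in informative}

    mean = np.tile(base_mean, (n_cells, 1))
    fold = 2.0 ** cfg.effect_log2fc
    for j in informative:
        mask = labels == class_of[gene_ids[j]]
        mean[mask, j] *= fold

    r = cfg.dispersion
    p = r / (r + mean)
    counts = rng.negative_binomial(r, p)
    if cfg.dropout_extra > 0:
        keep = rng.random(counts.shape) >= cfg.dropout_extra
        counts = counts * keep

    m = LabelledExpressionMatrix(
        counts=sp.csr_matrix(counts), gene_ids=gene_ids,
        cell_ids=cell_ids, labels=labels,
    )
    truth = GroundTruth(
        informative_gene_ids=[gene_ids[j] for j in informative],
        class_of_gene=class_of,
        true_labels=labels.copy(),
    )
    return m, truth


FIXTURES: dict[str, SyntheticConfig] = {
    # 5 classes × 20 cells × 200 genes: fast enough for CI round-trips
    "tiny": SyntheticConfig(
        n_classes=5, cells_per_class=[20] * 5, n_genes=200, n_informative=20,
        effect_log2fc=2.0, dispersion=5.0, seed=0,
    ),
    # mirrors the five-subpopulation atlas inventory
    "default": SyntheticConfig(
        n_classes=5, cells_per_class=list(_DEFAULT_CELLS), n_genes=2000,
        n_informative=50, effect_log2fc=2.0, dispersion=5.0, seed=0,
    ),
    # full transcriptome width for scaling tests
    "stress": SyntheticConfig(
        n_classes=5, cells_per_class=list(_DEFAULT_CELLS), n_genes=29733,
        n_informative=100, effect_log2fc=2.0, dispersion=5.0, seed=0,
    ),
}


def make_fixture(name: str, out_dir: str | Path,
                 seed: int | None = None) -> Path:
    """Write a named fixture dataset as an MTX triplet plus labels TSV.

    Returns the directory containing ``matrix.mtx``, ``genes.tsv``,
    ``barcodes.tsv`` and ``labels.tsv``.
    """
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
    cfg = FIXTURES[name]
    if seed is not None:
        cfg = SyntheticConfig(**{**cfg.__dict__, "seed": seed})
    m, _ = generate(cfg)
    out_dir = Path(out_dir)
    write_matrix(m, out_dir, format="mtx_triplet")
    return out_dir
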