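"""Reading, writing, quality control and splitting of labelled expression matrices.

The universal in-memory container is :class:`LabelledExpressionMatrix`: a
cells × genes non-negative count matrix (dense or CSR sparse) with ordered
gene/cell identifiers and, optionally, one class label per cell.  Two on-disk
dialects are supported: the 10x-style Matrix Market triplet
(``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv``) and a dense CSV/TSV with a
gene-id header row and a barcode first column.  Labels travel in a separate
two-column TSV (barcode, label).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

__all__ = [
    "LabelledExpressionMatrix",
    "QCParams",
    "QCReport",
    "SplitSpec",
    "read_matrix",
    "write_matrix",
    "read_labels",
    "attach_labels",
    "apply_qc",
    "split",
]


class FormatError(ValueError):
    """Raised when on-disk files are inconsistent or unparseable."""


@dataclass
class LabelledExpressionMatrix:
    """Cells × genes count matrix with identifiers and optional class labels.

    Parameters
    ----------
    counts
        Non-negative numeric matrix, shape ``(n_cells, n_genes)``; dense
        ndarray or scipy sparse (stored as CSR).
    gene_ids, cell_ids
        Ordered, unique identifier lists matching the matrix axes.
    labels
        Per-cell class label (one string per cell), or ``None`` when unset.
    """

    counts: np.ndarray | sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if sp.issparse(self.counts):
            self.counts = sp.csr_matrix(self.counts)
        else:
            self.counts = np.asarray(self.counts)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        n_cells, n_genes = self.counts.shape
        if n_cells != len(self.cell_ids):
            raise ValueError(
                f"counts has {n_cells} rows but {len(self.cell_ids)} cell_ids"
            )
        if n_genes != len(self.gene_ids):
            raise ValueError(
                f"counts has {n_genes} columns but {len(self.gene_ids)} gene_ids"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene_ids")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell_ids")
        # negative values are tolerated so the container can also hold
        # normalised / standardised expression; raw count readers enforce ≥ 0
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != n_cells:
                raise ValueError("labels length must equal number of cells")

    # -- basic properties ---------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def class_names(self) -> list[str]:
        """Label values in order of first appearance; empty if labels unset."""
        if self.labels is None:
            return []
        return list(pd.unique(self.labels))

    def dense(self) -> np.ndarray:
        """Counts as a dense float array."""
        if sp.issparse(self.counts):
            return self.counts.toarray().astype(float)
        return np.asarray(self.counts, dtype=float)

    # -- slicing ------------------------------------------------------------
    def subset_cells(self, idx: np.ndarray) -> "LabelledExpressionMatrix":
        idx = np.asarray(idx)
        return LabelledExpressionMatrix(
            counts=self.counts[idx],
            gene_ids=self.gene_ids,
            cell_ids=[self.cell_ids[i] for i in idx],
            labels=None if self.labels is None else self.labels[idx],
        )

    def subset_genes(self, gene_ids: list[str]) -> "LabelledExpressionMatrix":
        pos = {g: j for j, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in pos]
        if missing:
            raise KeyError(f"genes not present: {missing[:10]}")
        cols = np.array([pos[g] for g in gene_ids])
        counts = self.counts[:, cols]
        return LabelledExpressionMatrix(
            counts=counts, gene_ids=list(gene_ids),
            cell_ids=self.cell_ids, labels=self.labels,
        )

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (cells as obs, genes as var)."""
        import anndata as ad

        obs = pd.DataFrame(index=self.cell_ids)
        if self.labels is not None:
            obs["label"] = self.labels
        return ad.AnnData(
            X=self.counts.copy(), obs=obs, var=pd.DataFrame(index=self.gene_ids)
        )

    @classmethod
    def from_anndata(cls, adata, label_key: str | None = "label"):
        labels = None
        if label_key is not None and label_key in adata.obs:
            labels = np.asarray(adata.obs[label_key], dtype=object)
        return cls(
            counts=adata.X,
            gene_ids=list(adata.var_names),
            cell_ids=list(adata.obs_names),
            labels=labels,
        )


@dataclass
class QCParams:
    """Cell-level quality-control thresholds.

    A cell is kept when it has strictly more than ``min_genes_per_cell``
    detected genes, strictly more than ``min_umis_per_cell`` total UMIs, and a
    mitochondrial count fraction strictly below ``max_mito_fraction``.
    Mitochondrial genes are recognised by a case-insensitive id prefix.
    """

    min_genes_per_cell: int = 200
    min_umis_per_cell: int = 250
    max_mito_fraction: float = 0.20
    mito_gene_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if self.min_genes_per_cell <= 0 or self.min_umis_per_cell <= 0:
            raise ValueError("QC thresholds must be > 0")
        if not 0 < self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must be in (0, 1]")


@dataclass
class QCReport:
    n_input: int
    n_kept: int
    n_fail_genes: int
    n_fail_umis: int
    n_fail_mito: int


@dataclass
class SplitSpec:
    """Train/test split parameterisation (default 8:2, stratified)."""

    test_fraction: float = 0.2
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_id_file(path: Path, what: str) -> list[str]:
    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            # 10x genes.tsv may carry a second symbol column; first field is the id
            ids.append(line.split("\t")[0])
    if not ids:
        raise FormatError(f"{what} file {path} is empty")
    return ids


def read_matrix(path: str | Path, format: str = "mtx_triplet",
                cells_on_rows: bool | None = None) -> LabelledExpressionMatrix:
    """Read an expression matrix from disk (labels unset).

    Parameters
    ----------
    path
        For ``mtx_triplet``: a directory containing ``matrix.mtx``,
        ``genes.tsv`` and ``barcodes.tsv``.  For ``dense_csv``: a CSV/TSV file
        whose header row holds gene ids and whose first column holds barcodes.
    format
        ``"mtx_triplet"`` or ``"dense_csv"``.
    cells_on_rows
        Orientation override for square matrices where auto-detection by
        barcode count is ambiguous.

    Returns
    -------
    LabelledExpressionMatrix
        Orientation normalised to cells × genes regardless of on-disk layout.
    """
    path = Path(path)
    if format == "mtx_triplet":
        mtx_path = path / "matrix.mtx"
        genes_path = path / "genes.tsv"
        barcodes_path = path / "barcodes.tsv"
        for p in (mtx_path, genes_path, barcodes_path):
            if not p.exists():
                raise FileNotFoundError(p)
        mat = sp.csr_matrix(mmread(mtx_path))
        genes = _read_id_file(genes_path, "genes")
        barcodes = _read_id_file(barcodes_path, "barcodes")
        nr, nc = mat.shape
        if nr == nc:
            if cells_on_rows is None:
                raise FormatError(
                    "square matrix: pass cells_on_rows explicitly to fix orientation"
                )
            rows_are_cells = cells_on_rows
        elif nr == len(barcodes) and nc == len(genes):
            rows_are_cells = True
        elif nc == len(barcodes) and nr == len(genes):
            rows_are_cells = False
        else:
            raise FormatError(
                f"dimension mismatch in {path}: matrix.mtx is {nr}×{nc} but "
                f"genes.tsv has {len(genes)} entries and barcodes.tsv has "
                f"{len(barcodes)}"
            )
        if not rows_are_cells:
            mat = sp.csr_matrix(mat.T)
        if mat.shape != (len(barcodes), len(genes)):
            bad = "genes.tsv" if mat.shape[1] != len(genes) else "barcodes.tsv"
            raise FormatError(f"dimension mismatch in {path}: check {bad}")
        if mat.nnz and mat.data.min() < 0:
            raise FormatError(f"negative count in {mtx_path}")
        return LabelledExpressionMatrix(mat, genes, barcodes)

    if format == "dense_csv":
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
            counts = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise FormatError(f"non-numeric entry in {path}: {exc}") from exc
        return LabelledExpressionMatrix(
            counts, list(df.columns), list(df.index.astype(str))
        )

    raise ValueError(f"unknown format {format!r}")


def write_matrix(m: LabelledExpressionMatrix, path: str | Path,
                 format: str = "mtx_triplet") -> None:
    """Write a matrix (and labels, if set) in one of the supported dialects."""
    path = Path(path)
    if format == "mtx_triplet":
        path.mkdir(parents=True, exist_ok=True)
        counts = m.counts if sp.issparse(m.counts) else sp.coo_matrix(m.counts)
        mmwrite(path / "matrix.mtx", counts)
        (path / "genes.tsv").write_text("\n".join(m.gene_ids) + "\n")
        (path / "barcodes.tsv").write_text("\n".join(m.cell_ids) + "\n")
        if m.labels is not None:
            write_labels(m, path / "labels.tsv")
    elif format == "dense_csv":
        df = pd.DataFrame(m.dense(), index=m.cell_ids, columns=m.gene_ids)
        df.to_csv(path)
    else:
        raise ValueError(f"unknown format {format!r}")


def write_labels(m: LabelledExpressionMatrix, path: str | Path) -> None:
    if m.labels is None:
        raise ValueError("labels unset")
    pd.DataFrame({"barcode": m.cell_ids, "label": m.labels}).to_csv(
        path, sep="\t", index=False, header=False
    )


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column (barcode, label) TSV; a header row is auto-skipped."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"labels file {path} needs two tab-separated columns")
    first = str(df.iloc[0, 0]).lower()
    if first in {"barcode", "cell", "cell_id", "barcodes"}:
        df = df.iloc[1:]
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, dtype=object)


def attach_labels(m: LabelledExpressionMatrix, labels: pd.Series
                  ) -> LabelledExpressionMatrix:
    """Attach per-cell labels, matched by barcode."""
    missing = [c for c in m.cell_ids if c not in labels.index]
    if missing:
        raise ValueError(f"labels missing for {len(missing)} cells, e.g. {missing[:5]}")
    lab = np.asarray(labels.loc[m.cell_ids].values, dtype=object)
    return LabelledExpressionMatrix(m.counts, m.gene_ids, m.cell_ids, lab)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def apply_qc(m: LabelledExpressionMatrix, q: QCParams | None = None,
             return_report: bool = False):
    """Filter cells by detected genes, total UMIs and mitochondrial fraction.

    Keeps cells with ``detected genes > min_genes_per_cell`` AND
    ``UMIs > min_umis_per_cell`` AND ``mito fraction < max_mito_fraction``.
    The gene set is unchanged.  Idempotent.
    """
    q = q or QCParams()
    counts = m.counts
    if sp.issparse(counts):
        detected = np.asarray((counts > 0).sum(axis=1)).ravel()
        umis = np.asarray(counts.sum(axis=1)).ravel()
    else:
        detected = (counts > 0).sum(axis=1)
        umis = counts.sum(axis=1)
    prefix = q.mito_gene_prefix.lower()
    mito_cols = np.array(
        [g.lower().startswith(prefix) for g in m.gene_ids], dtype=bool
    )
    if mito_cols.any():
        sub = counts[:, np.where(mito_cols)[0]]
        mito_counts = np.asarray(sub.sum(axis=1)).ravel()
    else:
        mito_counts = np.zeros(m.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(umis > 0, mito_counts / np.maximum(umis, 1e-300), 0.0)

    pass_genes = detected > q.min_genes_per_cell
    pass_umis = umis > q.min_umis_per_cell
    pass_mito = mito_frac < q.max_mito_fraction
    keep = pass_genes & pass_umis & pass_mito

    report = QCReport(
        n_input=m.n_cells,
        n_kept=int(keep.sum()),
        n_fail_genes=int((~pass_genes).sum()),
        n_fail_umis=int((~pass_umis).sum()),
        n_fail_mito=int((~pass_mito).sum()),
    )
    logger.info(
        "QC: kept %d/%d cells (failed genes: %d, UMIs: %d, mito: %d)",
        report.n_kept, report.n_input, report.n_fail_genes,
        report.n_fail_umis, report.n_fail_mito,
    )
    if report.n_kept == 0:
        warnings.warn("QC removed every cell", stacklevel=2)
    out = m.subset_cells(np.where(keep)[0])
    return (out, report) if return_report else out


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split(m: LabelledExpressionMatrix, s: SplitSpec | None = None
          ) -> tuple[LabelledExpressionMatrix, LabelledExpressionMatrix]:
    """Partition cells into train/test sets, stratified by class by default.

    Per-class test counts are ``round(class_size × test_fraction)`` under
    stratification; deterministic for a fixed seed.
    """
    s = s or SplitSpec()
    if m.labels is None:
        raise ValueError("labels must be set before splitting")
    rng = np.random.default_rng(s.seed)
    labels = np.asarray(m.labels)
    test_idx: list[int] = []
    if s.stratified:
        for cls in m.class_names:
            cls_idx = np.where(labels == cls)[0]
            if len(cls_idx) < 2:
                raise ValueError(
                    f"class {cls!r} has {len(cls_idx)} cell(s); stratified "
                    "splitting needs at least 2 per class"
                )
            n_test = int(round(len(cls_idx) * s.test_fraction))
            perm = rng.permutation(cls_idx)
            test_idx.extend(perm[:n_test].tolist())
    else:
        n_test = int(round(m.n_cells * s.test_fraction))
        perm = rng.permutation(m.n_cells)
        test_idx = perm[:n_test].tolist()
    test_mask = np.zeros(m.n_cells, dtype=bool)
    test_mask[test_idx] = True
    train = m.subset_cells(np.where(~test_mask)[0])
    test = m.subset_cells(np.where(test_mask)[0])
    logger.info("split: %d train / %d test cells", train.n_cells, test.n_cells)
    return train, test
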