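"""Expression matrix I/O and cross-dataset preprocessing.

Matrices travel as :class:`AnnotatedMatrix`: a cells x genes array with
cell/gene identifiers and an optional per-cell label column.  Readers
cover MatrixMarket triplets (with companion row/column name files), dense
CSV/TSV, and the AnnData ``.h5ad`` container.

Cross-dataset preprocessing follows three rules: keep only genes shared
by training and test sets, log-transform counts, and drop the genes with
the highest and lowest 1% mean log expression.  The trim statistic is fit
on the training set alone and applied to both, avoiding leakage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = ["AnnotatedMatrix", "read_matrix", "write_matrix", "preprocess", "align_to_genes"]


@dataclass
class AnnotatedMatrix:
    """Cells x genes matrix with identifiers and optional labels."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    labels: list[str] | None = None
    log_transformed: bool = False

    def __post_init__(self) -> None:
        if sp.issparse(self.values):
            self.values = np.asarray(self.values.todense())
        self.values = np.asarray(self.values, dtype=float)
        n_cells, n_genes = self.values.shape
        if len(self.cell_ids) != n_cells:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n_cells} rows")
        if len(self.gene_ids) != n_genes:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {n_genes} columns")
        dupes = _duplicates(self.gene_ids)
        if dupes:
            raise ValueError(f"duplicate gene ids: {sorted(dupes)}")
        if self.labels is not None and len(self.labels) != n_cells:
            raise ValueError("label count does not match cell count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Sequence[str]) -> "AnnotatedMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [index[g] for g in genes]
        return replace(self, values=self.values[:, idx], gene_ids=list(genes))


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for x in items:
        if x in seen:
            dupes.add(x)
        seen.add(x)
    return dupes


def _read_names(path: Path) -> list[str]:
    return [line.strip() for line in path.read_text().splitlines() if line.strip()]


def read_matrix(
    path: str | Path,
    fmt: str | None = None,
    cells_path: str | Path | None = None,
    genes_path: str | Path | None = None,
) -> AnnotatedMatrix:
    """Read an expression matrix.

    ``fmt`` is inferred from the extension when omitted: ``.mtx``
    (requires companion name files, defaulting to ``<stem>_cells.txt`` /
    ``<stem>_genes.txt``), ``.csv``/``.tsv`` dense with genes as header
    and cell ids as first column, or ``.h5ad``.
    """
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".")
    if fmt == "mtx":
        cells_path = Path(cells_path) if cells_path else path.with_name(path.stem + "_cells.txt")
        genes_path = Path(genes_path) if genes_path else path.with_name(path.stem + "_genes.txt")
        mat = scipy.io.mmread(str(path)).tocsr()
        cell_ids = _read_names(cells_path)
        gene_ids = _read_names(genes_path)
        if mat.shape != (len(cell_ids), len(gene_ids)):
            raise ValueError(
                f"matrix shape {mat.shape} does not match name files "
                f"({len(cell_ids)} cells, {len(gene_ids)} genes)"
            )
        return AnnotatedMatrix(values=mat, cell_ids=cell_ids, gene_ids=gene_ids)
    if fmt in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if fmt == "csv" else "\t", index_col=0)
        return AnnotatedMatrix(
            values=df.to_numpy(dtype=float),
            cell_ids=[str(i) for i in df.index],
            gene_ids=[str(c) for c in df.columns],
        )
    if fmt in ("h5ad", "h5"):
        import anndata

        adata = anndata.read_h5ad(path)
        labels = (
            [str(x) for x in adata.obs["label"]] if "label" in adata.obs.columns else None
        )
        values = adata.X
        if sp.issparse(values):
            values = values.toarray()
        return AnnotatedMatrix(
            values=np.asarray(values),
            cell_ids=[str(i) for i in adata.obs_names],
            gene_ids=[str(g) for g in adata.var_names],
            labels=labels,
        )
    raise ValueError(f"unsupported format: {fmt!r}")


def write_matrix(matrix: AnnotatedMatrix, path: str | Path, fmt: str | None = None) -> None:
    """Write a matrix as MTX triplet (+ name files), dense CSV/TSV, or h5ad."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".")
    if fmt == "mtx":
        scipy.io.mmwrite(str(path), sp.csr_array(matrix.values))
        path.with_name(path.stem + "_cells.txt").write_text("\n".join(matrix.cell_ids) + "\n")
        path.with_name(path.stem + "_genes.txt").write_text("\n".join(matrix.gene_ids) + "\n")
        return
    if fmt in ("csv", "tsv"):
        df = pd.DataFrame(matrix.values, index=matrix.cell_ids, columns=matrix.gene_ids)
        df.to_csv(path, sep="," if fmt == "csv" else "\t")
        return
    if fmt in ("h5ad", "h5"):
        import anndata

        adata = anndata.AnnData(
            X=matrix.values,
            obs=pd.DataFrame(index=matrix.cell_ids),
            var=pd.DataFrame(index=matrix.gene_ids),
        )
        if matrix.labels is not None:
            adata.obs["label"] = matrix.labels
        adata.write_h5ad(path)
        return
    raise ValueError(f"unsupported format: {fmt!r}")


def preprocess(
    train: AnnotatedMatrix,
    test: AnnotatedMatrix,
    trim_frac: float = 0.01,
) -> tuple[AnnotatedMatrix, AnnotatedMatrix]:
    """Shared-gene intersection, log1p transform and extreme-gene trimming.

    Genes are intersected (training order kept), counts become
    ``log(1 + count)``, then the ``trim_frac`` fraction of genes with the
    highest and with the lowest mean log expression *in the training set*
    are removed from both matrices.  Boundary ties resolve by gene-id
    order.  Idempotent up to the log transform, which is guarded by the
    ``log_transformed`` flag.
    """
    if not 0 <= trim_frac < 0.5:
        raise ValueError("trim_frac must be in [0, 0.5)")
    shared = [g for g in train.gene_ids if g in set(test.gene_ids)]
    if not shared:
        raise ValueError("training and test sets share no genes")
    tr = train.subset_genes(shared)
    te = test.subset_genes(shared)

    def logged(m: AnnotatedMatrix) -> AnnotatedMatrix:
        if m.log_transformed:
            return m
        if np.any(m.values < 0):
            raise ValueError("negative values: expected raw counts before log transform")
        return replace(m, values=np.log1p(m.values), log_transformed=True)

    tr, te = logged(tr), logged(te)

    n_trim = int(len(shared) * trim_frac)
    if n_trim > 0:
        means = tr.values.mean(axis=0)
        # order by mean expression; ties by gene id for determinism
        order = np.lexsort((np.asarray(tr.gene_ids), means))
        drop = set(order[:n_trim]) | set(order[-n_trim:])
        keep = [g for i, g in enumerate(tr.gene_ids) if i not in drop]
        tr = tr.subset_genes(keep)
        te = te.subset_genes(keep)
    return tr, te


def align_to_genes(matrix: AnnotatedMatrix, gene_order: Sequence[str]) -> AnnotatedMatrix:
    """Align a matrix to a model's gene vocabulary.

    Genes missing from the input are zero-filled; extra genes are dropped.
    """
    gene_order = list(gene_order)
    index = {g: i for i, g in enumerate(matrix.gene_ids)}
    missing = [g for g in gene_order if g not in index]
    if missing:
        warnings.warn(f"{len(missing)} model genes absent from input; zero-filled")
    out = np.zeros((matrix.shape[0], len(gene_order)))
    for j, g in enumerate(gene_order):
        if g in index:
            out[:, j] = matrix.values[:, index[g]]
    return replace(matrix, values=out, gene_ids=gene_order)
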