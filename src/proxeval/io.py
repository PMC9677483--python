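"""Data model and readers/writers for count matrices, labels and benchmark results.

The central container is :class:`ExpressionDataset`, a cells × genes count
matrix with cell identifiers, gene names, optional ground-truth labels and an
optional mitochondrial-gene mask.  Counts are held sparse (CSR) throughout and
densified only where an individual operation requires it.

Supported on-disk formats
-------------------------
* Matrix Market ``.mtx`` with ``barcodes.tsv`` / ``genes.tsv`` sidecars
  (10x-style files are genes × cells; pass ``transpose=True``).
* Dense CSV with a header row (gene names) and an index column (cell ids).
* Labels CSV with columns ``cell_id,label``.
* Tidy benchmark results CSV (one row per metric/k/seed) via
  :class:`ResultTable`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "ExpressionDataset",
    "ResultTable",
    "read_dataset",
    "write_dataset",
    "read_labels",
    "write_results",
    "read_results",
]


def _as_csr(matrix) -> sp.csr_matrix:
    if sp.issparse(matrix):
        out = matrix.tocsr().astype(np.float64)
    else:
        out = sp.csr_matrix(np.asarray(matrix, dtype=np.float64))
    out.eliminate_zeros()
    return out


@dataclass
class ExpressionDataset:
    """A cells × genes expression matrix plus annotations.

    Parameters
    ----------
    counts
        Non-negative matrix, cells in rows, genes in columns.  Stored sparse.
    cell_ids, gene_names
        Unique string identifiers for rows and columns.
    labels
        Optional per-cell ground-truth category (cell type / cluster).
    mito_mask
        Optional boolean per-gene mask marking mitochondrial genes.
    space
        Which value space the matrix currently lives in:
        ``raw`` (counts), ``normalized`` (log1p of scaled counts),
        ``proportions`` (total-count scaled, pre-log) or ``binary``.
    """

    counts: sp.csr_matrix
    cell_ids: np.ndarray
    gene_names: np.ndarray
    labels: Optional[np.ndarray] = None
    mito_mask: Optional[np.ndarray] = None
    space: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = _as_csr(self.counts)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
        if self.mito_mask is not None:
            self.mito_mask = np.asarray(self.mito_mask, dtype=bool)
        self.validate()

    # -- contracts ---------------------------------------------------------
    def validate(self) -> None:
        n, g = self.counts.shape
        data = self.counts.data
        if data.size and (not np.all(np.isfinite(data)) or data.min() < 0):
            raise ValueError("counts must be finite and non-negative")
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} rows")
        if len(self.gene_names) != g:
            raise ValueError(f"{len(self.gene_names)} gene names for {g} columns")
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell ids")
        if len(set(self.gene_names)) != g:
            raise ValueError("duplicate gene names")
        if self.labels is not None and len(self.labels) != n:
            raise ValueError("labels must have one entry per cell")
        if self.mito_mask is not None and len(self.mito_mask) != g:
            raise ValueError("mito_mask must have one entry per gene")

    # -- basic views -------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def sparsity(self) -> float:
        """Fraction of exactly-zero entries."""
        return 1.0 - self.counts.nnz / (self.n_cells * self.n_genes)

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def subset_cells(self, idx) -> "ExpressionDataset":
        idx = np.asarray(idx)
        return replace(
            self,
            counts=self.counts[idx],
            cell_ids=self.cell_ids[idx],
            labels=None if self.labels is None else self.labels[idx],
            meta=dict(self.meta),
        )

    def subset_genes(self, idx) -> "ExpressionDataset":
        idx = np.asarray(idx)
        return replace(
            self,
            counts=self.counts[:, idx],
            gene_names=self.gene_names[idx],
            mito_mask=None if self.mito_mask is None else self.mito_mask[idx],
            meta=dict(self.meta),
        )

    def with_counts(self, counts, space: Optional[str] = None) -> "ExpressionDataset":
        return replace(self, counts=_as_csr(counts), space=space or self.space,
                       meta=dict(self.meta))

    def to_anndata(self):
        """Convenience export to an :class:`anndata.AnnData`."""
        import anndata as ad

        obs = pd.DataFrame(index=pd.Index(self.cell_ids.astype(str), name="cell_id"))
        if self.labels is not None:
            obs["label"] = pd.Categorical(self.labels.astype(str))
        var = pd.DataFrame(index=pd.Index(self.gene_names.astype(str), name="gene"))
        if self.mito_mask is not None:
            var["mito"] = self.mito_mask
        return ad.AnnData(X=self.counts.copy(), obs=obs, var=var)


def _default_mito_mask(gene_names: np.ndarray, mito_prefix: str) -> np.ndarray:
    prefix = mito_prefix.lower()
    return np.array([str(g).lower().startswith(prefix) for g in gene_names], dtype=bool)


def read_labels(path: str | os.PathLike, cell_ids: Sequence[str]) -> np.ndarray:
    """Read a ``cell_id,label`` CSV and align it to ``cell_ids``.

    Raises
    ------
    ValueError
        If any cell id in the dataset is missing from the file, or the file
        references unknown cells.
    """
    df = pd.read_csv(path, dtype=str)
    if not {"cell_id", "label"} <= set(df.columns):
        raise ValueError(f"labels file {path} must have columns cell_id,label")
    mapping = dict(zip(df["cell_id"], df["label"]))
    cells = [str(c) for c in cell_ids]
    missing = [c for c in cells if c not in mapping]
    if missing:
        raise ValueError(f"labels file missing cells: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    unknown = set(mapping) - set(cells)
    if unknown:
        raise ValueError(f"labels reference unknown cell ids: {sorted(unknown)[:5]}")
    return np.array([mapping[c] for c in cells], dtype=object)


def read_dataset(
    counts_path: str | os.PathLike,
    format: Optional[str] = None,
    labels_path: Optional[str | os.PathLike] = None,
    mito_prefix: str = "MT-",
    transpose: bool = False,
    barcodes_path: Optional[str | os.PathLike] = None,
    genes_path: Optional[str | os.PathLike] = None,
) -> ExpressionDataset:
    """Read a count matrix (MTX + sidecars, or dense CSV) into a dataset.

    The internal orientation is always cells × genes; set ``transpose=True``
    for genes × cells files (the common 10x MTX dialect).  The orientation is
    never guessed.
    """
    counts_path = Path(counts_path)
    if not counts_path.exists():
        raise FileNotFoundError(counts_path)
    if format is None:
        format = "mtx" if counts_path.suffix == ".mtx" else "csv"

    if format == "mtx":
        barcodes_path = Path(barcodes_path or counts_path.with_name("barcodes.tsv"))
        genes_path = Path(genes_path or counts_path.with_name("genes.tsv"))
        for p in (barcodes_path, genes_path):
            if not p.exists():
                raise FileNotFoundError(f"MTX sidecar not found: {p}")
        matrix = sp.csr_matrix(mmread(counts_path))
        if transpose:
            matrix = matrix.T.tocsr()
        cell_ids = pd.read_csv(barcodes_path, header=None, sep="\t")[0].astype(str).to_numpy()
        gene_names = pd.read_csv(genes_path, header=None, sep="\t")[0].astype(str).to_numpy()
        if matrix.shape != (len(cell_ids), len(gene_names)):
            raise ValueError(
                f"matrix shape {matrix.shape} does not match "
                f"{len(cell_ids)} barcodes x {len(gene_names)} genes "
                "(is the file genes x cells? pass transpose=True)"
            )
    elif format == "csv":
        df = pd.read_csv(counts_path, index_col=0)
        if transpose:
            df = df.T
        matrix = sp.csr_matrix(df.to_numpy(dtype=np.float64))
        cell_ids = df.index.astype(str).to_numpy()
        gene_names = df.columns.astype(str).to_numpy()
    else:
        raise ValueError(f"unknown format {format!r}; expected 'mtx' or 'csv'")

    labels = read_labels(labels_path, cell_ids) if labels_path is not None else None
    mito_mask = _default_mito_mask(gene_names, mito_prefix)
    return ExpressionDataset(
        counts=matrix,
        cell_ids=cell_ids,
        gene_names=gene_names,
        labels=labels,
        mito_mask=mito_mask,
    )


def write_dataset(dataset: ExpressionDataset, out_dir: str | os.PathLike) -> None:
    """Write MTX + barcodes/genes sidecars (+ labels CSV when present)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mmwrite(out / "matrix.mtx", sp.coo_matrix(dataset.counts))
    pd.Series(dataset.cell_ids.astype(str)).to_csv(
        out / "barcodes.tsv", sep="\t", index=False, header=False)
    pd.Series(dataset.gene_names.astype(str)).to_csv(
        out / "genes.tsv", sep="\t", index=False, header=False)
    if dataset.labels is not None:
        pd.DataFrame({"cell_id": dataset.cell_ids.astype(str),
                      "label": dataset.labels.astype(str)}).to_csv(
            out / "labels.csv", index=False)


RESULT_COLUMNS = [
    "dataset_id", "condition", "metric", "k", "seed",
    "psi", "ari", "ami", "resolution", "converged",
]


class ResultTable:
    """Tidy table of benchmark records, one row per (metric, k, seed).

    Enforces score ranges (``psi`` in [0, 1]; ``ari``/``ami`` ≤ 1) and
    uniqueness of the (dataset_id, condition, metric, k, seed) key.
    """

    def __init__(self, df: Optional[pd.DataFrame] = None):
        if df is None:
            df = pd.DataFrame(columns=RESULT_COLUMNS)
        missing = set(RESULT_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"result table missing columns: {sorted(missing)}")
        df = df[RESULT_COLUMNS].copy()
        if len(df):
            df = df.astype({"k": np.int64, "seed": np.int64,
                            "psi": float, "ari": float, "ami": float,
                            "resolution": float, "converged": bool})
        self.df = df.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.df
        if not len(df):
            return
        if ((df["psi"] < 0) | (df["psi"] > 1)).any():
            raise ValueError("psi out of range [0, 1]")
        if (df["ari"] > 1).any() or (df["ami"] > 1).any():
            raise ValueError("ari/ami exceed 1")
        if (df["k"] <= 0).any():
            raise ValueError("k must be positive")
        if (df["resolution"] <= 0).any():
            raise ValueError("resolution must be positive")
        key = ["dataset_id", "condition", "metric", "k", "seed"]
        if df.duplicated(subset=key).any():
            raise ValueError("duplicate (dataset, condition, metric, k, seed) rows")

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, ResultTable) and self.df.equals(other.df)


def write_results(table: ResultTable, path: str | os.PathLike) -> None:
    """Write a :class:`ResultTable` as tidy CSV with a stable column order."""
    table.validate()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.df.to_csv(path, index=False)


def read_results(path: str | os.PathLike) -> ResultTable:
    df = pd.read_csv(path)
    if not len(df):
        df = pd.DataFrame(columns=RESULT_COLUMNS)
    else:
        # empty condition tags survive the CSV round trip as empty strings
        for col in ("dataset_id", "condition", "metric"):
            df[col] = df[col].fillna("").astype(str)
    return ResultTable(df)
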