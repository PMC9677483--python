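"""Quality control, normalization, HVG selection and binarization.

Pipeline order is fixed: cells are filtered first (library complexity and
mitochondrial fraction), then genes (detection rate across the *retained*
cells), then counts are total-normalized, scaled and log-transformed, and
optionally restricted to the most highly variable genes.  Binarization applies
to raw counts only.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import ExpressionDataset

__all__ = [
    "filter_cells",
    "filter_genes",
    "normalize_log",
    "to_proportions",
    "select_hvg",
    "binarize",
]


def filter_cells(dataset: ExpressionDataset, min_genes: int = 200,
                 max_mito_frac: Optional[float] = 0.10) -> ExpressionDataset:
    """Drop low-complexity and high-mitochondrial cells.

    Removes cells expressing fewer than ``min_genes`` genes (non-zero count),
    and cells whose mitochondrial counts make up strictly more than
    ``max_mito_frac`` of their total counts.  Pass ``max_mito_frac=None`` to
    skip the mitochondrial filter (e.g. for synthetic data without one).
    """
    X = dataset.counts
    n_expressed = X.getnnz(axis=1)
    keep = n_expressed >= min_genes
    if max_mito_frac is not None:
        if dataset.mito_mask is None:
            raise ValueError(
                "max_mito_frac requires a mito_mask on the dataset; "
                "pass max_mito_frac=None to disable the filter")
        totals = np.asarray(X.sum(axis=1)).ravel()
        mito = np.asarray(X[:, dataset.mito_mask].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito / np.maximum(totals, 1e-300), 0.0)
        keep &= frac <= max_mito_frac
    if not keep.any():
        warnings.warn("cell filtering removed every cell")
    return dataset.subset_cells(np.flatnonzero(keep))


def filter_genes(dataset: ExpressionDataset, min_cell_frac: float = 0.10) -> ExpressionDataset:
    """Keep genes detected (count ≥ 1) in at least ``min_cell_frac`` of cells."""
    n = dataset.n_cells
    detected = dataset.counts.getnnz(axis=0)
    keep = detected >= min_cell_frac * n
    return dataset.subset_genes(np.flatnonzero(keep))


def normalize_log(dataset: ExpressionDataset, scale: float = 10_000.0) -> ExpressionDataset:
    """Total-count normalize, scale, and log-transform: x -> ln(1 + scale*x/sum(x)).

    Cells with zero total counts are left all-zero and flagged in
    ``meta['zero_total_cells']``.
    """
    prop = to_proportions(dataset, scale=scale)
    X = prop.counts.copy()
    X.data = np.log1p(X.data)
    out = prop.with_counts(X, space="normalized")
    return out


def to_proportions(dataset: ExpressionDataset, scale: float = 10_000.0) -> ExpressionDataset:
    """Total-count normalized, pre-log values: x -> scale * x / sum(x)."""
    X = dataset.counts.tocsr().copy()
    totals = np.asarray(X.sum(axis=1)).ravel()
    zero_cells = np.flatnonzero(totals == 0)
    if zero_cells.size:
        warnings.warn(f"{zero_cells.size} cells have zero total counts; left all-zero")
    inv = np.where(totals > 0, scale / np.maximum(totals, 1e-300), 0.0)
    X = sp.diags(inv) @ X
    out = dataset.with_counts(X.tocsr(), space="proportions")
    out.meta["zero_total_cells"] = zero_cells
    out.meta["scale"] = scale
    return out


def binarize(dataset: ExpressionDataset) -> ExpressionDataset:
    """Presence/absence transform: counts ≥ 1 map to 1, zeros stay 0. Idempotent."""
    X = dataset.counts.copy()
    X.data = (X.data > 0).astype(np.float64)
    X.eliminate_zeros()
    return dataset.with_counts(X, space="binary")


def _dispersion_table(X: sp.csr_matrix) -> pd.DataFrame:
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = X.copy()
    sq.data **= 2
    mean_sq = np.asarray(sq.mean(axis=0)).ravel()
    var = np.maximum(mean_sq - mean ** 2, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-300), 0.0)
    return pd.DataFrame({"mean": mean, "disp": disp})


def select_hvg(dataset: ExpressionDataset, n_top: int, n_bins: int = 20) -> ExpressionDataset:
    """Restrict to the ``n_top`` most highly variable genes.

    Genes are ranked by normalized dispersion: dispersion (variance/mean of
    the normalized values) is z-scored within 20 equal-frequency mean bins,
    so that variability is judged relative to genes of similar expression.
    Ties break by gene order, making the selection deterministic.
    """
    if n_top > dataset.n_genes:
        raise ValueError(f"n_top={n_top} exceeds {dataset.n_genes} genes")
    tab = _dispersion_table(dataset.counts)
    # equal-frequency bins on the mean; duplicate edges collapsed for ties
    try:
        bins = pd.qcut(tab["mean"], q=n_bins, duplicates="drop", labels=False)
    except ValueError:
        bins = pd.Series(np.zeros(len(tab), dtype=int))
    grouped = tab.groupby(bins)["disp"]
    mu = grouped.transform("mean")
    sd = grouped.transform("std").fillna(0.0)
    norm_disp = (tab["disp"] - mu) / sd.replace(0.0, 1.0)
    # rank by normalized dispersion, then raw dispersion (covers degenerate
    # single-gene bins), then gene order — fully deterministic
    order = np.lexsort((np.arange(len(tab)), -tab["disp"].to_numpy(),
                        -norm_disp.to_numpy()))
    keep = np.sort(order[:n_top])
    out = dataset.subset_genes(keep)
    out.meta["hvg_n_top"] = n_top
    return out
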