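"""External cluster validity: Pair Sets Index (headline), ARI and AMI.

PSI differs from ARI/AMI in that clusters are first paired one-to-one across
the two partitions (maximum-weight bipartite matching on a size-normalized
overlap), so every cluster — rare or abundant — contributes equally to the
score.  ARI and AMI are pair- and information-based and are dominated by
large clusters, which makes them insensitive to misclustered rare cell
populations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_mutual_info_score, adjusted_rand_score

__all__ = [
    "EvaluationRecord",
    "contingency_table",
    "pair_sets_index",
    "adjusted_rand_index",
    "adjusted_mutual_information",
    "score_partition",
    "summarize",
]


@dataclass
class EvaluationRecord:
    """One clustering outcome: (metric, k, seed) with its validity scores."""

    metric: str
    k: int
    seed: int
    psi: float
    ari: float
    ami: float
    resolution: float = 1.0
    converged: bool = True
    dataset_id: str = ""
    condition: str = ""

    def __post_init__(self):
        if not 0.0 <= self.psi <= 1.0:
            raise ValueError(f"psi must lie in [0, 1]; got {self.psi}")
        if self.ari > 1 or self.ami > 1:
            raise ValueError("ari/ami cannot exceed 1")


def _check_pair(truth, pred) -> Tuple[np.ndarray, np.ndarray]:
    truth = np.asarray(truth).ravel()
    pred = np.asarray(pred).ravel()
    if truth.shape != pred.shape:
        raise ValueError(f"length mismatch: {truth.size} vs {pred.size}")
    if truth.size < 2:
        raise ValueError("need at least two points")
    return truth, pred


def contingency_table(truth, pred) -> np.ndarray:
    """K × K' cross-tabulation of two label vectors."""
    truth, pred = _check_pair(truth, pred)
    ti = pd.factorize(truth)[0]
    pi = pd.factorize(pred)[0]
    K, L = ti.max() + 1, pi.max() + 1
    C = np.zeros((K, L), dtype=np.int64)
    np.add.at(C, (ti, pi), 1)
    return C


def pair_sets_index(truth, pred) -> float:
    """Pair Sets Index: chance-adjusted set-matching between two partitions.

    The K × K' contingency table is converted to pair similarities
    ``S_ij = n_ij / max(a_i, b_j)`` (a, b: cluster sizes).  Clusters are
    paired by maximum-weight bipartite matching (Hungarian algorithm); the
    total matched similarity S is adjusted for chance using the expectation
    over size-sorted marginals, E[S] = sum_r a_(r) * b_(r) / (n * max(a_(r),
    b_(r))), and normalized:

        PSI = max(0, (S - E[S]) / (max(K, K') - E[S]))

    Unmatched clusters (when K != K') contribute zero similarity.  PSI is 1
    for identical partitions (up to renaming), about 0 for random ones, and
    is symmetric in its arguments.
    """
    C = contingency_table(truth, pred)
    n = C.sum()
    a = C.sum(axis=1).astype(np.float64)
    b = C.sum(axis=0).astype(np.float64)
    K, L = C.shape
    S_ij = C / np.maximum.outer(a, b)
    rows, cols = linear_sum_assignment(-S_ij)
    S = float(S_ij[rows, cols].sum())
    a_sorted = np.sort(a)[::-1]
    b_sorted = np.sort(b)[::-1]
    m = min(K, L)
    E = float(np.sum(a_sorted[:m] * b_sorted[:m]
                     / (n * np.maximum(a_sorted[:m], b_sorted[:m]))))
    denom = max(K, L) - E
    if denom <= 0:
        # both partitions are a single cluster: trivially identical
        return 1.0
    return float(min(1.0, max(0.0, (S - E) / denom)))


def adjusted_rand_index(truth, pred) -> float:
    """Permutation-model chance-corrected Rand index."""
    truth, pred = _check_pair(truth, pred)
    return float(adjusted_rand_score(truth.astype(str), pred.astype(str)))


def adjusted_mutual_information(truth, pred) -> float:
    """AMI with arithmetic-mean normalization: (MI - E[MI]) / (mean(H) - E[MI])."""
    truth, pred = _check_pair(truth, pred)
    return float(adjusted_mutual_info_score(truth.astype(str), pred.astype(str),
                                            average_method="arithmetic"))


def score_partition(truth, pred) -> Tuple[float, float, float]:
    """(PSI, ARI, AMI) of a predicted partition against ground truth."""
    return (pair_sets_index(truth, pred),
            adjusted_rand_index(truth, pred),
            adjusted_mutual_information(truth, pred))


def summarize(records: Iterable[EvaluationRecord]) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate per-(metric, k) and per-metric summary statistics.

    Returns ``(per_k, per_metric)``: per_k holds mean and SD of PSI over
    seeds for every (metric, k); per_metric averages the per-k means across
    neighbourhood sizes (the grand mean used to rank metrics) and is sorted
    by descending grand-mean PSI.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to summarize")
    df = pd.DataFrame([r.__dict__ for r in records])
    per_k = (df.groupby(["metric", "k"], as_index=False)
               .agg(mean_psi=("psi", "mean"), sd_psi=("psi", "std"),
                    mean_ari=("ari", "mean"), mean_ami=("ami", "mean"),
                    n_seeds=("seed", "nunique")))
    per_k["sd_psi"] = per_k["sd_psi"].fillna(0.0)
    per_metric = (per_k.groupby("metric", as_index=False)
                  .agg(grand_mean_psi=("mean_psi", "mean"),
                       n_k=("k", "nunique"))
                  .sort_values("grand_mean_psi", ascending=False, kind="stable")
                  .reset_index(drop=True))
    per_metric["rank"] = np.arange(1, len(per_metric) + 1)
    return per_k, per_metric
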