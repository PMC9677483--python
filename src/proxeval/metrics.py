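"""The 17 cell-cell proximity metrics, as pairwise dissimilarity matrices.

Families and the value space each operates on:

====================  =======================================  ============
family                metrics                                  input space
====================  =======================================  ============
true distances        euclidean, manhattan, canberra,          normalized
                      chebyshev
binary                hamming, yule, kulsinski, jaccard        binary
correlation (1 - r)   pearson, spearman, kendall,              normalized
                      weighted_rank, zi_kendall
proportionality       bray_curtis, phi                         proportions
angular               cosine                                   normalized
optimal transport     ot (debiased entropic Sinkhorn)          proportions
====================  =======================================  ============

"normalized" is ln(1 + scale * x / total); "proportions" is the total-count
scaled, pre-log matrix; "binary" is presence/absence of raw counts.
Correlation-type dissimilarities are d = 1 - r (range [0, 2]).  Every matrix
is symmetrized, its diagonal forced to zero, and validated finite and
non-negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kendalltau, rankdata, weightedtau

from .io import ExpressionDataset

__all__ = [
    "METRICS",
    "METRIC_SPACES",
    "DistanceMatrix",
    "compute_distance_matrix",
    "true_distance",
    "binary_dissimilarity",
    "correlation_dissimilarity",
    "proportionality_dissimilarity",
    "cosine_dissimilarity",
    "ot_distance",
    "zero_inflated_kendall",
    "default_ot_cost",
]

METRIC_SPACES = {
    "euclidean": "normalized",
    "manhattan": "normalized",
    "canberra": "normalized",
    "chebyshev": "normalized",
    "hamming": "binary",
    "yule": "binary",
    "kulsinski": "binary",
    "jaccard": "binary",
    "pearson": "normalized",
    "spearman": "normalized",
    "kendall": "normalized",
    "weighted_rank": "normalized",
    "zi_kendall": "normalized",
    "phi": "proportions",
    "bray_curtis": "proportions",
    "cosine": "normalized",
    "ot": "proportions",
}

METRICS = tuple(METRIC_SPACES)


@dataclass
class DistanceMatrix:
    """n × n symmetric dissimilarity matrix tagged with its metric."""

    values: np.ndarray
    metric: str
    params: dict = field(default_factory=dict)
    input_space: str = "normalized"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        V = self.values
        if V.ndim != 2 or V.shape[0] != V.shape[1]:
            raise ValueError("distance matrix must be square")
        bad = np.argwhere(~np.isfinite(V))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"{self.metric}: non-finite dissimilarity for cell pair ({i}, {j})")
        if np.abs(V - V.T).max() > 1e-10:
            raise ValueError(f"{self.metric}: matrix not symmetric")
        if np.abs(np.diagonal(V)).max() > 1e-12:
            raise ValueError(f"{self.metric}: non-zero diagonal")
        if V.min() < 0:
            raise ValueError(f"{self.metric}: negative dissimilarities")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _finalize(V: np.ndarray, metric: str, params: dict, space: str) -> DistanceMatrix:
    V = np.asarray(V, dtype=np.float64)
    V = 0.5 * (V + V.T)
    np.fill_diagonal(V, 0.0)
    # numerical fuzz from vectorized algebra
    V[(V < 0) & (V > -1e-12)] = 0.0
    return DistanceMatrix(values=V, metric=metric, params=params, input_space=space)


# ---------------------------------------------------------------------------
# per-pair formulas (the public scalar API)
# ---------------------------------------------------------------------------

def _check_pair(x, y):
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite input")
    return x, y


def true_distance(x, y, form: str) -> float:
    """Euclidean, Manhattan, Chebyshev or Canberra distance between two cells."""
    x, y = _check_pair(x, y)
    d = np.abs(x - y)
    if form == "euclidean":
        return float(np.sqrt(np.sum(d ** 2)))
    if form == "manhattan":
        return float(np.sum(d))
    if form == "chebyshev":
        return float(d.max(initial=0.0))
    if form == "canberra":
        denom = np.abs(x) + np.abs(y)
        terms = np.divide(d, denom, out=np.zeros_like(d), where=denom > 0)
        return float(terms.sum())
    raise ValueError(f"unknown true-distance form {form!r}")


def _binary_counts(x, y):
    if not (np.isin(x, (0.0, 1.0)).all() and np.isin(y, (0.0, 1.0)).all()):
        raise ValueError("binary dissimilarity requires 0/1 vectors")
    c11 = float(np.sum((x == 1) & (y == 1)))
    c10 = float(np.sum((x == 1) & (y == 0)))
    c01 = float(np.sum((x == 0) & (y == 1)))
    c00 = float(np.sum((x == 0) & (y == 0)))
    return c11, c10, c01, c00


def binary_dissimilarity(x, y, form: str) -> float:
    """Hamming, Yule, Kulsinski or Jaccard dissimilarity on 0/1 vectors."""
    x, y = _check_pair(x, y)
    c11, c10, c01, c00 = _binary_counts(x, y)
    n = c11 + c10 + c01 + c00
    if form == "hamming":
        return (c10 + c01) / n
    if form == "jaccard":
        denom = c11 + c10 + c01
        return (c10 + c01) / denom if denom > 0 else 0.0
    if form == "yule":
        denom = c11 * c00 + c10 * c01
        return 2.0 * c10 * c01 / denom if denom > 0 else 0.0
    if form == "kulsinski":
        return (c10 + c01 - c11 + n) / (c10 + c01 + n)
    raise ValueError(f"unknown binary form {form!r}")


def _pearson_r(x, y) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        return 0.0  # zero-variance vector: r treated as 0
    return float(np.clip(np.dot(xc, yc) / (nx * ny), -1.0, 1.0))


def zero_inflated_kendall(x, y) -> float:
    """Zero-inflated Kendall's tau for non-negative, zero-inflated data.

    tau* = p11^2 * tau11 + 2 * (p00*p11 - p01*p10), where pAB are the
    fractions of positions in each joint zero/non-zero category and tau11 is
    Kendall's tau restricted to the doubly non-zero positions (0 if fewer
    than two such positions).
    """
    x, y = _check_pair(x, y)
    g = x.size
    nzx, nzy = x != 0, y != 0
    p11 = np.sum(nzx & nzy) / g
    p10 = np.sum(nzx & ~nzy) / g
    p01 = np.sum(~nzx & nzy) / g
    p00 = np.sum(~nzx & ~nzy) / g
    both = nzx & nzy
    if both.sum() >= 2:
        t = kendalltau(x[both], y[both]).statistic
        tau11 = 0.0 if np.isnan(t) else float(t)
    else:
        tau11 = 0.0
    return p11 ** 2 * tau11 + 2.0 * (p00 * p11 - p01 * p10)


def correlation_dissimilarity(x, y, form: str) -> float:
    """1 - r for Pearson/Spearman/Kendall/weighted-rank/ZI-Kendall correlations."""
    x, y = _check_pair(x, y)
    if x.size < 3:
        raise ValueError("correlation dissimilarity needs >= 3 entries")
    if form == "pearson":
        r = _pearson_r(x, y)
    elif form == "spearman":
        r = _pearson_r(rankdata(x), rankdata(y))
    elif form == "kendall":
        t = kendalltau(x, y).statistic
        r = 0.0 if np.isnan(t) else float(t)
    elif form == "weighted_rank":
        t = weightedtau(x, y).statistic
        r = 0.0 if np.isnan(t) else float(t)
    elif form == "zi_kendall":
        r = zero_inflated_kendall(x, y)
    else:
        raise ValueError(f"unknown correlation form {form!r}")
    return 1.0 - float(np.clip(r, -1.0, 1.0))


def proportionality_dissimilarity(x, y, form: str, pseudocount: float = 1.0) -> float:
    """Bray-Curtis or symmetric phi proportionality dissimilarity."""
    x, y = _check_pair(x, y)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("proportionality metrics need non-negative input")
    if form == "bray_curtis":
        denom = np.sum(x + y)
        if denom == 0:
            warnings.warn("bray_curtis on two all-zero vectors; defined as 0")
            return 0.0
        return float(np.sum(np.abs(x - y)) / denom)
    if form == "phi":
        if pseudocount <= 0:
            raise ValueError("phi requires pseudocount > 0")
        lx = np.log(x + pseudocount)
        ly = np.log(y + pseudocount)
        num = np.var(lx - ly)
        denom = np.var(lx) + np.var(ly)
        if denom == 0:
            return 0.0 if num == 0 else float("inf")
        return float(num / denom)
    raise ValueError(f"unknown proportionality form {form!r}")


def cosine_dissimilarity(x, y) -> float:
    """1 - cosine similarity; all-zero vectors give d = 1 (flagged)."""
    x, y = _check_pair(x, y)
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        warnings.warn("cosine dissimilarity with an all-zero vector; defined as 1")
        return 1.0
    return 1.0 - float(np.clip(np.dot(x, y) / (nx * ny), -1.0, 1.0))


# ---------------------------------------------------------------------------
# entropic optimal transport
# ---------------------------------------------------------------------------

def default_ot_cost(X: np.ndarray, n_components: int = 20) -> np.ndarray:
    """Ground cost between genes: Euclidean distance between gene coordinates
    in a principal subspace of the genes × cells matrix, rescaled to max 1."""
    from sklearn.decomposition import PCA

    G = np.asarray(X, dtype=np.float64).T  # genes × cells
    k = min(n_components, G.shape[0] - 1, G.shape[1])
    if k >= 1:
        coords = PCA(n_components=k, random_state=0).fit_transform(G)
    else:
        coords = G
    C = squareform(pdist(coords))
    m = C.max()
    if m > 0:
        C = C / m
    return C


def _sinkhorn_batch(A: np.ndarray, B: np.ndarray, K: np.ndarray, eps: float,
                    tol: float, max_iter: int):
    """Balanced Sinkhorn on column histograms.  Returns per-column regularized
    OT values (dual form) and the iteration count.

    Columns whose marginal error drops below ``tol`` are frozen and leave the
    iteration, so a few slowly-converging pairs do not inflate the cost of a
    whole batch.
    """
    g, m = A.shape
    u = np.ones_like(A)
    v = np.ones_like(B)
    act = np.arange(m)
    it = 0
    while act.size and it < max_iter:
        Kv = K @ v[:, act]
        if it > 0:
            err = np.abs(u[:, act] * Kv - A[:, act]).sum(axis=0)
            done = err < tol
            if done.any():
                Kv = Kv[:, ~done]
                act = act[~done]
                if not act.size:
                    break
        u[:, act] = np.divide(A[:, act], Kv, out=np.zeros_like(Kv), where=Kv > 0)
        Ktu = K.T @ u[:, act]
        v[:, act] = np.divide(B[:, act], Ktu, out=np.zeros_like(Ktu), where=Ktu > 0)
        it += 1
    if act.size:
        err = np.abs(u[:, act] * (K @ v[:, act]) - A[:, act]).sum(axis=0)
        warnings.warn(f"Sinkhorn: {act.size} of {m} pairs above tol={tol} "
                      f"after {it} iterations (worst marginal error "
                      f"{err.max():.2e})")
    # OT_eps = eps * (sum_i a_i ln(u_i/a_i) + sum_j b_j ln(v_j/b_j))
    def _term(P, w):
        with np.errstate(divide="ignore", invalid="ignore"):
            t = P * np.log(np.divide(w, P, out=np.ones_like(w), where=P > 0))
        return np.where(P > 0, t, 0.0).sum(axis=0)

    return eps * (_term(A, u) + _term(B, v)), it


def _normalize_hist(x: np.ndarray) -> np.ndarray:
    s = x.sum()
    if s <= 0:
        raise ValueError("OT requires vectors with positive total mass")
    return x / s


def ot_distance(x, y, cost: np.ndarray, epsilon: float = 0.1,
                tol: float = 1e-6, max_iter: int = 1000) -> float:
    """Debiased entropic OT (Sinkhorn divergence) between two cells.

    S(x, y) = OT_eps(x, y) - 0.5*OT_eps(x, x) - 0.5*OT_eps(y, y), clipped at
    0, where OT_eps is the entropy-regularized transport cost over the gene
    ground metric ``cost``.
    """
    x, y = _check_pair(x, y)
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    C = np.asarray(cost, dtype=np.float64)
    if C.shape != (x.size, x.size):
        raise ValueError("cost matrix shape must match the gene count")
    a = _normalize_hist(x)[:, None]
    b = _normalize_hist(y)[:, None]
    K = np.exp(-C / epsilon)
    oxy, _ = _sinkhorn_batch(a, b, K, epsilon, tol, max_iter)
    oxx, _ = _sinkhorn_batch(a, a, K, epsilon, tol, max_iter)
    oyy, _ = _sinkhorn_batch(b, b, K, epsilon, tol, max_iter)
    return float(max(0.0, oxy[0] - 0.5 * oxx[0] - 0.5 * oyy[0]))


# ---------------------------------------------------------------------------
# full-matrix computation
# ---------------------------------------------------------------------------

def _dense(dataset: ExpressionDataset) -> np.ndarray:
    return dataset.dense()


def _matrix_scipy_pdist(X, metric_name):
    with np.errstate(invalid="ignore", divide="ignore"):
        D = squareform(pdist(X, metric_name))
    return D


def _matrix_binary(X, form):
    if X.size and not np.isin(X, (0.0, 1.0)).all():
        raise ValueError(f"{form} requires a binarized dataset "
                         "(input-space error)")
    B = X
    g = B.shape[1]
    c11 = B @ B.T
    r = B.sum(axis=1)
    c10 = r[:, None] - c11
    c01 = r[None, :] - c11
    c00 = g - c11 - c10 - c01
    if form == "hamming":
        return (c10 + c01) / g
    if form == "jaccard":
        denom = c11 + c10 + c01
        return np.divide(c10 + c01, denom, out=np.zeros_like(c11, dtype=float),
                         where=denom > 0)
    if form == "yule":
        denom = c11 * c00 + c10 * c01
        return np.divide(2.0 * c10 * c01, denom,
                         out=np.zeros_like(c11, dtype=float), where=denom > 0)
    if form == "kulsinski":
        # self-dissimilarity is inherently non-zero; the diagonal is zeroed
        # during finalization (neighbours never include self anyway)
        return (c10 + c01 - c11 + g) / (c10 + c01 + g)
    raise AssertionError(form)


def _matrix_centered_corr(X):
    Z = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Z, axis=1)
    zero = norms == 0
    if zero.any():
        warnings.warn(f"{zero.sum()} zero-variance cells; their correlations "
                      "are treated as 0 (d = 1)")
    Z = Z / np.where(zero, 1.0, norms)[:, None]
    R = np.clip(Z @ Z.T, -1.0, 1.0)
    R[zero, :] = 0.0
    R[:, zero] = 0.0
    return 1.0 - R


def _matrix_pairloop(X, fn):
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        xi = X[i]
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = fn(xi, X[j])
    return D


def _matrix_kendall(X):
    def fn(x, y):
        t = kendalltau(x, y).statistic
        return 1.0 - (0.0 if np.isnan(t) else float(np.clip(t, -1, 1)))
    return _matrix_pairloop(X, fn)


def _matrix_weightedtau(X):
    def fn(x, y):
        t = weightedtau(x, y).statistic
        return 1.0 - (0.0 if np.isnan(t) else float(np.clip(t, -1, 1)))
    return _matrix_pairloop(X, fn)


def _matrix_zi_kendall(X):
    n, g = X.shape
    NZ = (X != 0).astype(np.float64)
    c11 = NZ @ NZ.T
    r = NZ.sum(axis=1)
    c10 = r[:, None] - c11
    c01 = r[None, :] - c11
    c00 = g - c11 - c10 - c01
    p11, p10, p01, p00 = c11 / g, c10 / g, c01 / g, c00 / g
    tau11 = np.zeros((n, n))
    masks = X != 0
    for i in range(n):
        for j in range(i + 1, n):
            both = masks[i] & masks[j]
            if both.sum() >= 2:
                t = kendalltau(X[i, both], X[j, both]).statistic
                if not np.isnan(t):
                    tau11[i, j] = tau11[j, i] = t
    tau_star = p11 ** 2 * tau11 + 2.0 * (p00 * p11 - p01 * p10)
    return 1.0 - np.clip(tau_star, -1.0, 1.0)


def _matrix_phi(X, pseudocount):
    L = np.log(X + pseudocount)
    Lc = L - L.mean(axis=1, keepdims=True)
    g = L.shape[1]
    v = (Lc ** 2).sum(axis=1) / g
    C = (Lc @ Lc.T) / g
    num = v[:, None] + v[None, :] - 2.0 * C
    denom = v[:, None] + v[None, :]
    D = np.divide(num, denom, out=np.zeros_like(num), where=denom > 0)
    return np.maximum(D, 0.0)


def _matrix_cosine(X):
    norms = np.linalg.norm(X, axis=1)
    zero = norms == 0
    if zero.any():
        warnings.warn(f"{zero.sum()} all-zero cells; cosine defined as 1")
    U = X / np.where(zero, 1.0, norms)[:, None]
    R = np.clip(U @ U.T, -1.0, 1.0)
    D = 1.0 - R
    D[zero, :] = 1.0
    D[:, zero] = 1.0
    return D


def _matrix_ot(X, params):
    epsilon = float(params.get("epsilon", 0.1))
    tol = float(params.get("tol", 1e-6))
    max_iter = int(params.get("max_iter", 1000))
    chunk = int(params.get("chunk", 5000))
    cost = params.get("cost")
    if cost is None:
        cost = default_ot_cost(X, n_components=int(params.get("n_pca", 20)))
    C = np.asarray(cost, dtype=np.float64)
    n, g = X.shape
    totals = X.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("OT requires every cell to have positive total mass")
    H = (X / totals[:, None]).T  # genes × cells histograms
    K = np.exp(-C / epsilon)

    self_vals, _ = _sinkhorn_batch(H, H, K, epsilon, tol, max_iter)
    iu, ju = np.triu_indices(n, k=1)
    vals = np.empty(iu.size)
    for s in range(0, iu.size, chunk):
        sl = slice(s, min(s + chunk, iu.size))
        o, _ = _sinkhorn_batch(H[:, iu[sl]], H[:, ju[sl]], K, epsilon, tol, max_iter)
        vals[sl] = o
    D = np.zeros((n, n))
    D[iu, ju] = vals - 0.5 * self_vals[iu] - 0.5 * self_vals[ju]
    D = D + D.T
    return np.maximum(D, 0.0)


def compute_distance_matrix(dataset: ExpressionDataset, metric: str,
                            params: Optional[dict] = None) -> DistanceMatrix:
    """Compute the full cell-cell dissimilarity matrix for one metric.

    The dataset must already be in the value space the metric requires (see
    :data:`METRIC_SPACES`); a mismatch raises ``ValueError``.
    """
    params = dict(params or {})
    if metric not in METRIC_SPACES:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
    required = METRIC_SPACES[metric]
    if dataset.space != required:
        raise ValueError(
            f"{metric} requires input space {required!r} but dataset is in "
            f"{dataset.space!r} (input-space error)")
    X = _dense(dataset)

    if metric in ("euclidean", "manhattan", "chebyshev", "canberra"):
        scipy_name = {"euclidean": "euclidean", "manhattan": "cityblock",
                      "chebyshev": "chebyshev", "canberra": "canberra"}[metric]
        D = _matrix_scipy_pdist(X, scipy_name)
    elif metric in ("hamming", "yule", "kulsinski", "jaccard"):
        D = _matrix_binary(X, metric)
    elif metric == "pearson":
        D = _matrix_centered_corr(X)
    elif metric == "spearman":
        ranks = rankdata(X, axis=1)
        D = _matrix_centered_corr(ranks)
    elif metric == "kendall":
        D = _matrix_kendall(X)
    elif metric == "weighted_rank":
        D = _matrix_weightedtau(X)
    elif metric == "zi_kendall":
        D = _matrix_zi_kendall(X)
    elif metric == "bray_curtis":
        D = _matrix_scipy_pdist(X, "braycurtis")
        if np.isnan(D).any():
            warnings.warn("bray_curtis between all-zero cells defined as 0")
            D = np.nan_to_num(D, nan=0.0)
    elif metric == "phi":
        D = _matrix_phi(X, float(params.get("pseudocount", 1.0)))
    elif metric == "cosine":
        D = _matrix_cosine(X)
    elif metric == "ot":
        D = _matrix_ot(X, params)
    else:  # pragma: no cover
        raise AssertionError(metric)

    return _finalize(D, metric, params, required)
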