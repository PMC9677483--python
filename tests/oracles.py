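"""Independent brute-force oracles used only by the test suite.

Every function here re-derives its quantity from first principles (explicit
loops, exhaustive enumeration, direct formula evaluation) without touching
the package's vectorized implementations, so agreement between the two is a
genuine cross-check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# pairwise dissimilarity formulas (plain Python loops)
# ---------------------------------------------------------------------------

def euclidean(x, y):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(x, y)))


def manhattan(x, y):
    return sum(abs(a - b) for a, b in zip(x, y))


def chebyshev(x, y):
    return max((abs(a - b) for a, b in zip(x, y)), default=0.0)


def canberra(x, y):
    tot = 0.0
    for a, b in zip(x, y):
        denom = abs(a) + abs(b)
        if denom > 0:
            tot += abs(a - b) / denom
    return tot


def _binary_counts(x, y):
    c11 = sum(1 for a, b in zip(x, y) if a == 1 and b == 1)
    c10 = sum(1 for a, b in zip(x, y) if a == 1 and b == 0)
    c01 = sum(1 for a, b in zip(x, y) if a == 0 and b == 1)
    c00 = sum(1 for a, b in zip(x, y) if a == 0 and b == 0)
    return c11, c10, c01, c00


def hamming(x, y):
    c11, c10, c01, c00 = _binary_counts(x, y)
    return (c10 + c01) / (c11 + c10 + c01 + c00)


def jaccard(x, y):
    c11, c10, c01, _ = _binary_counts(x, y)
    denom = c11 + c10 + c01
    return (c10 + c01) / denom if denom else 0.0


def yule(x, y):
    c11, c10, c01, c00 = _binary_counts(x, y)
    denom = c11 * c00 + c10 * c01
    return 2 * c10 * c01 / denom if denom else 0.0


def kulsinski(x, y):
    c11, c10, c01, c00 = _binary_counts(x, y)
    n = c11 + c10 + c01 + c00
    return (c10 + c01 - c11 + n) / (c10 + c01 + n)


def pearson_d(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = math.sqrt(sum((a - mx) ** 2 for a in x))
    dy = math.sqrt(sum((b - my) ** 2 for b in y))
    if dx == 0 or dy == 0:
        return 1.0
    return 1.0 - max(-1.0, min(1.0, num / (dx * dy)))


def _ranks_average(x):
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def spearman_d(x, y):
    return pearson_d(_ranks_average(x), _ranks_average(y))


def kendall_tau_b(x, y):
    """Kendall tau-b from explicit concordance counting with tie correction."""
    n = len(x)
    con = dis = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif (dx > 0) == (dy > 0):
                con += 1
            else:
                dis += 1
    denom = math.sqrt((con + dis + tx) * (con + dis + ty))
    if denom == 0:
        return 0.0
    return (con - dis) / denom


def kendall_d(x, y):
    return 1.0 - kendall_tau_b(x, y)


def weighted_tau_d(x, y):
    """Vigna's weighted tau with additive hyperbolic weights, averaged over
    the two reference rankings (by decreasing x and by decreasing y).
    Assumes tie-free inputs."""
    n = len(x)

    def one(ref, other):
        order = sorted(range(n), key=lambda i: -ref[i])
        rank = [0] * n
        for pos, i in enumerate(order):
            rank[i] = pos
        num = den = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                w = 1.0 / (1 + rank[i]) + 1.0 / (1 + rank[j])
                s = np.sign(ref[i] - ref[j]) * np.sign(other[i] - other[j])
                num += s * w
                den += w
        return num / den

    return 1.0 - 0.5 * (one(x, y) + one(y, x))


def zi_kendall_d(x, y):
    n = len(x)
    c11 = [(a, b) for a, b in zip(x, y) if a != 0 and b != 0]
    p11 = len(c11) / n
    p10 = sum(1 for a, b in zip(x, y) if a != 0 and b == 0) / n
    p01 = sum(1 for a, b in zip(x, y) if a == 0 and b != 0) / n
    p00 = sum(1 for a, b in zip(x, y) if a == 0 and b == 0) / n
    if len(c11) >= 2:
        tau11 = kendall_tau_b([a for a, _ in c11], [b for _, b in c11])
    else:
        tau11 = 0.0
    tau_star = p11 ** 2 * tau11 + 2 * (p00 * p11 - p01 * p10)
    return 1.0 - max(-1.0, min(1.0, tau_star))


def bray_curtis(x, y):
    denom = sum(a + b for a, b in zip(x, y))
    if denom == 0:
        return 0.0
    return sum(abs(a - b) for a, b in zip(x, y)) / denom


def phi_d(x, y, pseudocount=1.0):
    lx = [math.log(a + pseudocount) for a in x]
    ly = [math.log(b + pseudocount) for b in y]

    def var(v):
        m = sum(v) / len(v)
        return sum((a - m) ** 2 for a in v) / len(v)

    num = var([a - b for a, b in zip(lx, ly)])
    den = var(lx) + var(ly)
    if den == 0:
        return 0.0
    return num / den


def cosine_d(x, y):
    nx = math.sqrt(sum(a * a for a in x))
    ny = math.sqrt(sum(b * b for b in y))
    if nx == 0 or ny == 0:
        return 1.0
    dot = sum(a * b for a, b in zip(x, y))
    return 1.0 - max(-1.0, min(1.0, dot / (nx * ny)))


# ---------------------------------------------------------------------------
# entropic optimal transport via log-domain Sinkhorn (independent of the
# package's plain-domain matrix-scaling implementation)
# ---------------------------------------------------------------------------

def _log_sinkhorn_value(a, b, C, eps, n_iter=5000):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    C = np.asarray(C, float)
    sup_a = a > 0
    sup_b = b > 0
    la = np.log(a[sup_a])
    lb = np.log(b[sup_b])
    Cs = C[np.ix_(sup_a, sup_b)]
    f = np.zeros(la.size)
    g = np.zeros(lb.size)
    for _ in range(n_iter):
        # f_i = -eps * LSE_j[(g_j - C_ij)/eps + ln b_j]
        f_new = -eps * _lse((g[None, :] - Cs) / eps + lb[None, :], axis=1)
        g_new = -eps * _lse((f_new[:, None] - Cs) / eps + la[:, None], axis=0)
        if np.max(np.abs(f_new - f)) < 1e-15 and np.max(np.abs(g_new - g)) < 1e-15:
            f, g = f_new, g_new
            break
        f, g = f_new, g_new
    return float(a[sup_a] @ f + b[sup_b] @ g)


def _lse(M, axis):
    m = M.max(axis=axis, keepdims=True)
    return (m + np.log(np.exp(M - m).sum(axis=axis, keepdims=True))).squeeze(axis)


def sinkhorn_divergence(x, y, C, eps):
    a = np.asarray(x, float)
    b = np.asarray(y, float)
    a = a / a.sum()
    b = b / b.sum()
    val = (_log_sinkhorn_value(a, b, C, eps)
           - 0.5 * _log_sinkhorn_value(a, a, C, eps)
           - 0.5 * _log_sinkhorn_value(b, b, C, eps))
    return max(0.0, val)


# ---------------------------------------------------------------------------
# external validity indices
# ---------------------------------------------------------------------------

def contingency(truth, pred):
    ts = sorted(set(truth))
    ps = sorted(set(pred))
    C = np.zeros((len(ts), len(ps)), dtype=int)
    for t, p in zip(truth, pred):
        C[ts.index(t), ps.index(p)] += 1
    return C


def psi_exhaustive(truth, pred):
    """Pair Sets Index with the cluster matching found by exhaustive
    enumeration over all injective assignments (no Hungarian algorithm)."""
    C = contingency(truth, pred)
    n = C.sum()
    a = C.sum(axis=1)
    b = C.sum(axis=0)
    K, L = C.shape
    S_ij = np.zeros((K, L))
    for i in range(K):
        for j in range(L):
            S_ij[i, j] = C[i, j] / max(a[i], b[j])
    best = 0.0
    if K <= L:
        for perm in itertools.permutations(range(L), K):
            best = max(best, sum(S_ij[i, perm[i]] for i in range(K)))
    else:
        for perm in itertools.permutations(range(K), L):
            best = max(best, sum(S_ij[perm[j], j] for j in range(L)))
    a_sorted = sorted(a, reverse=True)
    b_sorted = sorted(b, reverse=True)
    E = sum(ai * bi / (n * max(ai, bi))
            for ai, bi in zip(a_sorted, b_sorted))
    denom = max(K, L) - E
    if denom <= 0:
        return 1.0
    return min(1.0, max(0.0, (best - E) / denom))


def ari_pair_counting(truth, pred):
    """ARI from the closed-form pair-counting formula on the contingency table."""
    C = contingency(truth, pred)
    n = C.sum()

    def comb2(v):
        return v * (v - 1) / 2

    sum_ij = sum(comb2(int(v)) for v in C.ravel())
    sum_a = sum(comb2(int(v)) for v in C.sum(axis=1))
    sum_b = sum(comb2(int(v)) for v in C.sum(axis=0))
    total = comb2(n)
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


def ami_direct(truth, pred):
    """AMI via direct evaluation of MI, entropies and the permutation-model
    expected MI (hypergeometric sum), arithmetic-mean normalization."""
    C = contingency(truth, pred).astype(float)
    n = C.sum()
    a = C.sum(axis=1)
    b = C.sum(axis=0)
    mi = 0.0
    for i in range(C.shape[0]):
        for j in range(C.shape[1]):
            if C[i, j] > 0:
                mi += (C[i, j] / n) * math.log(n * C[i, j] / (a[i] * b[j]))

    def H(sizes):
        return -sum((s / n) * math.log(s / n) for s in sizes if s > 0)

    emi = 0.0
    for ai in a:
        for bj in b:
            lo = int(max(0, ai + bj - n))
            hi = int(min(ai, bj))
            for nij in range(max(lo, 1), hi + 1):
                p = (math.comb(int(ai), nij) * math.comb(int(n - ai), int(bj) - nij)
                     / math.comb(int(n), int(bj)))
                emi += p * (nij / n) * math.log(n * nij / (ai * bj))
    denom = 0.5 * (H(a) + H(b)) - emi
    if denom == 0:
        return 1.0
    return (mi - emi) / denom
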