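"""KNN graphs over cells and resolution-tuned Leiden clustering.

Each cell is connected to its k nearest cells under a given dissimilarity
matrix (ties broken by cell index), the directed graph is symmetrized by
union by default, and Leiden community detection (RB-configuration
modularity) is run at an automatically adjusted resolution until the target
cluster count is reached or an attempt cap is hit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional

import igraph as ig
import leidenalg
import numpy as np

from .metrics import DistanceMatrix

__all__ = ["KNNGraph", "Partition", "build_knn_graph", "tune_leiden",
           "cluster_replicates"]

RESOLUTION_BOUNDS = (1e-5, 1e4)


@dataclass
class KNNGraph:
    """Undirected neighbour graph at neighbourhood size k."""

    n_nodes: int
    k: int
    edges: np.ndarray          # (m, 2) int array, i < j
    weights: Optional[np.ndarray] = None
    symmetrization: str = "union"
    neighbors: Optional[np.ndarray] = None  # (n, k) pre-symmetrization

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if (self.edges[:, 0] == self.edges[:, 1]).any():
            raise ValueError("self-loops are not allowed")

    def to_igraph(self) -> ig.Graph:
        g = ig.Graph(n=self.n_nodes, edges=[tuple(e) for e in self.edges],
                     directed=False)
        if self.weights is not None:
            g.es["weight"] = list(self.weights)
        return g

    @property
    def n_components(self) -> int:
        return len(self.to_igraph().connected_components())


@dataclass
class Partition:
    """A clustering of the graph's nodes at a given Leiden resolution."""

    labels: np.ndarray
    resolution: float
    seed: int
    converged: bool
    attempts: int
    quality: float = 0.0
    n_components: int = 1

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


def build_knn_graph(dist: DistanceMatrix, k: int, symmetrization: str = "union",
                    weighted: bool = False) -> KNNGraph:
    """Connect each cell to its k smallest-distance cells (self excluded).

    Ties at the k-th neighbour break deterministically by cell index.  The
    directed k-neighbour relation is made undirected by union (default) or
    intersection; optional edge weights are 1/(1+d).
    """
    n = dist.n
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n_cells ({n}); got {k}")
    V = dist.values
    idx = np.arange(n)
    # lexicographic (distance, index) order makes ties deterministic
    neighbors = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        order = np.lexsort((idx, V[i]))
        order = order[order != i]
        neighbors[i] = order[:k]

    pairs = np.stack([np.repeat(idx, k), neighbors.ravel()], axis=1)
    lo = np.minimum(pairs[:, 0], pairs[:, 1])
    hi = np.maximum(pairs[:, 0], pairs[:, 1])
    canon = np.stack([lo, hi], axis=1)
    uniq, counts = np.unique(canon, axis=0, return_counts=True)
    if symmetrization == "union":
        edges = uniq
    elif symmetrization == "intersection":
        edges = uniq[counts == 2]
    else:
        raise ValueError(f"unknown symmetrization {symmetrization!r}")
    weights = 1.0 / (1.0 + V[edges[:, 0], edges[:, 1]]) if weighted else None
    return KNNGraph(n_nodes=n, k=k, edges=edges, weights=weights,
                    symmetrization=symmetrization, neighbors=neighbors)


def _leiden_once(g: ig.Graph, resolution: float, seed: int) -> Partition:
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights="weight" if "weight" in g.es.attributes() else None,
        resolution_parameter=resolution, seed=int(seed),
    )
    return Partition(labels=np.array(part.membership), resolution=resolution,
                     seed=seed, converged=False, attempts=0,
                     quality=part.quality())


def tune_leiden(graph: KNNGraph, target_clusters: int, seed: int,
                max_attempts: int = 1000) -> Partition:
    """Adjust the Leiden resolution until the target cluster count is found.

    Starts at resolution 1.0, brackets the target by doubling/halving within
    [1e-5, 1e4], then bisects.  Stops as soon as a run yields exactly
    ``target_clusters`` communities (converged) or after ``max_attempts``
    Leiden runs, returning the partition whose count is closest to the target
    (ties to the lower resolution).  Deterministic for a fixed seed.
    """
    if not 1 <= target_clusters <= graph.n_nodes:
        raise ValueError("target_clusters must be in [1, n_nodes]")
    g = graph.to_igraph()
    n_comp = len(g.connected_components())
    if n_comp > target_clusters:
        warnings.warn(f"graph has {n_comp} components; cannot produce fewer "
                      f"than {n_comp} clusters (target {target_clusters})")

    lo_bound, hi_bound = RESOLUTION_BOUNDS
    attempts = 0
    best: Optional[Partition] = None

    def run(res: float) -> Partition:
        nonlocal attempts, best
        attempts += 1
        p = _leiden_once(g, res, seed)
        p.n_components = n_comp
        if best is None:
            best = p
        else:
            d_new = abs(p.n_clusters - target_clusters)
            d_old = abs(best.n_clusters - target_clusters)
            if d_new < d_old or (d_new == d_old and p.resolution < best.resolution):
                best = p
        return p

    def finish(p: Partition, converged: bool) -> Partition:
        p.converged = converged
        p.attempts = attempts
        return p

    p = run(1.0)
    if p.n_clusters == target_clusters:
        return finish(p, True)

    # exponential bracketing: higher resolution -> more clusters
    if p.n_clusters < target_clusters:
        lo_res, lo_part = 1.0, p
        res = 1.0
        while attempts < max_attempts:
            res = min(res * 2.0, hi_bound)
            q = run(res)
            if q.n_clusters == target_clusters:
                return finish(q, True)
            if q.n_clusters > target_clusters:
                hi_res, hi_part = res, q
                break
            lo_res, lo_part = res, q
            if res >= hi_bound:
                return finish(best, False)
        else:
            return finish(best, False)
    else:
        hi_res, hi_part = 1.0, p
        res = 1.0
        while attempts < max_attempts:
            res = max(res / 2.0, lo_bound)
            q = run(res)
            if q.n_clusters == target_clusters:
                return finish(q, True)
            if q.n_clusters < target_clusters:
                lo_res, lo_part = res, q
                break
            hi_res, hi_part = res, q
            if res <= lo_bound:
                return finish(best, False)
        else:
            return finish(best, False)

    # bisection between lo_res (too few clusters) and hi_res (too many)
    while attempts < max_attempts:
        mid = np.sqrt(lo_res * hi_res)  # geometric midpoint on the log scale
        if not lo_res < mid < hi_res:
            break
        q = run(mid)
        if q.n_clusters == target_clusters:
            return finish(q, True)
        if q.n_clusters < target_clusters:
            lo_res = mid
        else:
            hi_res = mid
        if hi_res / lo_res < 1 + 1e-12:
            break
    return finish(best, False)


def cluster_replicates(graph: KNNGraph, target_clusters: int,
                       n_seeds: int = 10, base_seed: int = 0,
                       max_attempts: int = 1000) -> List[Partition]:
    """Repeat resolution-tuned Leiden with ``n_seeds`` derived seeds."""
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    seeds = derive_seeds(base_seed, n_seeds)
    return [tune_leiden(graph, target_clusters, seed=s, max_attempts=max_attempts)
            for s in seeds]


def derive_seeds(base_seed: int, n: int, *extra: int) -> List[int]:
    """Deterministic child seeds (< 2**31) from a base seed and context tags."""
    ss = np.random.SeedSequence([int(base_seed) % (2 ** 31), *[int(e) % (2 ** 31) for e in extra]])
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]
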