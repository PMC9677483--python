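"""Synthetic scRNA-seq datasets with controlled structure.

The generator emulates the study conditions the evaluation framework is
designed around:

* **discrete** structure — well-separated cell populations, each with its own
  block of marker genes expressed several-fold above baseline;
* **continuous** structure — a star topology of differentiation trajectories
  diverging from a single origin state, with gene means interpolating
  linearly along pseudotime and ground-truth labels taken as discretized
  path segments (origin + one population per path);
* population-proportion classes: Abundant (majority of populations >= 5%),
  Rare (majority < 5%, obtained by downsampling), Ultra-Rare (multiple
  populations < 1%);
* sparsity: counts are negative-binomial with gene means rescaled so the
  expected zero fraction matches a base target near 0.48 (the study's low
  band, 46-50%); extra dropout is injected to reach the moderate (68-71%)
  or high (89-90%) bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import scipy.sparse as sp

from .io import ExpressionDataset

__all__ = [
    "SynthConfig",
    "StructuralProfile",
    "SPARSITY_BANDS",
    "generate_discrete",
    "generate_continuous",
    "inject_sparsity",
    "subset_rarity",
    "profile",
    "sparsity_band",
    "recommend_metrics",
    "DEFAULT_RECOMMENDATIONS",
]

SPARSITY_BANDS = {
    "low": (0.46, 0.50),
    "moderate": (0.68, 0.71),
    "high": (0.89, 0.90),
}

# rarity thresholds: a population is rare below 5% and ultra-rare below 1%
RARE_THRESHOLD = 0.05
ULTRA_RARE_THRESHOLD = 0.01


@dataclass
class SynthConfig:
    """Parameters of the synthetic generator.

    Defaults encode the study's desk-scale conditions: 2000 cells x 1500
    genes, five populations at equal (abundant) proportions, 5-fold marker
    separation, negative-binomial dispersion 2.0, base sparsity 0.48.
    """

    n_cells: int = 2000
    n_genes: int = 1500
    structure: str = "discrete"
    n_populations: int = 5           # discrete: clusters; continuous: 1 origin + (n-1) paths
    proportions: Optional[Sequence[float]] = None
    marker_frac: float = 0.04        # fraction of genes in each population's marker block
    marker_fold: float = 5.0         # marker over baseline mean ratio
    dispersion: float = 2.0          # NB size parameter r (var = mu + mu^2/r)
    base_sparsity_target: float = 0.48
    mean_log_sigma: float = 1.0      # sigma of the log-normal baseline gene means
    seed: int = 0

    def resolved_proportions(self) -> np.ndarray:
        if self.proportions is None:
            p = np.full(self.n_populations, 1.0 / self.n_populations)
        else:
            p = np.asarray(self.proportions, dtype=np.float64)
        if len(p) != self.n_populations:
            raise ValueError("proportions length must equal n_populations")
        if abs(p.sum() - 1.0) > 1e-9 or (p <= 0).any():
            raise ValueError("proportions must be positive and sum to 1")
        return p


@dataclass
class StructuralProfile:
    """Measured structural properties of a dataset."""

    sparsity: float
    proportions: Dict[str, float]
    structure_class: str = "unknown"
    rarity_class: str = "unknown"

    def __post_init__(self):
        if self.proportions:
            total = sum(self.proportions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"proportions sum to {total}, expected 1")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _population_sizes(n_cells: int, proportions: np.ndarray) -> np.ndarray:
    sizes = np.floor(proportions * n_cells).astype(int)
    # distribute the rounding remainder to the largest fractional parts
    rem = n_cells - sizes.sum()
    frac = proportions * n_cells - sizes
    for i in np.argsort(-frac)[:rem]:
        sizes[i] += 1
    if (sizes == 0).any():
        bad = np.flatnonzero(sizes == 0)
        raise ValueError(f"infeasible proportions: populations {bad.tolist()} "
                         f"round to 0 cells at n_cells={n_cells}")
    return sizes


def _baseline_means(rng: np.random.Generator, n_genes: int, sigma: float) -> np.ndarray:
    return rng.lognormal(mean=0.0, sigma=sigma, size=n_genes)


def _marker_blocks(n_genes: int, n_groups: int, marker_frac: float) -> List[np.ndarray]:
    block = max(1, int(round(marker_frac * n_genes)))
    if block * n_groups > n_genes:
        raise ValueError("marker blocks exceed the gene count; lower marker_frac")
    return [np.arange(i * block, (i + 1) * block) for i in range(n_groups)]


def _expected_zero_fraction(mu: np.ndarray, r: float) -> float:
    return float(np.mean((r / (r + mu)) ** r))


def _calibrate_scale(mu: np.ndarray, r: float, target: float) -> float:
    """Scalar c such that negative-binomial counts with means c*mu have an
    expected zero fraction equal to ``target`` (bisection; monotone in c)."""
    lo, hi = 1e-8, 1e8
    if not _expected_zero_fraction(mu * hi, r) < target < _expected_zero_fraction(mu * lo, r):
        raise ValueError(f"base sparsity target {target} not reachable")
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if _expected_zero_fraction(mu * mid, r) > target:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1 + 1e-12:
            break
    return float(np.sqrt(lo * hi))


def _sample_counts(rng: np.random.Generator, mu: np.ndarray, r: float) -> np.ndarray:
    p = r / (r + mu)
    return rng.negative_binomial(r, p).astype(np.float64)


def _finalize_dataset(counts: np.ndarray, labels: np.ndarray, structure: str,
                      config: SynthConfig) -> ExpressionDataset:
    n, g = counts.shape
    ds = ExpressionDataset(
        counts=sp.csr_matrix(counts),
        cell_ids=np.array([f"cell_{i:05d}" for i in range(n)], dtype=object),
        gene_names=np.array([f"gene_{j:05d}" for j in range(g)], dtype=object),
        labels=labels,
        mito_mask=np.zeros(g, dtype=bool),
    )
    ds.meta["structure"] = structure
    ds.meta["config"] = config
    return ds


def generate_discrete(config: SynthConfig) -> ExpressionDataset:
    """Discrete cluster structure: per-population marker blocks, NB counts.

    Each population's mean profile is the shared log-normal baseline with its
    marker block multiplied by ``marker_fold``; gene means are rescaled so
    the expected zero fraction equals ``base_sparsity_target``.
    """
    if config.structure != "discrete":
        raise ValueError("config.structure must be 'discrete'")
    if config.n_populations < 2:
        raise ValueError("need at least two populations")
    rng = np.random.default_rng(config.seed)
    p = config.resolved_proportions()
    sizes = _population_sizes(config.n_cells, p)
    base = _baseline_means(rng, config.n_genes, config.mean_log_sigma)
    blocks = _marker_blocks(config.n_genes, config.n_populations, config.marker_frac)

    pop_means = np.tile(base, (config.n_populations, 1))
    for i, blk in enumerate(blocks):
        pop_means[i, blk] *= config.marker_fold

    labels = np.repeat([f"pop_{i}" for i in range(config.n_populations)], sizes)
    order = rng.permutation(config.n_cells)
    labels = labels[order]
    pop_idx = np.repeat(np.arange(config.n_populations), sizes)[order]

    M = pop_means[pop_idx]  # per-cell mean matrix
    c = _calibrate_scale(M, config.dispersion, config.base_sparsity_target)
    counts = _sample_counts(rng, c * M, config.dispersion)
    ds = _finalize_dataset(counts, labels.astype(object), "discrete", config)
    ds.meta["mean_scale"] = c
    ds.meta["pop_means"] = c * pop_means
    return ds


def generate_continuous(config: SynthConfig) -> ExpressionDataset:
    """Continuous structure: star of differentiation trajectories.

    ``n_populations - 1`` paths diverge from one origin state.  Each cell is
    assigned a path and a pseudotime t ~ U(0, 1); its gene means interpolate
    linearly between the origin profile (t=0) and the path's endpoint
    profile (t=1).  Ground-truth labels discretize the topology into origin
    (t below the origin fraction) plus one population per path, sized to the
    configured proportions.
    """
    if config.structure != "continuous":
        raise ValueError("config.structure must be 'continuous'")
    n_paths = config.n_populations - 1
    if n_paths < 1:
        raise ValueError("need at least one path (n_populations >= 2)")
    rng = np.random.default_rng(config.seed)
    p = config.resolved_proportions()   # [origin, path_1, ..., path_P]
    _population_sizes(config.n_cells, p)  # feasibility check
    base = _baseline_means(rng, config.n_genes, config.mean_log_sigma)
    blocks = _marker_blocks(config.n_genes, n_paths, config.marker_frac)

    end_means = np.tile(base, (n_paths, 1))
    for i, blk in enumerate(blocks):
        end_means[i, blk] *= config.marker_fold

    origin_frac = p[0]
    path_probs = p[1:] / (1.0 - origin_frac)
    path = rng.choice(n_paths, size=config.n_cells, p=path_probs)
    t = rng.uniform(0.0, 1.0, size=config.n_cells)
    labels = np.where(t < origin_frac, "origin",
                      np.char.add("path_", path.astype(str))).astype(object)

    M = (1.0 - t)[:, None] * base[None, :] + t[:, None] * end_means[path]
    c = _calibrate_scale(M, config.dispersion, config.base_sparsity_target)
    counts = _sample_counts(rng, c * M, config.dispersion)
    ds = _finalize_dataset(counts, labels, "continuous", config)
    ds.meta["mean_scale"] = c
    ds.meta["pseudotime"] = t
    ds.meta["path"] = path
    return ds


# ---------------------------------------------------------------------------
# structural manipulation
# ---------------------------------------------------------------------------

def inject_sparsity(dataset: ExpressionDataset,
                    target: Union[str, float],
                    seed: int = 0,
                    max_rounds: int = 25) -> ExpressionDataset:
    """Add dropout zeros until the global zero fraction reaches a target band.

    ``target`` is ``'moderate'`` (68-71% zeros), ``'high'`` (89-90%) or an
    explicit fraction.  Per round, each cell's number of entries to zero is
    drawn from a Gaussian centred on its share of the global deficit (SD =
    10% of the mean deficit, clipped at 0); within a cell, positions are
    sampled without replacement with probability inversely proportional to
    the entry's magnitude rank, so dropout favours low counts.  Surviving
    entries are never altered.  Rounds repeat until the band is reached.
    """
    if isinstance(target, str):
        if target not in SPARSITY_BANDS or target == "low":
            raise ValueError(f"unknown sparsity preset {target!r}")
        band = SPARSITY_BANDS[target]
    else:
        f = float(target)
        if not 0.0 <= f < 1.0:
            raise ValueError("explicit sparsity target must lie in [0, 1)")
        band = (f, f)
    goal = 0.5 * (band[0] + band[1])

    current = dataset.sparsity
    if current >= band[0] and current <= band[1]:
        warnings.warn(f"dataset already at sparsity {current:.3f}, within the "
                      "target band; returning an unchanged copy")
        return dataset.with_counts(dataset.counts.copy())
    if current > band[1]:
        raise ValueError(f"current sparsity {current:.3f} already exceeds the "
                         f"target band {band}")

    rng = np.random.default_rng(seed)
    X = dataset.dense()
    n, g = X.shape
    total = n * g

    for _ in range(max_rounds):
        zero_frac = np.mean(X == 0)
        if band[0] <= zero_frac:
            break
        needed = int(round(goal * total)) - int(total - np.count_nonzero(X))
        if needed <= 0:
            break
        nnz_per_cell = np.count_nonzero(X, axis=1)
        total_nnz = nnz_per_cell.sum()
        quota = needed * nnz_per_cell / total_nnz
        sd = 0.1 * quota.mean()
        draws = np.clip(np.round(rng.normal(quota, sd)), 0, nnz_per_cell)
        for i in range(n):
            m = int(draws[i])
            if m <= 0:
                continue
            nz = np.flatnonzero(X[i])
            # rank 1 = smallest magnitude; ties resolved by position
            order = np.lexsort((nz, X[i, nz]))
            ranks = np.empty(nz.size)
            ranks[order] = np.arange(1, nz.size + 1)
            logw = -np.log(ranks)
            # Gumbel top-k = weighted sampling without replacement
            keys = logw + rng.gumbel(size=nz.size)
            drop = nz[np.argpartition(-keys, m - 1)[:m]]
            X[i, drop] = 0.0

    final = np.mean(X == 0)
    if not band[0] <= final <= band[1] + 5e-3:
        warnings.warn(f"sparsity injection reached {final:.4f}, outside the "
                      f"band {band}")
    out = dataset.with_counts(sp.csr_matrix(X))
    out.meta["sparsity_injected"] = band
    return out


def subset_rarity(dataset: ExpressionDataset,
                  target_proportions: Dict[str, float],
                  seed: int = 0) -> ExpressionDataset:
    """Downsample named populations to target fractions of the final total.

    Populations absent from ``target_proportions`` are retained in full; the
    targeted ones are sampled without replacement so that each makes up its
    target fraction of the resulting dataset (±1 cell).
    """
    if dataset.labels is None:
        raise ValueError("subset_rarity requires ground-truth labels")
    targets = {str(k): float(v) for k, v in target_proportions.items()}
    if any(v <= 0 for v in targets.values()):
        raise ValueError("target proportions must be positive")
    tot = sum(targets.values())
    if tot >= 1.0:
        raise ValueError(f"target proportions sum to {tot}; must be < 1")
    labels = dataset.labels.astype(str)
    present = set(labels)
    unknown = set(targets) - present
    if unknown:
        raise ValueError(f"unknown populations in targets: {sorted(unknown)}")

    untargeted_idx = np.flatnonzero(~np.isin(labels, list(targets)))
    n_final = untargeted_idx.size / (1.0 - tot)
    rng = np.random.default_rng(seed)
    keep = [untargeted_idx]
    for name in sorted(targets):
        pool = np.flatnonzero(labels == name)
        want = int(round(targets[name] * n_final))
        if want < 1 or want > pool.size:
            raise ValueError(
                f"infeasible target for {name!r}: need {want} of {pool.size} cells")
        keep.append(rng.choice(pool, size=want, replace=False))
    idx = np.sort(np.concatenate(keep))
    return dataset.subset_cells(idx)


# ---------------------------------------------------------------------------
# profiling and recommendations
# ---------------------------------------------------------------------------

def profile(dataset: ExpressionDataset) -> StructuralProfile:
    """Measure sparsity, population proportions and the rarity class.

    Rarity follows the study's thresholds: *abundant* if the majority of
    populations are at >= 5% of cells, *rare* if the majority are below 5%,
    and *ultra_rare* if, in addition, at least two populations are below 1%.
    The structure class is taken from generator metadata and never inferred.
    """
    sparsity = dataset.sparsity
    structure = str(dataset.meta.get("structure", "unknown"))
    if dataset.labels is None:
        return StructuralProfile(sparsity=sparsity, proportions={},
                                 structure_class=structure,
                                 rarity_class="unknown")
    labels = dataset.labels.astype(str)
    names, counts = np.unique(labels, return_counts=True)
    props = {str(nm): float(c) / labels.size for nm, c in zip(names, counts)}
    fracs = np.array(list(props.values()))
    n_rare = int(np.sum(fracs < RARE_THRESHOLD))
    if n_rare > fracs.size / 2:
        rarity = "rare"
        if int(np.sum(fracs < ULTRA_RARE_THRESHOLD)) >= 2:
            rarity = "ultra_rare"
    else:
        rarity = "abundant"
    return StructuralProfile(sparsity=sparsity, proportions=props,
                             structure_class=structure, rarity_class=rarity)


def sparsity_band(sparsity: float) -> str:
    """Nearest named band (low / moderate / high) for a zero fraction."""
    centers = {name: 0.5 * (lo + hi) for name, (lo, hi) in SPARSITY_BANDS.items()}
    return min(centers, key=lambda nm: abs(centers[nm] - sparsity))


GLOBAL_METRICS = ["pearson", "cosine", "bray_curtis", "kendall"]

# Keyed by (structure, rarity, sparsity band); None acts as a wildcard level.
# Encodes the study's main recommendations: the four globally preferred
# metrics; small neighbourhoods (3, 10) for rare populations; large
# neighbourhoods and the sparsity-robust trio for highly sparse discrete data.
DEFAULT_RECOMMENDATIONS: Dict[Tuple, Dict[str, list]] = {
    (None, None, None): {"metrics": list(GLOBAL_METRICS), "k": [10, 30]},
    (None, "rare", None): {"metrics": list(GLOBAL_METRICS), "k": [3, 10]},
    (None, "ultra_rare", None): {"metrics": ["bray_curtis", "cosine"], "k": [3, 10]},
    ("discrete", "abundant", "high"): {"metrics": ["bray_curtis", "cosine", "pearson"],
                                       "k": [30, 50, 100]},
    ("discrete", "rare", "high"): {"metrics": ["cosine", "pearson"], "k": [3]},
    (None, None, "moderate"): {"metrics": ["bray_curtis", "cosine", "pearson"],
                               "k": [10, 30]},
}


def recommend_metrics(prof: StructuralProfile,
                      table: Optional[Dict[Tuple, Dict[str, list]]] = None) -> Dict[str, list]:
    """Look up recommended metrics and neighbourhood sizes for a profile.

    The mapping is editable; lookup tries (structure, rarity, band), then
    progressively more general keys, and falls back to the global defaults
    (Pearson, Cosine, Bray-Curtis, Kendall) with a warning when no specific
    entry exists.
    """
    table = DEFAULT_RECOMMENDATIONS if table is None else table
    band = sparsity_band(prof.sparsity)
    struct = prof.structure_class if prof.structure_class != "unknown" else None
    rarity = prof.rarity_class if prof.rarity_class != "unknown" else None
    candidates = [
        (struct, rarity, band),
        (struct, rarity, None),
        (None, rarity, band),
        (None, rarity, None),
        (None, None, band),
        (None, None, None),
    ]
    for key in candidates:
        if key in table:
            if key == (None, None, None):
                warnings.warn("no specific recommendation for "
                              f"(structure={struct}, rarity={rarity}, band={band}); "
                              "falling back to the global defaults")
            rec = table[key]
            return {"metrics": list(rec["metrics"]), "k": list(rec["k"]),
                    "key": key}
    warnings.warn("recommendation table has no global fallback; using built-in defaults")
    return {"metrics": list(GLOBAL_METRICS), "k": [10, 30], "key": None}
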