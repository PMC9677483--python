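# Methods

This note documents the models, formulas, parameters and design decisions
behind `proxeval`: what each component computes, which knobs matter, and
what the synthetic data does and does not emulate.

## Pipeline overview

A labelled cells × genes count matrix is QC-filtered and normalized, a
dissimilarity matrix is computed for each proximity metric, a KNN graph is
built at each neighbourhood size k, Leiden community detection is run at an
automatically tuned resolution with several random seeds, and each partition
is scored against the ground-truth labels with PSI (plus ARI and AMI).
Per-(metric, k) means over seeds are averaged across k into a grand-mean PSI
that ranks metrics.

## Preprocessing

Fixed order: cells, then genes, then normalization — gene detection
fractions depend on the retained cell set.

* `filter_cells`: remove cells with non-zero expression for fewer than
  `min_genes` (default 200) genes, and cells with strictly more than
  `max_mito_frac` (default 0.10) of their total counts from
  mitochondrial genes (mask = gene-name prefix match, default `MT-`,
  case-insensitive).  Synthetic data carries an all-false mask.
* `filter_genes`: keep genes with a count ≥ 1 in at least `min_cell_frac`
  (default 0.10) of the remaining cells.
* `normalize_log`: x → ln(1 + scale · x / total), scale 10 000.  Cells with
  zero totals stay all-zero and are flagged.  Conservation check: row sums
  of exp(·) − 1 equal the scale factor.
* `select_hvg`: dispersion (variance/mean) of the normalized values,
  z-scored within 20 equal-frequency mean bins; genes ranked by normalized
  dispersion with ties broken by raw dispersion then gene order, so
  selection is deterministic.  This is implemented directly rather than
  through a toolkit call to keep the tie-break contract explicit.
* `binarize`: counts ≥ 1 → 1 (idempotent); applied to raw counts only.

## Proximity metrics

Each metric consumes a specific value space:

| space         | definition                          | metrics |
|---------------|-------------------------------------|---------|
| `normalized`  | ln(1 + 10⁴·x/total)                | euclidean, manhattan, canberra, chebyshev, pearson, spearman, kendall, weighted_rank, zi_kendall, cosine |
| `binary`      | presence/absence of raw counts      | hamming, yule, kulsinski, jaccard |
| `proportions` | 10⁴·x/total (pre-log)              | bray_curtis, phi, ot |

Formulas (x, y are one cell's vector over g genes; c11/c10/c01/c00 the 2×2
binary agreement counts, n their sum):

* Euclidean √Σ(xᵢ−yᵢ)², Manhattan Σ|xᵢ−yᵢ|, Chebyshev max|xᵢ−yᵢ|,
  Canberra Σ|xᵢ−yᵢ|/(|xᵢ|+|yᵢ|) with 0/0 terms contributing 0.
* Hamming (c10+c01)/n; Jaccard (c10+c01)/(c11+c10+c01) (0 when empty);
  Yule 2·c10·c01/(c11·c00+c10·c01) (0 when the denominator is 0);
  Kulsinski (c10+c01−c11+n)/(c10+c01+n).  Kulsinski's self-dissimilarity
  is inherently non-zero; the matrix diagonal is forced to 0 (neighbour
  search excludes self regardless).
* Correlations are converted by d = 1 − r (range [0, 2]); a zero-variance
  vector gets r = 0 (d = 1) with a warning.  Kendall is tau-b;
  weighted-rank is the weighted Kendall tau with additive hyperbolic
  weights 1/(1+rank), averaged over both reference orderings (top ranks
  count more).  The zero-inflated Kendall estimator is
  τ\* = p̂₁₁²·τ₁₁ + 2(p̂₀₀p̂₁₁ − p̂₀₁p̂₁₀), where the p̂ terms are the
  fractions of gene positions in each joint zero/non-zero category and τ₁₁
  is tau-b on the doubly non-zero positions (0 if fewer than two).
* Bray-Curtis Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ) (two all-zero cells → 0, warned).  Phi is
  the symmetric proportionality statistic
  var(ln(x+ε) − ln(y+ε)) / (var ln(x+ε) + var ln(y+ε)) with pseudocount
  ε = 1 on the proportion-space values.
* Cosine 1 − x·y/(‖x‖‖y‖); an all-zero vector gives d = 1, warned.
* Optimal transport: debiased entropic OT (Sinkhorn divergence)
  S(a,b) = OT_ε(a,b) − ½OT_ε(a,a) − ½OT_ε(b,b), clipped at 0, on cells
  renormalized to probability histograms over genes.  The ground cost is
  the pairwise Euclidean distance between gene coordinates in a
  20-component principal subspace of the genes × cells matrix, rescaled to
  max 1; ε defaults to 0.1.  Sinkhorn runs in the plain domain until the
  L1 marginal error is < 1e-6 or 1000 iterations; OT_ε is evaluated in its
  dual form ε(Σaᵢ ln(uᵢ/aᵢ) + Σbⱼ ln(vⱼ/bⱼ)).  Converged pairs are frozen
  out of the batched iteration so a few slow pairs (typically < 1 %) do
  not dominate runtime; unconverged pairs are reported with their error.

Every matrix is symmetrized ((V+Vᵀ)/2), diagonal-zeroed, and validated
finite, symmetric within 1e-10 and non-negative (negatives above −1e-12
are clamped as vectorization fuzz).

## Graph construction and Leiden tuning

Each cell connects to its k smallest-distance cells, self excluded, ties
broken by cell index (lexicographic (distance, index) sort), so graphs
depend only on distance *ranks* — any monotone transform of a distance
matrix yields the same graph.  The directed relation is union-symmetrized
by default (intersection and 1/(1+d) edge weights are options).

Leiden uses the RB-configuration modularity with a resolution parameter.
The tuner starts at resolution 1.0, doubles/halves until the target cluster
count (the number of distinct ground-truth labels) is straddled, then
bisects geometrically, stopping at the first partition with exactly the
target count (`converged=True`) or after `max_attempts` (default 1000)
Leiden runs.  Bounds are clamped to [1e-5, 1e4]; if the search space is
exhausted at a bound the best partition found (closest count, ties to the
lower resolution) is returned with `converged=False` — re-running at the
same bound and seed would be a no-op, so remaining attempts are not burned.
Everything is deterministic for a fixed seed; replicate seeds derive from a
base seed via `numpy.random.SeedSequence`.

## External validity

PSI builds the K × K′ contingency table, forms pair similarities
S₍ᵢⱼ₎ = nᵢⱼ/max(aᵢ, bⱼ), pairs clusters by maximum-weight bipartite
matching (Hungarian algorithm; unmatched clusters contribute 0), and
adjusts the total matched similarity S for chance with
E[S] = Σ aᵣbᵣ/(n·max(aᵣ, bᵣ)) over size-sorted marginals:
PSI = max(0, (S − E[S])/(max(K, K′) − E[S])).  It is 1 for identical
partitions up to renaming, symmetric, and invariant to label permutation.

A known finite-size property: because S is an *optimum* over matchings
while E[S] is the expectation of the fixed size-sorted matching, uniformly
random partitions score slightly above 0 (mean ≈ 0.026 for 5 balanced
random labels against a 300/100/50/30/20 truth at n = 500, shrinking as n
grows).  This bias is intrinsic to the clipped, Hungarian-matched variant
implemented here and is orders of magnitude below any real structure
signal.

ARI and AMI are the standard permutation-model chance-corrected indices
(AMI with arithmetic-mean normalization); they are computed through
scikit-learn and cross-checked in the tests against direct pair-counting
and expected-MI summation.

## Synthetic data

The generator emulates the structural conditions the framework studies:

* **Discrete**: P populations (default 5, equal proportions).  Baseline
  gene means are log-normal (σ = 1); each population's disjoint marker
  block (default 4 % of genes) is multiplied by `marker_fold` (default 5).
  Counts are negative-binomial with size r = 2 (var = μ + μ²/r).
* **Continuous**: a star of P−1 trajectories (default 4) from one origin
  state.  Each cell draws a path and pseudotime t ~ U(0,1); its gene means
  interpolate linearly between the origin profile and the path endpoint
  profile.  Ground-truth labels discretize the topology into origin
  (t below the origin proportion, default 0.2) plus one population per
  path, giving five populations at 20 % each by default.
* **Base sparsity calibration**: gene means are rescaled by a scalar c
  found by bisection so that the *expected* NB zero fraction
  mean((r/(r+cμ))^r) equals the target (default 0.48, the middle of the
  low band 46–50 %).  Observed zero fractions land within the band.
* **Sparsity injection**: dropout is added until the global zero fraction
  reaches the moderate (68–71 %) or high (89–90 %) band.  Per round, each
  cell's number of entries to zero is drawn from a Gaussian centred on its
  share of the global deficit (SD = 10 % of the mean deficit, clipped at
  0, capped by the cell's non-zero count); within a cell, positions are
  sampled without replacement with probability ∝ 1/rank of the entry's
  magnitude (smallest counts drop first), via Gumbel top-k.  Rounds repeat
  until the band is reached; surviving entries are never altered, so the
  operator is monotone and a no-op when already inside the band.  The
  magnitude-biased policy is this package's definition of
  "Gaussian-distributed dropout"; uniform masking can be substituted by
  editing the per-cell weights.
* **Rarity subsetting**: named populations are downsampled without
  replacement so each forms its target fraction of the resulting total
  (±1 cell); untargeted populations are kept whole.
* **Profiling**: sparsity = zero fraction; a dataset is *abundant* if the
  majority of populations are at ≥5 % of cells, *rare* if the majority are
  below 5 %, *ultra-rare* if additionally at least two populations are
  below 1 %.  Structure class comes from generator metadata and is never
  inferred from the data.
* **Recommendations**: a small editable table keyed by
  (structure, rarity, sparsity band) returns suggested metrics and k;
  the global defaults are Pearson, Cosine, Bray-Curtis and Kendall, rare
  profiles get small neighbourhoods (3, 10), and highly sparse discrete
  data gets Bray-Curtis/Cosine/Pearson at large k.  Unknown keys fall back
  with a warning.

What the generator does **not** emulate: sequencing-depth variation per
cell, batch effects, doublets, ambient contamination, gene–gene
correlation beyond marker-block structure, and zero inflation beyond what
the NB dropout plus the injection operator produce.  Passing tests
therefore show that the framework's machinery behaves correctly on data
with planted structure of the intended shape — not that any particular
metric will win on a given real dataset.

## Benchmark orchestration

`run_benchmark` executes QC → spaces → (per metric) distance → (per k)
graph → (per seed) tuned Leiden → scores, with the target cluster count
taken from the ground truth.  Per-run seeds derive from
(base seed, CRC32 of the metric name, k, replicate index), so adding or
removing a metric never perturbs the others' randomness and reruns are
byte-identical.  A metric that raises (or yields non-finite distances) is
logged and skipped without aborting the grid.  `report` writes per-(metric,
k) summaries, the grand-mean ranking, and a metrics × conditions mean-PSI
matrix ready for heatmap plotting.

## Problem sizes in the test suite

End-to-end checks run at desk scale, chosen to keep the default suite in
the minutes range: planted-structure recovery uses the generator's default
2000 × 1500 matrix with a single metric; the structure-ordering check
(all 17 metrics) uses 300–400 cells × 600 genes with an HVG-200
restriction, two neighbourhood sizes and two seeds; oracle-equivalence
checks use ≤10 × 8 matrices.  The acceptance script uses the full
2000 × 1500 generator output for the sparsity targets.

## Known limitations

* Kendall-family metrics are O(n² g log g) via per-pair statistics; they
  dominate runtime beyond a few hundred cells.
* The OT ground metric (PCA gene coordinates) and ε = 0.1 are defaults,
  not fitted; OT results should be read as "entropic OT under a generic
  expression-derived gene geometry".
* The weighted-rank and zero-inflated Kendall forms are standard published
  estimators and are configurable; other variants exist.
* The recommendation table encodes coarse, study-level guidance; it is a
  lookup, not a model.
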