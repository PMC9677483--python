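import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import oracles
from proxeval import (METRICS, METRIC_SPACES, DistanceMatrix,
                      binary_dissimilarity, compute_distance_matrix,
                      correlation_dissimilarity, cosine_dissimilarity,
                      default_ot_cost, ot_distance,
                      proportionality_dissimilarity, true_distance,
                      zero_inflated_kendall)
from conftest import make_dataset

# oracle implementations keyed by metric name (pairwise formulas)
PAIR_ORACLES = {
    "euclidean": oracles.euclidean,
    "manhattan": oracles.manhattan,
    "canberra": oracles.canberra,
    "chebyshev": oracles.chebyshev,
    "hamming": oracles.hamming,
    "yule": oracles.yule,
    "kulsinski": oracles.kulsinski,
    "jaccard": oracles.jaccard,
    "pearson": oracles.pearson_d,
    "spearman": oracles.spearman_d,
    "kendall": oracles.kendall_d,
    "weighted_rank": oracles.weighted_tau_d,
    "zi_kendall": oracles.zi_kendall_d,
    "phi": oracles.phi_d,
    "bray_curtis": oracles.bray_curtis,
    "cosine": oracles.cosine_d,
}


def _random_input(metric, rng, n=8, g=8):
    """Random matrix in the metric's input space.  Continuous tie-free values
    for rank-weighted forms; sparse non-negative values elsewhere."""
    space = METRIC_SPACES[metric]
    if space == "binary":
        return (rng.random((n, g)) < 0.5).astype(float)
    if metric == "weighted_rank":
        return rng.random((n, g)) + 0.1  # tie-free
    X = rng.gamma(0.6, 2.0, size=(n, g))
    X[rng.random((n, g)) < 0.4] = 0.0
    if space == "proportions":
        X = X + (X.sum(axis=1, keepdims=True) == 0)  # avoid empty cells
    return X


def oracle_matrix(metric, X, params=None):
    n = X.shape[0]
    D = np.zeros((n, n))
    if metric == "ot":
        C = params["cost"]
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = oracles.sinkhorn_divergence(
                    X[i], X[j], C, params["epsilon"])
        return D
    fn = PAIR_ORACLES[metric]
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = fn(list(X[i]), list(X[j]))
    return D


class TestBruteForceEquivalence:
    @pytest.mark.parametrize("metric", [m for m in METRICS if m != "ot"])
    def test_matrix_equals_double_loop(self, metric, rng):
        """Vectorized pairwise matrices equal an independent per-pair
        evaluation of each formula on small random inputs."""
        for _ in range(3):
            X = _random_input(metric, rng)
            ds = make_dataset(X, space=METRIC_SPACES[metric])
            D = compute_distance_matrix(ds, metric).values
            expected = oracle_matrix(metric, X)
            assert np.allclose(D, expected, atol=1e-10), metric

    def test_ot_matrix_equals_log_domain_sinkhorn(self, rng):
        """Plain-domain batched Sinkhorn agrees with an independent
        log-domain implementation run to machine-tight convergence."""
        X = _random_input("ot", rng, n=6, g=8)
        C = default_ot_cost(X)
        params = {"cost": C, "epsilon": 0.1, "tol": 1e-14, "max_iter": 50_000}
        ds = make_dataset(X, space="proportions")
        D = compute_distance_matrix(ds, "ot", params).values
        expected = oracle_matrix("ot", X, params)
        assert np.allclose(D, expected, atol=1e-10)


class TestWorkedExamples:
    def test_true_distances(self):
        assert true_distance((0, 0), (3, 4), "euclidean") == 5.0
        assert true_distance((1, 0), (0, 1), "canberra") == 2.0
        assert true_distance((1, 5), (4, 1), "chebyshev") == 4.0
        assert true_distance((1, 5), (4, 1), "manhattan") == 7.0

    def test_binary_dissimilarities(self):
        assert binary_dissimilarity([1, 1, 0], [1, 0, 1], "jaccard") == pytest.approx(2 / 3)
        assert binary_dissimilarity([1, 1, 0, 0], [1, 0, 1, 0], "yule") == 1.0
        x = [1, 0, 1, 1]
        assert binary_dissimilarity(x, x, "hamming") == 0.0

    def test_binary_rejects_non_binary(self):
        with pytest.raises(ValueError, match="0/1"):
            binary_dissimilarity([0, 2], [1, 0], "jaccard")

    def test_correlations(self):
        x = np.array([1.0, 2.0, 5.0, 7.0])
        assert correlation_dissimilarity(x, 2 * x + 1, "pearson") == pytest.approx(0.0)
        assert correlation_dissimilarity(x, -x, "kendall") == pytest.approx(2.0)

    def test_zi_kendall_collapses_on_positive_vectors(self, rng):
        x = rng.random(30) + 0.5
        y = rng.random(30) + 0.5
        zi = correlation_dissimilarity(x, y, "zi_kendall")
        kd = correlation_dissimilarity(x, y, "kendall")
        assert zi == pytest.approx(kd, abs=1e-12)

    def test_zero_variance_flagged_as_one(self):
        assert correlation_dissimilarity([2, 2, 2], [1, 2, 3], "pearson") == 1.0

    def test_proportionality(self):
        assert proportionality_dissimilarity((1, 2), (2, 1), "bray_curtis") == pytest.approx(1 / 3)
        x = np.array([1.0, 4.0, 2.0])
        assert proportionality_dissimilarity(x, x, "bray_curtis") == 0.0
        # phi(x, c*x) -> 0 as the pseudocount vanishes (log-ratio constant)
        assert proportionality_dissimilarity(x, 3 * x, "phi",
                                             pseudocount=1e-9) == pytest.approx(0.0, abs=1e-6)

    def test_cosine(self):
        x = np.array([1.0, 2.0, 0.5])
        assert cosine_dissimilarity(x, 4 * x) == pytest.approx(0.0, abs=1e-12)
        assert cosine_dissimilarity((1, 0), (0, 1)) == pytest.approx(1.0)
        assert cosine_dissimilarity((1, 0), (0, 3)) == pytest.approx(1.0)

    def test_ot_point_masses(self):
        C = np.array([[0.0, 1.0], [1.0, 0.0]])
        x = np.array([1.0, 0.0])
        y = np.array([0.0, 1.0])
        # unit mass forced across cost 1: divergence 1 for any epsilon
        assert ot_distance(x, y, C, epsilon=0.05) == pytest.approx(1.0, abs=1e-9)
        assert ot_distance(x, x, C, epsilon=0.05) == pytest.approx(0.0, abs=1e-12)

    def test_ot_symmetry(self, rng):
        g = 6
        C = default_ot_cost(rng.random((8, g)))
        x = rng.random(g) + 0.01
        y = rng.random(g) + 0.01
        a = ot_distance(x, y, C, epsilon=0.1, tol=1e-10, max_iter=20_000)
        b = ot_distance(y, x, C, epsilon=0.1, tol=1e-10, max_iter=20_000)
        assert a == pytest.approx(b, abs=1e-8)


class TestContracts:
    def test_unknown_metric(self, toy_dataset):
        with pytest.raises(ValueError, match="unknown metric"):
            compute_distance_matrix(toy_dataset, "minkowski3")

    def test_input_space_mismatch(self, toy_dataset):
        # raw counts are not a binarized matrix
        with pytest.raises(ValueError, match="input space"):
            compute_distance_matrix(toy_dataset, "yule")

    def test_identical_cells_zero_distance(self):
        X = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        ds = make_dataset(X, space="normalized")
        D = compute_distance_matrix(ds, "euclidean").values
        assert D[0, 1] == 0.0

    def test_distance_matrix_invariants_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(values=np.array([[0.0, 1.0], [2.0, 0.0]]), metric="x")
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(values=np.array([[1.0, 0.0], [0.0, 0.0]]), metric="x")
        with pytest.raises(ValueError, match="non-finite"):
            DistanceMatrix(values=np.full((2, 2), np.nan), metric="x")


FAST_METRICS = [m for m in METRICS if m != "ot"]


@st.composite
def expression_matrix(draw):
    n = draw(st.integers(3, 6))
    g = draw(st.integers(4, 8))
    X = draw(arrays(np.float64, (n, g),
                    elements=st.floats(0, 50, allow_nan=False, width=16)))
    return X


class TestMetricProperties:
    @settings(max_examples=25, deadline=None)
    @given(X=expression_matrix(), data=st.data())
    def test_axioms_self_symmetry_nonneg(self, X, data):
        """d(x,x)=0, symmetry and non-negativity for every metric family."""
        metric = data.draw(st.sampled_from(FAST_METRICS))
        space = METRIC_SPACES[metric]
        if space == "binary":
            X = (X > np.median(X)).astype(float)
        if space == "proportions":
            X = X + (X.sum(axis=1, keepdims=True) == 0)
        ds = make_dataset(X, space=space)
        D = compute_distance_matrix(ds, metric).values
        assert np.allclose(np.diagonal(D), 0.0)
        assert np.allclose(D, D.T, atol=1e-10)
        assert D.min() >= 0

    @settings(max_examples=25, deadline=None)
    @given(X=expression_matrix(), data=st.data())
    def test_triangle_inequality_for_true_distances(self, X, data):
        metric = data.draw(st.sampled_from(
            ["euclidean", "manhattan", "chebyshev", "canberra", "hamming"]))
        if metric == "hamming":
            X = (X > np.median(X)).astype(float)
        ds = make_dataset(X, space=METRIC_SPACES[metric])
        D = compute_distance_matrix(ds, metric).values
        n = D.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-9

    def test_scale_invariance_contrast(self, rng):
        """Correlation/cosine metrics ignore per-cell scaling; Euclidean and
        Manhattan do not."""
        X = rng.random((5, 12)) + 0.1
        Xs = X * rng.uniform(2, 9, size=(5, 1))
        for metric in ("cosine", "pearson", "spearman", "kendall", "weighted_rank"):
            a = compute_distance_matrix(make_dataset(X, space="normalized"), metric).values
            b = compute_distance_matrix(make_dataset(Xs, space="normalized"), metric).values
            assert np.allclose(a, b, atol=1e-9), metric
        for metric in ("euclidean", "manhattan"):
            a = compute_distance_matrix(make_dataset(X, space="normalized"), metric).values
            b = compute_distance_matrix(make_dataset(Xs, space="normalized"), metric).values
            assert not np.allclose(a, b, atol=1e-6), metric
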