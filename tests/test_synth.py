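import numpy as np
import pytest

from proxeval import (SPARSITY_BANDS, StructuralProfile, SynthConfig,
                      generate_continuous, generate_discrete, inject_sparsity,
                      profile, recommend_metrics, sparsity_band, subset_rarity)


def small_discrete(**kw):
    base = dict(n_cells=400, n_genes=300, seed=7)
    base.update(kw)
    return generate_discrete(SynthConfig(**base))


class TestGenerateDiscrete:
    def test_population_counts_match_proportions(self):
        props = [0.3, 0.2, 0.15, 0.1, 0.1, 0.05, 0.05, 0.05]
        ds = small_discrete(n_cells=1000, n_populations=8, proportions=props)
        names, counts = np.unique(ds.labels.astype(str), return_counts=True)
        assert len(names) == 8
        got = dict(zip(names, counts))
        for i, p in enumerate(props):
            assert abs(got[f"pop_{i}"] - p * 1000) <= 1

    def test_same_seed_reproducible(self):
        a = small_discrete()
        b = small_discrete()
        assert np.array_equal(a.dense(), b.dense())
        assert list(a.labels) == list(b.labels)

    def test_infeasible_proportions_raise(self):
        with pytest.raises(ValueError, match="infeasible"):
            generate_discrete(SynthConfig(n_cells=10, n_populations=3,
                                          proportions=[0.9, 0.08, 0.02], seed=0))

    def test_base_sparsity_calibration(self):
        ds = small_discrete(n_cells=800, n_genes=500)
        lo, hi = SPARSITY_BANDS["low"]
        assert lo <= ds.sparsity <= hi

    def test_population_means_converge(self):
        """Law of large numbers: per-population empirical gene means approach
        the configured negative-binomial means."""
        ds = generate_discrete(SynthConfig(n_cells=5000, n_genes=200,
                                           n_populations=4, seed=3))
        means = ds.meta["pop_means"]
        X = ds.dense()
        labels = ds.labels.astype(str)
        for i in range(4):
            emp = X[labels == f"pop_{i}"].mean(axis=0)
            # aggregate over genes: the overall expression level is unbiased
            assert emp.mean() == pytest.approx(means[i].mean(), rel=0.05)
            # and per-gene means correlate near-perfectly with the target
            assert np.corrcoef(emp, means[i])[0, 1] > 0.95


class TestGenerateContinuous:
    def test_five_labels_for_four_paths(self):
        ds = generate_continuous(SynthConfig(n_cells=600, n_genes=300,
                                             structure="continuous",
                                             n_populations=5, seed=2))
        names = set(ds.labels.astype(str))
        assert names == {"origin", "path_0", "path_1", "path_2", "path_3"}
        # equal 20% proportions on average (origin fraction = 0.2)
        _, counts = np.unique(ds.labels.astype(str), return_counts=True)
        assert counts.min() > 0.12 * 600

    def test_origin_cells_share_profile_across_paths(self):
        """Early-pseudotime cells sit at the shared origin regardless of
        path: their centroids are closer to each other than path endpoints
        are to one another."""
        ds = generate_continuous(SynthConfig(n_cells=2000, n_genes=300,
                                             structure="continuous", seed=4))
        X = ds.dense()
        t = ds.meta["pseudotime"]
        path = ds.meta["path"]
        early = [X[(path == p) & (t < 0.15)].mean(axis=0) for p in range(4)]
        late = [X[(path == p) & (t > 0.85)].mean(axis=0) for p in range(4)]
        d_early = np.linalg.norm(early[0] - early[1])
        d_late = np.linalg.norm(late[0] - late[1])
        assert d_early < d_late

    def test_adjacent_segments_closer_than_cross_path_endpoints(self):
        ds = generate_continuous(SynthConfig(n_cells=2000, n_genes=300,
                                             structure="continuous", seed=4))
        X = ds.dense()
        t = ds.meta["pseudotime"]
        path = ds.meta["path"]
        mid0 = X[(path == 0) & (t >= 0.2) & (t < 0.6)].mean(axis=0)
        end0 = X[(path == 0) & (t >= 0.6)].mean(axis=0)
        end1 = X[(path == 1) & (t >= 0.6)].mean(axis=0)
        assert np.linalg.norm(mid0 - end0) < np.linalg.norm(end0 - end1)


class TestInjectSparsity:
    def test_reaches_high_band(self):
        ds = small_discrete(n_cells=600, n_genes=400)
        out = inject_sparsity(ds, "high", seed=1)
        lo, hi = SPARSITY_BANDS["high"]
        assert lo <= out.sparsity <= hi

    def test_reaches_moderate_band(self):
        ds = small_discrete(n_cells=600, n_genes=400)
        out = inject_sparsity(ds, "moderate", seed=1)
        lo, hi = SPARSITY_BANDS["moderate"]
        assert lo <= out.sparsity <= hi

    def test_monotone_and_masking_only(self):
        ds = small_discrete()
        out = inject_sparsity(ds, "moderate", seed=2)
        X, Y = ds.dense(), out.dense()
        assert out.sparsity >= ds.sparsity
        surviving = Y != 0
        assert np.array_equal(Y[surviving], X[surviving])

    def test_identity_when_already_at_target(self):
        ds = small_discrete()
        s = ds.sparsity
        with pytest.warns(UserWarning, match="already"):
            out = inject_sparsity(ds, s, seed=0)
        assert np.array_equal(out.dense(), ds.dense())

    def test_target_below_current_raises(self):
        ds = small_discrete()
        out = inject_sparsity(ds, "high", seed=1)
        with pytest.raises(ValueError, match="exceeds"):
            inject_sparsity(out, "moderate", seed=1)

    def test_dropout_favours_low_counts(self):
        ds = small_discrete(n_cells=600, n_genes=400)
        out = inject_sparsity(ds, "high", seed=3)
        X, Y = ds.dense(), out.dense()
        dropped = (X != 0) & (Y == 0)
        kept = (X != 0) & (Y != 0)
        assert X[dropped].mean() < X[kept].mean()


class TestSubsetRarity:
    def test_proportions_hit_within_one_cell(self):
        ds = small_discrete(n_cells=2000, n_populations=4)
        out = subset_rarity(ds, {"pop_0": 0.03, "pop_1": 0.01}, seed=5)
        labels = out.labels.astype(str)
        n = labels.size
        assert abs(np.sum(labels == "pop_0") - 0.03 * n) <= 1
        assert abs(np.sum(labels == "pop_1") - 0.01 * n) <= 1

    def test_untargeted_populations_kept_in_full(self):
        ds = small_discrete(n_cells=1000, n_populations=4)
        before = np.sum(ds.labels.astype(str) == "pop_3")
        out = subset_rarity(ds, {"pop_0": 0.02}, seed=5)
        assert np.sum(out.labels.astype(str) == "pop_3") == before

    def test_labels_are_submultiset(self):
        ds = small_discrete(n_cells=1000, n_populations=4)
        out = subset_rarity(ds, {"pop_0": 0.02}, seed=5)
        assert set(out.cell_ids) <= set(ds.cell_ids)

    def test_targets_summing_to_one_rejected(self):
        ds = small_discrete(n_populations=2)
        with pytest.raises(ValueError, match="sum"):
            subset_rarity(ds, {"pop_0": 0.6, "pop_1": 0.4}, seed=0)

    def test_missing_labels_rejected(self):
        ds = small_discrete()
        ds.labels = None
        with pytest.raises(ValueError, match="labels"):
            subset_rarity(ds, {"pop_0": 0.1}, seed=0)


class TestProfileAndRecommend:
    def test_abundant_profile(self):
        ds = small_discrete(n_cells=500, n_populations=5)
        prof = profile(ds)
        assert prof.rarity_class == "abundant"
        assert prof.structure_class == "discrete"
        assert sum(prof.proportions.values()) == pytest.approx(1.0)

    def test_rare_majority(self):
        ds = small_discrete(n_cells=4000, n_populations=5,
                            proportions=[0.455, 0.425, 0.04, 0.045, 0.035])
        assert profile(ds).rarity_class == "rare"

    def test_ultra_rare_needs_two_tiny_populations(self):
        ds = small_discrete(n_cells=4000, n_populations=5,
                            proportions=[0.49, 0.4875, 0.005, 0.0075, 0.01])
        assert profile(ds).rarity_class == "ultra_rare"

    def test_profile_without_labels(self):
        ds = small_discrete()
        ds.labels = None
        assert profile(ds).rarity_class == "unknown"

    def test_sparsity_band_classification(self):
        assert sparsity_band(0.48) == "low"
        assert sparsity_band(0.70) == "moderate"
        assert sparsity_band(0.895) == "high"

    def test_global_defaults_include_pearson_and_cosine(self):
        prof = StructuralProfile(sparsity=0.48, proportions={},
                                 structure_class="unknown",
                                 rarity_class="unknown")
        with pytest.warns(UserWarning):
            rec = recommend_metrics(prof)
        assert "pearson" in rec["metrics"] and "cosine" in rec["metrics"]

    def test_rare_profiles_get_small_neighbourhoods(self):
        prof = StructuralProfile(sparsity=0.48, proportions={},
                                 structure_class="discrete",
                                 rarity_class="rare")
        rec = recommend_metrics(prof)
        assert 3 in rec["k"] and 10 in rec["k"]

    def test_proportion_invariant_enforced(self):
        with pytest.raises(ValueError, match="sum"):
            StructuralProfile(sparsity=0.5, proportions={"a": 0.5, "b": 0.4})
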