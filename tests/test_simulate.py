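import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mixclust import (
    ScenarioSpec,
    add_irrelevant_variables,
    adjusted_rand_index,
    estimate_separation_index,
    generate_categorical,
    generate_continuous,
    generate_scenario,
    scale_continuous,
    separation_distance,
)
from mixclust.simulate import balanced_sizes, nearest_pair_separation

Z975 = stats.norm.ppf(0.975)


class TestSeparationIndex:
    def test_closed_form_spacing(self):
        # J=0 -> delta = 2z; general J -> 2z(1+J)/(1-J)
        assert separation_distance(0.0) == pytest.approx(2 * Z975)
        assert separation_distance(0.3) == pytest.approx(2 * Z975 * 1.3 / 0.7)

    def test_monte_carlo_confirms_spacing_formula(self):
        # two unit normals at the J=0.3 spacing measure 0.3 +/- 0.05 at n=1e5
        rng = np.random.default_rng(42)
        delta = separation_distance(0.3)
        a = rng.standard_normal(100_000)
        b = rng.standard_normal(100_000) + delta
        assert estimate_separation_index(a, b) == pytest.approx(0.3, abs=0.05)

    def test_identical_samples_negative(self, rng):
        x = rng.standard_normal(500)
        assert estimate_separation_index(x, x) < 0

    def test_disjoint_ranges_positive(self, rng):
        a = rng.uniform(0, 1, 200)
        b = rng.uniform(10, 11, 200)
        assert estimate_separation_index(a, b) > 0

    def test_degenerate_samples_raise(self):
        with pytest.raises(ValueError):
            estimate_separation_index(np.ones(5), np.ones(5))

    @given(
        shift=st.floats(-5, 5),
        scale=st.floats(0.1, 10),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_affine_equivariance(self, shift, scale, seed):
        # the index depends only on relative overlap: invariant under a
        # common positive affine map and under argument order
        r = np.random.default_rng(seed)
        a = r.standard_normal(80)
        b = r.standard_normal(80) + r.uniform(0, 4)
        idx = estimate_separation_index(a, b)
        assert estimate_separation_index(b, a) == pytest.approx(idx)
        assert estimate_separation_index(scale * a + shift, scale * b + shift) == pytest.approx(idx)


class TestGenerateContinuous:
    def test_balanced_sizes(self):
        assert balanced_sizes(6, 6).tolist() == [1, 1, 1, 1, 1, 1]
        assert balanced_sizes(10, 3).tolist() == [4, 3, 3]

    def test_singleton_clusters(self, rng):
        x, labels = generate_continuous(6, 6, 2, 0.0, rng)
        assert np.bincount(labels).tolist() == [1] * 6

    def test_empirical_index_hits_target(self):
        # two clusters at N=1200, projected on the centre line
        for target in (-0.3, 0.0, 0.3):
            vals = []
            for seed in range(10):
                r = np.random.default_rng(seed)
                x, labels = generate_continuous(1200, 2, 4, target, r)
                vals.append(nearest_pair_separation(x, labels))
            assert np.mean(vals) == pytest.approx(target, abs=0.05)

    def test_invalid_requests(self, rng):
        with pytest.raises(ValueError):
            generate_continuous(10, 2, 0, 0.0, rng)  # no variables
        with pytest.raises(ValueError):
            generate_continuous(3, 6, 2, 0.0, rng)  # N < G


class TestGenerateCategorical:
    def test_noise_free_equals_labels(self, rng):
        labels = np.repeat(np.arange(4), 25)
        col = generate_categorical(labels, 4, 0.0, rng)
        assert np.array_equal(col, labels)
        assert adjusted_rand_index(col, labels) == 1.0

    def test_deterministic_resample_count(self, rng):
        # 20% of 150 rows -> exactly 30 resampled; expected own-level match
        # (1 - nu) + nu/G = 0.8 + 0.2/3
        labels = np.repeat(np.arange(3), 50)
        changed = []
        match = []
        for seed in range(200):
            col = generate_categorical(labels, 3, 0.2, np.random.default_rng(seed))
            changed.append(int((col != labels).sum()))
            match.append((col == labels).mean())
        assert max(changed) <= 30  # resampling may redraw the same level
        expected = 0.8 + 0.2 / 3
        assert np.mean(match) == pytest.approx(expected, abs=0.01)

    def test_full_noise_match_within_binomial_band(self):
        labels = np.repeat(np.arange(6), 200)  # N = 1200
        col = generate_categorical(labels, 6, 1.0, np.random.default_rng(3))
        k = int((col == labels).sum())
        lo, hi = stats.binom.interval(0.99, 1200, 1 / 6)
        assert lo <= k <= hi


class TestIrrelevantVariables:
    def test_noop_when_zero(self, default_dataset):
        out = add_irrelevant_variables(default_dataset, 0, 0, np.random.default_rng(0))
        assert out is default_dataset

    def test_appended_columns_marked_irrelevant(self, default_dataset, rng):
        out = add_irrelevant_variables(default_dataset, 2, 3, rng)
        assert out.n_continuous == 6 and out.n_categorical == 7
        assert [m.relevant for m in out.continuous_meta] == [True] * 4 + [False] * 2
        assert [m.relevant for m in out.categorical_meta] == [True] * 4 + [False] * 3
        assert np.all(out.level_counts[4:] == 6)

    def test_irrelevant_column_ari_near_zero(self):
        # ARI of a padding column (as a partition) vs truth: mean within 3 SE of 0
        aris = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            ds = generate_scenario(
                ScenarioSpec(population_size=120, n_clusters=3), r, scale=False
            )
            ds = add_irrelevant_variables(ds, 0, 1, r)
            aris.append(adjusted_rand_index(ds.categorical[:, -1], ds.true_labels))
        aris = np.asarray(aris)
        se = aris.std(ddof=1) / np.sqrt(len(aris))
        assert abs(aris.mean()) < 3 * se

    def test_irrelevant_columns_independent_of_labels(self):
        # chi-square p-values should be uniform across replicates
        pvals = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            labels = np.repeat(np.arange(3), 80)
            ds = generate_scenario(
                ScenarioSpec(population_size=240, n_clusters=3), r, scale=False
            )
            ds = add_irrelevant_variables(ds, 0, 1, r)
            table = np.zeros((3, 3))
            np.add.at(table, (ds.true_labels, ds.categorical[:, -1]), 1)
            pvals.append(stats.chi2_contingency(table)[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestScaling:
    def test_three_point_column(self, make_mixed):
        small = make_mixed([1.0, 2.0, 3.0], [[0], [0], [0]], [1])
        out = scale_continuous(small)
        np.testing.assert_allclose(out.continuous[:, 0], [-1.0, 0.0, 1.0])

    def test_mean_zero_sd_one_and_idempotent(self, default_dataset):
        out = scale_continuous(default_dataset)
        assert np.all(np.abs(out.continuous.mean(axis=0)) < 1e-12)
        np.testing.assert_allclose(out.continuous.std(axis=0, ddof=1), 1.0, atol=1e-12)
        again = scale_continuous(out)
        np.testing.assert_allclose(again.continuous, out.continuous, atol=1e-10)

    def test_constant_column_named_in_error(self, make_mixed):
        bad = make_mixed(np.ones(5), np.zeros((5, 1)), [1])
        with pytest.raises(ValueError, match="num1"):
            scale_continuous(bad)


class TestGenerateScenario:
    def test_default_shape(self, default_dataset):
        ds = default_dataset
        assert (ds.n_obs, ds.n_continuous, ds.n_categorical) == (300, 4, 4)
        assert ds.n_clusters == 6
        assert np.all(ds.level_counts == 6)
        assert all(m.relevant for m in ds.continuous_meta + ds.categorical_meta)

    def test_levels_equal_cluster_count(self):
        ds = generate_scenario(ScenarioSpec(n_clusters=2), np.random.default_rng(5))
        assert np.all(ds.level_counts == 2)
        assert set(np.unique(ds.categorical)) <= {0, 1}

    def test_irrelevant_padding_counts(self):
        spec = ScenarioSpec(n_categorical=10, prop_relevant_categorical=0.2)
        ds = generate_scenario(spec, np.random.default_rng(7))
        assert ds.n_categorical == 10
        assert sum(m.relevant for m in ds.categorical_meta) == 2

    def test_bit_reproducible(self):
        a = generate_scenario(ScenarioSpec(), np.random.default_rng(99))
        b = generate_scenario(ScenarioSpec(), np.random.default_rng(99))
        np.testing.assert_array_equal(a.continuous, b.continuous)
        np.testing.assert_array_equal(a.categorical, b.categorical)
        np.testing.assert_array_equal(a.true_labels, b.true_labels)
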