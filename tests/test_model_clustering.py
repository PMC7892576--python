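import numpy as np
import pytest
from scipy import stats

from mixclust import (
    ScenarioSpec,
    adjusted_rand_index,
    discretize_tertiles,
    em_mixture,
    generate_scenario,
    kamila,
    lca,
    lca_pipeline,
    lcm_cluster,
    mixmod_cluster,
)


class TestEMMixture:
    def test_single_component_closed_form(self, make_mixed):
        r = np.random.default_rng(0)
        x = r.standard_normal((50, 2)) * [1.0, 2.0] + [0.5, -1.0]
        cats = r.integers(0, 3, (50, 1))
        ds = make_mixed(x, cats, [3])
        part, fit = em_mixture(ds, 1, rng=r)
        np.testing.assert_allclose(fit.tau, [1.0])
        np.testing.assert_allclose(fit.means[0], x.mean(axis=0), atol=1e-8)
        np.testing.assert_allclose(fit.variances[0], x.var(axis=0), rtol=1e-6)
        freqs = np.bincount(cats[:, 0], minlength=3) / 50
        np.testing.assert_allclose(fit.cat_probs[0][0], freqs, atol=1e-8)
        # saturated single-component log-likelihood in closed form
        expected = (
            sum(stats.norm.logpdf(x[:, j], x[:, j].mean(), x[:, j].std()).sum() for j in range(2))
            + sum(np.log(freqs[c]) for c in cats[:, 0])
        )
        assert fit.loglik == pytest.approx(expected, rel=1e-6)

    def test_recovers_two_separated_gaussians(self, make_mixed):
        r = np.random.default_rng(1)
        x = np.concatenate([r.normal(0, 1, 200), r.normal(6, 1, 200)])
        truth = np.repeat([0, 1], 200)
        ds = make_mixed(x, np.zeros((400, 0), dtype=int), [])
        part, fit = em_mixture(ds, 2, n_init=5, rng=r)
        order = np.argsort(fit.means[:, 0])
        assert abs(fit.means[order[0], 0] - 0) < 0.1
        assert abs(fit.means[order[1], 0] - 6) < 0.1
        assert adjusted_rand_index(part.labels, truth) >= 0.95

    def test_soft_loglik_monotone(self):
        for seed in range(10):
            ds = generate_scenario(
                ScenarioSpec(population_size=60, n_clusters=3, n_continuous=2, n_categorical=2),
                np.random.default_rng(seed),
            )
            _, fit = em_mixture(ds, 3, rng=np.random.default_rng(seed + 1))
            assert np.all(np.diff(fit.loglik_trace) >= -1e-7)

    def test_responsibilities_row_stochastic(self, default_dataset):
        _, fit = mixmod_cluster(default_dataset, 6, rng=np.random.default_rng(2))
        np.testing.assert_allclose(fit.responsibilities.sum(axis=1), 1.0, atol=1e-10)

    def test_hard_mode_reports_completed_loglik(self, default_dataset):
        part, fit = mixmod_cluster(default_dataset, 6, rng=np.random.default_rng(3), mode="hard")
        assert fit.completed_loglik is not None
        assert np.isfinite(fit.completed_loglik)
        assert part.labels.shape == (300,)

    def test_lcm_preset_runs_multistart(self, default_dataset):
        part, fit = lcm_cluster(default_dataset, 6, rng=np.random.default_rng(4), n_init=5)
        assert fit.converged or len(fit.loglik_trace) > 1
        assert part.n_clusters == 6


class TestKamila:
    def test_perfectly_separable_instance(self):
        spec = ScenarioSpec(
            population_size=100,
            n_clusters=2,
            n_continuous=2,
            n_categorical=2,
            sep_index_override=0.7,
            noise_prop_override=0.0,
        )
        for seed in range(20):
            ds = generate_scenario(spec, np.random.default_rng(seed))
            part, _ = kamila(ds, 2, n_runs=3, rng=np.random.default_rng(seed + 1000))
            assert adjusted_rand_index(part.labels, ds.true_labels) == 1.0

    def test_cat_probs_normalised(self, default_dataset):
        _, fit = kamila(default_dataset, 6, n_runs=2, rng=np.random.default_rng(5))
        for probs in fit.cat_probs:
            np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-10)

    def test_initialisation_invariance_up_to_relabeling(self, easy_dataset):
        # on separable data two independent fits agree perfectly up to a
        # permutation of cluster indices; ARI is the relabeling-invariant gauge
        a, _ = kamila(easy_dataset, 3, n_runs=3, rng=np.random.default_rng(6))
        b, _ = kamila(easy_dataset, 3, n_runs=3, rng=np.random.default_rng(60))
        assert adjusted_rand_index(a.labels, b.labels) == 1.0

    def test_categorical_only_falls_back_to_mixture_em(self, make_mixed, caplog):
        labels = np.repeat([0, 1], 20)
        ds = make_mixed(np.zeros((40, 0)), labels[:, None], [2])
        with caplog.at_level("WARNING"):
            part, fit = kamila(ds, 2, rng=np.random.default_rng(0))
        assert "falling back" in caplog.text
        assert adjusted_rand_index(part.labels, labels) == 1.0


class TestDiscretizeTertiles:
    def test_one_to_nine(self):
        codes = discretize_tertiles(np.arange(1.0, 10.0))
        assert codes.tolist() == [0, 0, 0, 1, 1, 1, 2, 2, 2]

    def test_balanced_on_normal_sample(self):
        x = np.random.default_rng(7).standard_normal(300)
        sizes = np.bincount(discretize_tertiles(x))
        assert sizes.tolist() == [100, 100, 100]

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError):
            discretize_tertiles(np.full(10, 3.0))

    def test_heavy_ties_fall_back_to_ranks(self, caplog):
        x = np.array([0.0] * 28 + [1.0, 2.0])
        with caplog.at_level("WARNING"):
            codes = discretize_tertiles(x)
        assert np.unique(codes).size == 3


class TestLCA:
    def test_single_perfect_variable_recovers_partition(self, make_mixed):
        labels = np.repeat(np.arange(3), 30)
        ds = make_mixed(np.zeros((90, 0)), labels[:, None], [3], labels=labels)
        part, _ = lca(ds, 3, rng=np.random.default_rng(0))
        assert adjusted_rand_index(part.labels, labels) == 1.0

    def test_single_component_closed_form(self, make_mixed):
        r = np.random.default_rng(1)
        cats = r.integers(0, 4, (60, 2))
        ds = make_mixed(np.zeros((60, 0)), cats, [4, 4])
        _, fit = lca(ds, 1, n_runs=1, rng=r)
        np.testing.assert_allclose(fit.tau, [1.0])
        for j in range(2):
            freqs = np.bincount(cats[:, j], minlength=4) / 60
            np.testing.assert_allclose(fit.cat_probs[j][0], freqs, atol=1e-8)

    def test_loglik_monotone_and_tolerance_stop(self, make_mixed):
        r = np.random.default_rng(2)
        cats = r.integers(0, 3, (60, 3))
        ds = make_mixed(np.zeros((60, 0)), cats, [3, 3, 3])
        _, fit = lca(ds, 2, n_runs=2, rng=r)
        diffs = np.diff(fit.loglik_trace)
        assert np.all(diffs >= -1e-8)
        if fit.converged:
            assert abs(diffs[-1]) < 1e-10

    def test_rejects_continuous_input(self, make_mixed):
        ds = make_mixed(np.zeros((10, 1)), np.zeros((10, 1), dtype=int), [1])
        with pytest.raises(ValueError):
            lca(ds, 2)

    def test_pipeline_discretizes_then_clusters(self, easy_dataset):
        part, fit = lca_pipeline(easy_dataset, 3, rng=np.random.default_rng(3))
        # 2 continuous become tertile variables (3 levels), 2 categorical stay
        assert len(fit.cat_probs) == 4
        assert fit.cat_probs[0].shape == (3, 3)
        assert adjusted_rand_index(part.labels, easy_dataset.true_labels) > 0.6
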