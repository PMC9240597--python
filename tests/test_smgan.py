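import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gmploc.dataset import MultiLabelDataset
from gmploc.smgan import (GANTrainConfig, discriminator_objective,
                          distance_term, generator_objective, plan_rebalance,
                          rebalance_dataset, synthesize, train_smgan)
from tests.conftest import make_toy_dataset


class TestDistanceTerm:
    def test_zero_distance_floored_at_epsilon(self):
        mean = np.ones(4)
        d = distance_term(np.ones((3, 4)), mean, epsilon=1e-6)
        np.testing.assert_allclose(d, 1e-6)

    def test_three_four_five(self):
        d = distance_term(np.array([[3.0, 4.0]]), np.zeros(2), epsilon=1e-9)
        assert d[0] == pytest.approx(5.0)

    def test_matches_brute_force(self, rng):
        batch = rng.normal(size=(10, 6))
        mean = rng.normal(size=6)
        expected = [np.sqrt(((b - mean) ** 2).sum()) for b in batch]
        np.testing.assert_allclose(distance_term(batch, mean, 1e-12), expected)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            distance_term(rng.normal(size=(2, 3)), rng.normal(size=4), 1e-6)


class TestObjectives:
    def test_discriminator_worked_case(self):
        val = discriminator_objective([0.9], [0.2], [0.5])
        assert val == pytest.approx(np.log(0.9) + np.log(0.8) + np.log(0.5))

    def test_perfect_discriminator_unit_distance_near_zero(self):
        eps = 1e-9
        assert discriminator_objective([1 - eps], [eps], [1.0]) == pytest.approx(0.0, abs=1e-4)

    def test_unit_distance_reduces_to_standard_gan(self, rng):
        p_r, p_f = rng.uniform(0.1, 0.9, 5), rng.uniform(0.1, 0.9, 5)
        with_d = discriminator_objective(p_r, p_f, np.ones(5))
        standard = np.log(p_r).mean() + np.log1p(-p_f).mean()
        assert with_d == pytest.approx(standard)

    def test_generator_worked_case(self):
        assert generator_objective([0.2], [0.5], 1.0) == pytest.approx(
            -np.log(0.2) + np.log(0.5))

    def test_lambda_zero_is_non_saturating_loss(self, rng):
        p_f = rng.uniform(0.05, 0.95, 8)
        assert generator_objective(p_f, rng.uniform(0.1, 2.0, 8), 0.0) == \
            pytest.approx((-np.log(p_f)).mean())

    def test_half_probability_unit_distance(self):
        assert generator_objective([0.5], [1.0], 3.7) == pytest.approx(np.log(2))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_objectives_finite_under_extreme_inputs(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(1, 6))
        p_r = r.uniform(0, 1, n)       # includes exact 0/1 occasionally
        p_f = np.round(r.uniform(0, 1, n))
        dist = np.maximum(r.exponential(1.0, n), 1e-12)
        assert np.isfinite(discriminator_objective(p_r, p_f, dist))
        assert np.isfinite(generator_objective(p_f, dist, r.uniform(0, 2)))


class TestTraining:
    def test_recovers_toy_gaussian_mean(self):
        rng = np.random.default_rng(42)
        true_mean = np.array([1.5, -0.5])
        samples = true_mean + rng.normal(0, 1.0, size=(200, 2))
        state = train_smgan(samples, GANTrainConfig(epochs=300, seed=7))
        out = synthesize(state, 500, seed=11)
        assert np.abs(out.mean(axis=0) - true_mean).max() < 0.5

    def test_seeded_determinism(self):
        rng = np.random.default_rng(1)
        samples = rng.normal(size=(20, 2))
        cfg = GANTrainConfig(epochs=5, seed=3)
        s1 = train_smgan(samples, cfg)
        s2 = train_smgan(samples, cfg)
        for a, b in zip(s1.state_arrays(), s2.state_arrays()):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(synthesize(s1, 7, seed=5),
                                      synthesize(s2, 7, seed=5))

    def test_minimum_samples(self):
        with pytest.raises(ValueError, match="at least 2"):
            train_smgan(np.zeros((1, 2)), GANTrainConfig(epochs=1))

    def test_synthesize_contracts(self):
        rng = np.random.default_rng(2)
        state = train_smgan(rng.normal(size=(10, 20, 20)),
                            GANTrainConfig(epochs=2, seed=0))
        assert synthesize(state, 0, seed=1).shape == (0, 20, 20)
        assert synthesize(state, 7, seed=1).shape == (7, 20, 20)
        with pytest.raises(ValueError):
            synthesize(state, -1, seed=1)


class TestRebalancePlan:
    def test_match_majority(self):
        labels = np.zeros((115, 3), dtype=int)
        labels[:100, 0] = 1
        labels[100:110, 1] = 1
        labels[110:, 2] = 1
        plan = plan_rebalance(labels)
        np.testing.assert_array_equal(plan.real_counts, [100, 10, 5])
        np.testing.assert_array_equal(plan.synth_counts, [0, 90, 95])

    def test_ratio_policy(self):
        labels = np.zeros((115, 3), dtype=int)
        labels[:100, 0] = 1
        labels[100:110, 1] = 1
        labels[110:, 2] = 1
        plan = plan_rebalance(labels, policy="ratio", ratio=0.5)
        np.testing.assert_array_equal(plan.synth_counts, [0, 40, 45])

    def test_balanced_is_noop(self):
        labels = np.tile(np.eye(3, dtype=int), (4, 1))
        assert plan_rebalance(labels).synth_counts.sum() == 0

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            plan_rebalance(np.zeros((0, 3)))


class TestRebalanceDataset:
    def test_zero_plan_is_identity(self, toy_dataset):
        plan = plan_rebalance(np.tile(np.eye(2, dtype=int), (5, 1)))
        out = rebalance_dataset(toy_dataset, plan, GANTrainConfig(epochs=1))
        assert out.n_samples == toy_dataset.n_samples

    def test_counts_and_single_label_annotation(self, toy_dataset):
        plan = plan_rebalance(toy_dataset.labels)
        out = rebalance_dataset(toy_dataset, plan,
                                GANTrainConfig(epochs=30, seed=0))
        counts = out.labels.sum(axis=0)
        assert counts[0] == counts[1]  # match-majority conservation
        syn = out.labels[out.synthetic]
        assert (syn.sum(axis=1) == 1).all()
        assert (syn[:, 1] == 1).all()
        assert not out.synthetic[:toy_dataset.n_samples].any()

    def test_synthetic_mean_near_real_mean(self):
        ds = make_toy_dataset(n0=150, n1=60, seed=3)
        plan = plan_rebalance(ds.labels)
        out = rebalance_dataset(ds, plan, GANTrainConfig(epochs=400, seed=1))
        real = ds.features[ds.labels[:, 1] == 1]
        syn = out.features[out.synthetic]
        assert np.abs(syn.mean(axis=0) - real.mean(axis=0)).max() < 0.7

    def test_tiny_pool_falls_back_to_jitter(self, caplog):
        ds = make_toy_dataset(n0=8, n1=1, seed=0)
        plan = plan_rebalance(ds.labels)
        with caplog.at_level(logging.WARNING, logger="gmploc.smgan"):
            out = rebalance_dataset(ds, plan, GANTrainConfig(epochs=5, seed=0))
        assert "jitter" in caplog.text
        assert out.labels[:, 1].sum() == out.labels[:, 0].sum()

    def test_minority_recall_improves_with_rebalancing(self):
        """Distribution recovery: a linear classifier's minority recall
        rises after GAN rebalancing, over 5 seeds."""
        from sklearn.linear_model import LogisticRegression
        wins = 0
        for seed in range(5):
            tr = make_toy_dataset(n0=200, n1=20, seed=seed)
            te = make_toy_dataset(n0=100, n1=50, seed=seed + 500)
            plan = plan_rebalance(tr.labels)
            aug = rebalance_dataset(tr, plan, GANTrainConfig(epochs=400, seed=seed))
            rec = {}
            for tag, d in (("plain", tr), ("rebalanced", aug)):
                clf = LogisticRegression().fit(d.flat_features(), d.labels[:, 1])
                pred = clf.predict(te.flat_features())
                truth = te.labels[:, 1]
                rec[tag] = (pred[truth == 1] == 1).mean()
            wins += rec["rebalanced"] >= rec["plain"]
        assert wins >= 4
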