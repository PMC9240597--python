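import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gmploc.mldeepfm import (ClassifierConfig, LossConfig, MLDeepFM,
                             decide_labels, deep_forward, fm_forward,
                             fm_interaction, load_model, multilabel_loss,
                             multilabel_loss_grad, predict_scores, save_model,
                             train_mldeepfm)


def brute_force_fm(x, w, V):
    total = float(np.dot(w, x))
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            total += float(np.dot(V[i], V[j])) * x[i] * x[j]
    return total


class TestFMInteraction:
    def test_printed_toy_instance(self):
        x = np.array([1.0, 2.0])
        w = np.array([0.5, -1.0])
        V = np.array([[1.0, 0.0], [0.5, 0.5]])
        assert fm_interaction(x, w, V) == pytest.approx(-0.5)
        assert brute_force_fm(x, w, V) == pytest.approx(-0.5)

    def test_zero_factors_reduce_to_linear(self, rng):
        x, w = rng.normal(size=8), rng.normal(size=8)
        assert fm_interaction(x, w, np.zeros((8, 4))) == pytest.approx(w @ x)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_pooled_identity_equals_double_sum(self, seed):
        r = np.random.default_rng(seed)
        n, k = int(r.integers(2, 12)), int(r.integers(1, 5))
        x, w = r.normal(size=n), r.normal(size=n)
        V = r.normal(size=(n, k))
        assert fm_interaction(x, w, V) == pytest.approx(
            brute_force_fm(x, w, V), abs=1e-6)


class TestForward:
    @pytest.fixture
    def model(self):
        return MLDeepFM(ClassifierConfig(n_features=6, n_labels=4, seed=1))

    def test_zero_head_gives_zero_scores(self, model, rng):
        model.fm_head.W[...] = 0.0
        model.fm_head.b[...] = 0.0
        x = rng.normal(size=(3, 6))
        np.testing.assert_allclose(fm_forward(x, model), 0.0)

    def test_sum_head_reproduces_fm_value(self, model, rng):
        # head summing the FM emission (bypass weights zero) = Eq-style FM value
        model.fm_head.W[...] = 0.0
        model.fm_head.b[...] = 0.0
        model.fm_head.W[:1 + model.config.k_lat, :] = 1.0
        x = rng.normal(size=(2, 6))
        expected = [fm_interaction(xi, model.fm_layer.w, model.fm_layer.V)
                    for xi in x]
        out = fm_forward(x, model)
        for k in range(4):
            np.testing.assert_allclose(out[:, k], expected, atol=1e-10)

    def test_score_shape_contract(self, model, rng):
        assert predict_scores(rng.normal(size=(5, 6)), model).shape == (5, 4)

    def test_zero_deep_network_gives_zeros(self, rng):
        m = MLDeepFM(ClassifierConfig(n_features=4, n_labels=3, seed=0,
                                      include_fm=False, dropout=0.0))
        for p in m.deep.params():
            p[...] = 0.0
        np.testing.assert_allclose(deep_forward(rng.normal(size=(2, 4)), m), 0.0)

    def test_deep_single_hidden_layer_hand_computed(self):
        m = MLDeepFM(ClassifierConfig(n_features=2, n_labels=1, hidden=(2,),
                                      dropout=0.0, include_fm=False, seed=0))
        dense1, _, dense2 = m.deep.layers
        dense1.W[...] = np.eye(2)
        dense1.b[...] = [0.0, -1.0]
        dense2.W[...] = [[1.0], [2.0]]
        dense2.b[...] = [0.5]
        out = deep_forward(np.array([[3.0, 2.0]]), m)
        # relu([3, 2-1]) = [3, 1]; 3*1 + 1*2 + 0.5 = 5.5
        assert out[0, 0] == pytest.approx(5.5)

    def test_deep_head_can_emit_negative_scores(self, rng):
        m = MLDeepFM(ClassifierConfig(n_features=3, n_labels=2, seed=5,
                                      include_fm=False, dropout=0.0))
        scores = deep_forward(rng.normal(size=(200, 3)), m)
        assert (scores < 0).any()

    def test_components_sum(self, rng):
        m = MLDeepFM(ClassifierConfig(n_features=6, n_labels=4, seed=2,
                                      dropout=0.0))
        x = rng.normal(size=(3, 6))
        np.testing.assert_allclose(
            predict_scores(x, m), fm_forward(x, m) + deep_forward(x, m))


class TestDecideLabels:
    def test_threshold(self):
        np.testing.assert_array_equal(
            decide_labels(np.array([0.5, -0.2, 0.1]), 0.0), [1, 0, 1])

    def test_empty_falls_back_to_top1(self):
        np.testing.assert_array_equal(
            decide_labels(np.array([-3.0, -0.5, -1.0]), 0.0), [0, 1, 0])

    def test_tie_at_top_takes_lowest_index(self):
        np.testing.assert_array_equal(
            decide_labels(np.array([-1.0, -1.0, -2.0]), 0.0), [1, 0, 0])


class TestLoss:
    def test_all_equal_point_closed_form(self):
        y = np.array([1, 0, 0])  # a=2 irrelevant, b=1 relevant
        s = np.zeros(3)
        assert multilabel_loss(s, y, LossConfig(plus_one=False)) == \
            pytest.approx(np.log(5))
        assert multilabel_loss(s, y, LossConfig(plus_one=True)) == \
            pytest.approx(np.log(6))

    def test_term_by_term_worked_example(self):
        s, y = np.array([2.0, 0.0, 0.0]), np.array([1, 0, 0])
        expected = np.log(1 + 2 * np.exp(-2) + 2 + np.exp(-2))
        assert multilabel_loss(s, y, LossConfig()) == pytest.approx(expected)

    def test_perfect_separation_limit(self):
        s = np.array([60.0, -60.0, -60.0])
        y = np.array([1, 0, 0])
        assert multilabel_loss(s, y, LossConfig()) == pytest.approx(0.0, abs=1e-12)

    def test_all_labels_relevant_drops_irrelevant_sums(self):
        s, y = np.array([1.0, -1.0]), np.array([1, 1])
        expected = np.log(1 + np.exp(-1) + np.exp(1))
        assert multilabel_loss(s, y, LossConfig()) == pytest.approx(expected)

    def test_batch_sum_and_mean_reductions(self, rng):
        s = rng.normal(size=(4, 5))
        y = np.eye(5, dtype=int)[[0, 2, 1, 4]]
        total = multilabel_loss(s, y, LossConfig(reduction="sum"))
        per = [multilabel_loss(s[i], y[i], LossConfig()) for i in range(4)]
        assert total == pytest.approx(sum(per))
        assert multilabel_loss(s, y, LossConfig(reduction="mean")) == \
            pytest.approx(total / 4)

    def test_no_relevant_label_rejected(self):
        with pytest.raises(ValueError):
            multilabel_loss(np.zeros(3), np.zeros(3, dtype=int), LossConfig())

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_gradient_matches_finite_differences(self, seed):
        r = np.random.default_rng(seed)
        k = int(r.integers(2, 7))
        s = r.normal(scale=2.0, size=k)
        y = (r.random(k) < 0.5).astype(int)
        if y.sum() == 0:
            y[int(r.integers(0, k))] = 1
        cfg = LossConfig(plus_one=bool(r.integers(0, 2)))
        _, grad = multilabel_loss_grad(s, y, cfg)
        for j in range(k):
            sp, sm = s.copy(), s.copy()
            sp[j] += 1e-6
            sm[j] -= 1e-6
            num = (multilabel_loss(sp, y, cfg) - multilabel_loss(sm, y, cfg)) / 2e-6
            assert grad[0, j] == pytest.approx(num, abs=1e-4)

    def test_monotonicity_in_scores(self, rng):
        """Raising a relevant score lowers the loss; raising an
        irrelevant score raises it."""
        s = rng.normal(size=6)
        y = np.array([1, 0, 1, 0, 0, 1])
        base = multilabel_loss(s, y, LossConfig())
        for j in range(6):
            bumped = s.copy()
            bumped[j] += 0.1
            delta = multilabel_loss(bumped, y, LossConfig()) - base
            assert (delta < 0) if y[j] else (delta > 0)


class TestTraining:
    def test_loss_decreases_on_separable_toy(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(-2, 0.5, size=(30, 4)),
                            rng.normal(2, 0.5, size=(30, 4))])
        y = np.zeros((60, 2), dtype=int)
        y[:30, 0] = 1
        y[30:, 1] = 1
        cfg = ClassifierConfig(n_features=4, n_labels=2, epochs=200,
                               learning_rate=1e-3, seed=1)
        _, trace = train_mldeepfm(x, y, cfg)
        assert trace[-1] < trace[0]

    def test_seeded_determinism(self, rng):
        x = rng.normal(size=(20, 3))
        y = np.eye(2, dtype=int)[rng.integers(0, 2, 20)]
        cfg = ClassifierConfig(n_features=3, n_labels=2, epochs=10, seed=4)
        _, t1 = train_mldeepfm(x, y, cfg)
        _, t2 = train_mldeepfm(x, y, cfg)
        assert t1 == t2

    def test_overfits_single_repeated_sample(self):
        x = np.tile([[1.0, -2.0, 0.5]], (8, 1))
        y = np.tile([[1, 0, 1]], (8, 1))
        cfg = ClassifierConfig(n_features=3, n_labels=3, epochs=300,
                               learning_rate=1e-2, dropout=0.0, seed=2)
        model, _ = train_mldeepfm(x, y, cfg)
        pred = decide_labels(model.scores(x[:1])[0], cfg.loss.y0)
        np.testing.assert_array_equal(pred, [1, 0, 1])

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_mldeepfm(np.zeros((0, 3)), np.zeros((0, 2)),
                           ClassifierConfig(n_features=3, n_labels=2, epochs=1))


def test_checkpoint_round_trip(tmp_path, rng):
    x = rng.normal(size=(12, 5))
    y = np.eye(3, dtype=int)[rng.integers(0, 3, 12)]
    cfg = ClassifierConfig(n_features=5, n_labels=3, epochs=3, seed=6)
    model, trace = train_mldeepfm(x, y, cfg)
    save_model(model, tmp_path / "ckpt.npz", label_names=["a", "b", "c"],
               loss_trace=trace)
    loaded, names = load_model(tmp_path / "ckpt.npz")
    assert names == ["a", "b", "c"]
    np.testing.assert_allclose(loaded.scores(x), model.scores(x))
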