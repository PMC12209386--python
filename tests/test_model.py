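"""LSTM cell equations, aggregation, forward contracts, training loop,
hyperparameter search, and the conv-LSTM baseline."""

import numpy as np
import pytest

from subtremor.model import (BaselineConvLSTM, ModelConfig, SearchSpace,
                             TrainConfig, TremorLSTM, aggregate_hidden,
                             build_baseline_convlstm, hyperparameter_search,
                             lstm_step, train_model)


def scalar_params(value: float):
    gates = ("i", "f", "o", "c")
    U = {g: np.array([[value]]) for g in gates}
    W = {g: np.array([[value]]) for g in gates}
    return U, W


class TestLstmStep:
    def test_zero_everything_gives_half_gates(self):
        U, W = scalar_params(0.0)
        out = lstm_step([0.0], [0.0], [0.0], U, W)
        for gate in ("I", "f", "O"):
            assert out[gate] == pytest.approx(0.5)
        assert out["Cbar"] == pytest.approx(0.0)
        assert out["C"] == pytest.approx(0.0)
        assert out["h"] == pytest.approx(0.0)

    def test_scalar_unit_weights_hand_computed(self):
        U, W = scalar_params(1.0)
        out = lstm_step([1.0], [0.0], [0.0], U, W)
        sig1, tanh1 = 1 / (1 + np.exp(-1)), np.tanh(1.0)
        assert out["I"] == pytest.approx(0.73106, abs=1e-5)
        assert out["f"] == pytest.approx(sig1)
        assert out["O"] == pytest.approx(sig1)
        assert out["Cbar"] == pytest.approx(0.76159, abs=1e-5)
        assert out["C"] == pytest.approx(sig1 * tanh1, abs=1e-5)
        assert out["C"] == pytest.approx(0.55677, abs=1e-5)
        assert out["h"] == pytest.approx(sig1 * np.tanh(sig1 * tanh1), abs=1e-5)
        assert out["h"] == pytest.approx(0.36961, abs=1e-5)

    def test_gate_ranges_hold_for_random_weights(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            U = {g: rng.standard_normal((3, 2)) * 3 for g in "ifoc"}
            W = {g: rng.standard_normal((2, 2)) * 3 for g in "ifoc"}
            out = lstm_step(rng.standard_normal(3), rng.standard_normal(2),
                            rng.standard_normal(2), U, W)
            for gate in ("I", "f", "O"):
                assert np.all((out[gate] > 0) & (out[gate] < 1))
            assert np.all((out["Cbar"] > -1) & (out["Cbar"] < 1))

    def test_non_finite_inputs_rejected(self):
        U, W = scalar_params(1.0)
        with pytest.raises(ValueError):
            lstm_step([np.nan], [0.0], [0.0], U, W)


class TestAggregateHidden:
    def test_single_step_passthrough(self):
        h = np.array([[1.0, -2.0]])
        assert np.array_equal(aggregate_hidden(h), [1.0, -2.0])

    def test_literal_sum_over_time(self):
        h = np.array([[1.0], [2.0], [3.0]])
        assert aggregate_hidden(h) == pytest.approx(6.0)

    def test_permutation_invariance(self, rng):
        h = rng.standard_normal((10, 4))
        perm = rng.permutation(10)
        assert np.allclose(aggregate_hidden(h), aggregate_hidden(h[perm]))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            aggregate_hidden(np.empty((0, 4)))


def make_model(n_features=6, n_classes=2, **kw):
    m = TremorLSTM(ModelConfig(n_features=n_features, n_classes=n_classes,
                               hidden_units=kw.pop("hidden_units", 8),
                               fc_widths=kw.pop("fc_widths", (8,)),
                               dropout=kw.pop("dropout", 0.0), seed=0))
    m.fit_normalizer(np.random.default_rng(0).standard_normal((4, 5, n_features)))
    return m


class TestForward:
    def test_probability_simplex(self, rng):
        m = make_model(n_classes=3)
        probs = m.predict_proba(rng.standard_normal((7, 5, 6)))
        assert probs.shape == (7, 3)
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_output_width_matches_class_count(self, rng):
        x = rng.standard_normal((2, 5, 6))
        assert make_model(n_classes=2).predict_proba(x).shape[1] == 2
        assert make_model(n_classes=3).predict_proba(x).shape[1] == 3

    def test_duplicate_inputs_identical_rows(self, rng):
        m = make_model()
        x = rng.standard_normal((1, 5, 6))
        batch = np.concatenate([x, x], axis=0)
        probs = m.predict_proba(batch)
        assert np.array_equal(probs[0], probs[1])

    def test_width_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            make_model(n_features=6).forward(rng.standard_normal((2, 5, 7)))


def separable_toy(n_per_class=10, seed=0):
    """Two classes separated by which half of the features carries energy."""
    rng = np.random.default_rng(seed)
    x, y = [], []
    for label in (0, 1):
        for _ in range(n_per_class):
            v = 0.05 * rng.standard_normal((6, 8))
            cols = slice(0, 4) if label == 0 else slice(4, 8)
            v[:, cols] += 1.0
            x.append(v)
            y.append(label)
    return np.stack(x), np.array(y)


class TestTraining:
    def test_interpolates_tiny_separable_set(self):
        x, y = separable_toy()
        m = TremorLSTM(ModelConfig(n_features=8, n_classes=2, hidden_units=16,
                                   fc_widths=(16,), dropout=0.0, seed=1))
        train_model(m, x, y, x, y,
                    TrainConfig(max_epochs=200, patience=200, l2=0.0, seed=0))
        assert np.mean(m.predict(x) == y) == 1.0

    def test_early_stopping_fires_on_hopeless_validation(self):
        x, y = separable_toy()
        # validation labels shuffled so accuracy cannot improve reliably
        y_bad = np.roll(y, 1)
        m = TremorLSTM(ModelConfig(n_features=8, n_classes=2, hidden_units=8,
                                   fc_widths=(8,), dropout=0.0, seed=1))
        hist = train_model(m, x, y, x, y_bad,
                           TrainConfig(max_epochs=500, patience=5, seed=0))
        assert len(hist["val_acc"]) < 500

    def test_fixed_seed_reproduces_history_bitwise(self):
        x, y = separable_toy()
        runs = []
        for _ in range(2):
            m = TremorLSTM(ModelConfig(n_features=8, n_classes=2,
                                       hidden_units=8, dropout=0.3, seed=2))
            hist = train_model(m, x, y, x, y,
                               TrainConfig(max_epochs=10, patience=10, seed=5))
            runs.append(hist)
        assert runs[0]["loss"] == runs[1]["loss"]
        assert runs[0]["val_acc"] == runs[1]["val_acc"]

    def test_divergence_raises_training_error(self):
        x, y = separable_toy(4)
        m = TremorLSTM(ModelConfig(n_features=8, n_classes=2, hidden_units=4,
                                   seed=0))
        m.out.params["W"][0, 0] = np.inf  # corrupted state -> non-finite loss
        with pytest.raises(FloatingPointError):
            train_model(m, x, y, x, y, TrainConfig(max_epochs=5, seed=0))

    def test_batch_size_outside_printed_range_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(batch_size=8)

    def test_full_batch_loss_non_increasing_without_regularization(self):
        # convex-head sanity: small-lr SGD on a fixed batch
        x, y = separable_toy(5)
        m = TremorLSTM(ModelConfig(n_features=8, n_classes=2, hidden_units=8,
                                   dropout=0.0, seed=3))
        hist = train_model(m, x, y, x, y,
                           TrainConfig(optimizer="sgd", learning_rate=1e-3,
                                       l2=0.0, batch_size=20, max_epochs=30,
                                       patience=30, seed=0))
        losses = hist["loss"]
        assert all(b <= a + 1e-9 for a, b in zip(losses, losses[1:]))


class TestHyperparameterSearch:
    def test_budget_one_returns_that_trial(self):
        res = hyperparameter_search(SearchSpace(), lambda cfg: 0.5, 1, seed=0)
        assert res["best"] == res["trials"][0]["config"]

    def test_sampled_values_respect_printed_grids(self):
        space = SearchSpace()
        rng = np.random.default_rng(0)
        for _ in range(25):
            cfg = space.sample(rng)
            assert cfg["hidden_units"] % 10 == 0
            assert 10 <= cfg["hidden_units"] <= 300
            assert 1e-6 <= cfg["dropout"] <= 1.0
            assert 1e-5 <= cfg["l2"] <= 1.0
            assert 1 <= len(cfg["fc_widths"]) <= 3
            assert all(w % 10 == 0 and 10 <= w <= 300 for w in cfg["fc_widths"])
            assert cfg["batch_size"] % 4 == 0 and 16 <= cfg["batch_size"] <= 128
            assert cfg["optimizer"] in ("sgd", "adam")

    def test_best_dominates_all_trials(self):
        rng = np.random.default_rng(1)
        res = hyperparameter_search(SearchSpace(), lambda cfg: rng.random(),
                                    10, seed=0)
        assert all(res["best_score"] >= t["score"] for t in res["trials"])

    def test_zero_budget_rejected(self):
        with pytest.raises(ValueError):
            hyperparameter_search(SearchSpace(), lambda cfg: 0.0, 0)


class TestBaselineConvLSTM:
    def test_layer_output_lengths(self, rng):
        m = build_baseline_convlstm((3, 1300), n_classes=2)
        m.fit_normalizer(rng.standard_normal((4, 3, 1300)))
        m.forward(rng.standard_normal((2, 3, 1300)))
        shapes = dict(m.layer_shapes)
        assert shapes["conv1+pool1"][2] == 1281   # (1300 - 20 + 1)
        assert shapes["conv2+pool2"][2] == 631    # (640 - 10 + 1)
        assert shapes["sequence"][1] == 315       # floor(631 / 2)
        assert shapes["sequence"][2] == 30        # 30 filters

    def test_forward_on_zeros_is_simplex(self):
        m = build_baseline_convlstm((3, 1300), n_classes=3)
        m.fit_normalizer(np.random.default_rng(0).standard_normal((4, 3, 1300)))
        probs = m.predict_proba(np.zeros((2, 3, 1300)))
        assert np.all(probs >= 0) and np.allclose(probs.sum(axis=1), 1.0)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            BaselineConvLSTM(input_length=10)

    def test_trainable_by_shared_loop(self):
        rng = np.random.default_rng(0)
        x = 0.1 * rng.standard_normal((12, 3, 200))
        y = np.repeat([0, 1], 6)
        x[y == 1, :, ::5] += 1.0
        m = BaselineConvLSTM(n_channels=3, input_length=200, n_classes=2,
                             hidden_units=8, fc_width=8, seed=0)
        hist = train_model(m, x, y, x, y,
                           TrainConfig(max_epochs=15, patience=15, seed=0))
        assert hist["train_acc"][-1] >= 0.75
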