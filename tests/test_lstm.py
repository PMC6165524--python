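"""Stacked LSTM: cell oracle, gradient check, training behaviour."""

import math

import numpy as np
import pytest

import harspec as h
from harspec.features import FeatureSet
from harspec.lstm import (GATE_BIAS_NAMES, GATE_WEIGHT_NAMES, LstmCellWeights,
                          LstmConfig, StackedLstmClassifier, init_cell_weights,
                          lstm_cell_step)


def sigmoid(x):
    return 1.0 / (1.0 + math.exp(-x))


def oracle_cell_step(x, h_prev, c_prev, w, peephole=True):
    """Element-wise pure-Python evaluation of the five gate equations."""
    H, D = w.W_xi.shape
    i = [0.0] * H
    f = [0.0] * H
    g = [0.0] * H
    c = [0.0] * H
    o = [0.0] * H
    h_out = [0.0] * H
    for r in range(H):
        a_i = w.b_i[r] + sum(w.W_xi[r, d] * x[d] for d in range(D))
        rec = c_prev if peephole else h_prev
        a_i += sum(w.W_hi[r, k] * rec[k] for k in range(H))
        i[r] = sigmoid(a_i)

        a_f = w.b_f[r] + sum(w.W_xf[r, d] * x[d] for d in range(D))
        a_f += sum(w.W_hf[r, k] * h_prev[k] for k in range(H))
        if peephole:
            a_f += sum(w.W_cf[r, k] * c_prev[k] for k in range(H))
        f[r] = sigmoid(a_f)

        a_c = w.b_c[r] + sum(w.W_xc[r, d] * x[d] for d in range(D))
        a_c += sum(w.W_hc[r, k] * h_prev[k] for k in range(H))
        g[r] = math.tanh(a_c)
        c[r] = f[r] * c_prev[r] + i[r] * g[r]
    for r in range(H):
        a_o = w.b_o[r] + sum(w.W_xo[r, d] * x[d] for d in range(D))
        a_o += sum(w.W_ho[r, k] * h_prev[k] for k in range(H))
        if peephole:
            a_o += sum(w.W_co[r, k] * c[k] for k in range(H))
        o[r] = sigmoid(a_o)
        h_out[r] = o[r] * math.tanh(c[r])
    return np.array(h_out), np.array(c)


def random_weights(input_dim, hidden, seed):
    rng = np.random.default_rng(seed)
    kwargs = {}
    for name in GATE_WEIGHT_NAMES:
        cols = input_dim if name.startswith("W_x") else hidden
        kwargs[name] = rng.normal(0, 0.5, size=(hidden, cols))
    for name in GATE_BIAS_NAMES:
        kwargs[name] = rng.normal(0, 0.5, size=hidden)
    return LstmCellWeights(**kwargs)


class TestCellStep:
    def test_zero_weights_give_zero_state(self):
        w = LstmCellWeights(**{n: np.zeros((2, 3)) for n in GATE_WEIGHT_NAMES
                               if n.startswith("W_x")},
                            **{n: np.zeros((2, 2)) for n in GATE_WEIGHT_NAMES
                               if not n.startswith("W_x")},
                            **{n: np.zeros(2) for n in GATE_BIAS_NAMES})
        h_t, c_t = lstm_cell_step(np.array([1.0, -2.0, 3.0]), np.zeros(2),
                                  np.zeros(2), w)
        # sigma(0)=0.5 gates, tanh(0)=0 candidate: c_t = 0, h_t = 0
        np.testing.assert_array_equal(c_t, np.zeros(2))
        np.testing.assert_array_equal(h_t, np.zeros(2))

    def test_scalar_cell_hand_walkthrough(self):
        """1-unit cell with hand-set weights, checked line by line."""
        w = LstmCellWeights(
            W_xi=np.array([[0.5]]), W_hi=np.array([[0.1]]),
            W_xf=np.array([[-0.3]]), W_hf=np.array([[0.2]]), W_cf=np.array([[0.4]]),
            W_xc=np.array([[1.0]]), W_hc=np.array([[-0.5]]),
            W_xo=np.array([[0.7]]), W_ho=np.array([[0.3]]), W_co=np.array([[-0.2]]),
            b_i=np.array([0.1]), b_f=np.array([-0.1]),
            b_c=np.array([0.2]), b_o=np.array([0.0]))
        x, h_prev, c_prev = 2.0, 0.3, -0.4
        i = sigmoid(0.5 * x + 0.1 * c_prev + 0.1)
        f = sigmoid(-0.3 * x + 0.2 * h_prev + 0.4 * c_prev - 0.1)
        g = math.tanh(1.0 * x - 0.5 * h_prev + 0.2)
        c = f * c_prev + i * g
        o = sigmoid(0.7 * x + 0.3 * h_prev - 0.2 * c)
        expected_h = o * math.tanh(c)
        h_t, c_t = lstm_cell_step(np.array([x]), np.array([h_prev]),
                                  np.array([c_prev]), w)
        assert c_t[0] == pytest.approx(c, abs=1e-12)
        assert h_t[0] == pytest.approx(expected_h, abs=1e-12)

    @pytest.mark.parametrize("peephole", [True, False])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_elementwise_oracle(self, peephole, seed):
        rng = np.random.default_rng(seed + 100)
        w = random_weights(4, 3, seed)
        x = rng.normal(size=4)
        h_prev = rng.normal(size=3)
        c_prev = rng.normal(size=3)
        h_t, c_t = lstm_cell_step(x, h_prev, c_prev, w, peephole=peephole)
        h_exp, c_exp = oracle_cell_step(x, h_prev, c_prev, w, peephole=peephole)
        np.testing.assert_allclose(h_t, h_exp, atol=1e-10)
        np.testing.assert_allclose(c_t, c_exp, atol=1e-10)

    def test_hidden_output_bounded(self):
        rng = np.random.default_rng(8)
        w = random_weights(5, 4, 9)
        for _ in range(20):
            h_t, _ = lstm_cell_step(rng.normal(size=5) * 10,
                                    rng.normal(size=4), rng.normal(size=4), w)
            assert np.all(np.abs(h_t) < 1.0)

    def test_shape_mismatch_rejected(self):
        w = random_weights(4, 3, 0)
        with pytest.raises(ValueError):
            lstm_cell_step(np.zeros(5), np.zeros(3), np.zeros(3), w)


class TestGradients:
    @pytest.mark.parametrize("peephole", [True, False])
    def test_backprop_matches_finite_differences(self, peephole):
        """Analytic BPTT gradients agree with central differences."""
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 5, size=(10, 8))
        labels = np.array(["A", "B", "C", "A", "B"] * 2)
        cfg = LstmConfig(hidden_units=4, stacked_layers=2, dense_units=3,
                         max_epochs=0, seed=3, log_transform=False,
                         peephole=peephole)
        m = StackedLstmClassifier(cfg)
        m.fit(X, labels)  # max_epochs=0: init only
        seq = m._to_sequences(m._transform(X))
        Y = np.array([{"A": 0, "B": 1, "C": 2}[l] for l in labels])
        _, grads = m._gradients(seq, Y)
        eps = 1e-5
        for k, (holder, name) in enumerate(m._params()):
            W = getattr(holder, name)
            flat = W.reshape(-1)
            for j in rng.choice(W.size, size=min(3, W.size), replace=False):
                orig = flat[j]
                flat[j] = orig + eps
                lp = m._loss(m._forward(seq), Y)
                flat[j] = orig - eps
                lm = m._loss(m._forward(seq), Y)
                flat[j] = orig
                numeric = (lp - lm) / (2 * eps)
                analytic = grads[k].reshape(-1)[j]
                assert numeric == pytest.approx(analytic, rel=1e-4, abs=1e-7), name


def separable_feature_set(n_per_class=20, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.uniform(0.0, 1.0, size=(n_per_class, 8))
    b = rng.uniform(5.0, 6.0, size=(n_per_class, 8))
    X = np.vstack([a, b])
    labels = np.array(["A"] * n_per_class + ["B"] * n_per_class)
    return FeatureSet(X=X, labels=labels)


class TestTraining:
    def test_linearly_separable_reaches_full_accuracy(self):
        fs = separable_feature_set()
        cfg = LstmConfig(hidden_units=6, stacked_layers=2, learning_rate=0.01,
                         max_epochs=150, seed=0)
        model, history = h.train(fs, cfg)
        assert history[-1]["accuracy"] == 1.0
        np.testing.assert_array_equal(h.predict(model, fs), fs.labels)

    def test_zero_epochs_returns_untrained_model(self):
        fs = separable_feature_set()
        cfg = LstmConfig(max_epochs=0, loss_target=float("inf"),
                         sequence_reshape=(2, 4))
        model, history = h.train(fs, cfg)
        assert history == []
        assert model.predict_proba(fs.X).shape == (len(fs), 2)

    def test_seeded_determinism(self):
        fs = separable_feature_set()
        cfg = LstmConfig(hidden_units=4, stacked_layers=2, max_epochs=30, seed=5)
        _, hist_a = h.train(fs, cfg)
        _, hist_b = h.train(fs, cfg)
        assert hist_a[-1]["loss"] == hist_b[-1]["loss"]

    def test_single_class_rejected(self):
        fs = FeatureSet(X=np.ones((4, 8)), labels=np.array(["A"] * 4))
        with pytest.raises(ValueError):
            h.train(fs, LstmConfig(max_epochs=1))

    def test_l2_regularization_monotonicity(self):
        """10x the L2 penalty never lowers the final training loss."""
        fs = separable_feature_set()
        losses = []
        for lam in (1e-4, 1e-3):
            cfg = LstmConfig(hidden_units=4, stacked_layers=2, max_epochs=60,
                             seed=2, l2_lambda=lam)
            _, hist = h.train(fs, cfg)
            losses.append(hist[-1]["loss"])
        assert losses[1] >= losses[0]

    def test_loss_trend_decreases(self):
        fs = separable_feature_set()
        cfg = LstmConfig(hidden_units=4, stacked_layers=2, max_epochs=80, seed=1)
        _, hist = h.train(fs, cfg)
        assert hist[-1]["loss"] < hist[0]["loss"]

    def test_softmax_rows_normalised_and_prediction_consistent(self):
        fs = separable_feature_set()
        cfg = LstmConfig(hidden_units=4, stacked_layers=2, max_epochs=40, seed=0)
        model, _ = h.train(fs, cfg)
        probs = model.predict_proba(fs.X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        dup = np.vstack([fs.X[0], fs.X[0]])
        pred = model.predict(dup)
        assert pred[0] == pred[1]

    def test_feature_width_mismatch_rejected(self):
        fs = separable_feature_set()
        model, _ = h.train(fs, LstmConfig(hidden_units=4, stacked_layers=1,
                                          max_epochs=5))
        with pytest.raises(ValueError):
            model.predict(np.ones((2, 12)))

    def test_learning_rate_bounds_validated(self):
        with pytest.raises(ValueError):
            LstmConfig(learning_rate=1.5)
        with pytest.raises(ValueError):
            LstmConfig(learning_rate=0.0)

    def test_save_load_round_trip(self, tmp_path):
        fs = separable_feature_set()
        cfg = LstmConfig(hidden_units=4, stacked_layers=2, max_epochs=30, seed=0)
        model, _ = h.train(fs, cfg)
        model.save(tmp_path / "model.json")
        loaded = StackedLstmClassifier.load(tmp_path / "model.json")
        np.testing.assert_allclose(loaded.predict_proba(fs.X),
                                   model.predict_proba(fs.X), atol=1e-12)
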