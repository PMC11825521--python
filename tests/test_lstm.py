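"""LSTM: gate arithmetic, backprop correctness, training behavior."""

import numpy as np
import pytest

from neosleep import lstm as L


def zero_params(units, d):
    p = {f"W_{g}": np.zeros((units, units + d)) for g in L.GATES}
    p.update({f"b_{g}": np.zeros(units) for g in L.GATES})
    return p


def gaussian_blobs(n_per_class, dim, separation, seed):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.standard_normal((n_per_class, dim)) + separation * k
         for k in range(2)]
    )
    y = np.repeat([1, 2], n_per_class)
    return X, y


class TestCellStep:
    def test_zero_parameters_closed_form(self):
        prev = L.CellState(h=np.zeros(3), C=np.zeros(3))
        st = L.lstm_cell_step(np.zeros(4), prev, zero_params(3, 4))
        assert np.all(st.f == 0.5) and np.all(st.i == 0.5) and np.all(st.o == 0.5)
        assert np.all(st.candidate == 0.0)
        assert np.all(st.C == 0.0) and np.all(st.h == 0.0)

    def test_saturated_forget_gate_is_memory_passthrough(self):
        p = zero_params(3, 4)
        p["b_f"] = np.full(3, 50.0)
        prev = L.CellState(h=np.zeros(3), C=np.array([1.0, -2.0, 0.5]))
        st = L.lstm_cell_step(np.zeros(4), prev, p)
        assert np.allclose(st.C, prev.C, atol=1e-6)

    def test_hand_stepped_two_unit_oracle(self):
        rng = np.random.default_rng(0)
        p = {f"W_{g}": rng.standard_normal((2, 5)) for g in L.GATES}
        p.update({f"b_{g}": rng.standard_normal(2) for g in L.GATES})
        h0 = rng.standard_normal(2)
        C0 = rng.standard_normal(2)
        x = rng.standard_normal(3)
        st = L.lstm_cell_step(x, L.CellState(h=h0, C=C0), p)

        # independent scalar evaluation of the gate equations
        import math

        z = list(h0) + list(x)
        def affine(W, b, u):
            return sum(W[u][j] * z[j] for j in range(5)) + b[u]
        for u in range(2):
            f = 1 / (1 + math.exp(-affine(p["W_f"], p["b_f"], u)))
            i = 1 / (1 + math.exp(-affine(p["W_i"], p["b_i"], u)))
            g = math.tanh(affine(p["W_C"], p["b_C"], u))
            o = 1 / (1 + math.exp(-affine(p["W_o"], p["b_o"], u)))
            C = f * C0[u] + i * g
            h = o * math.tanh(C)
            assert st.h[u] == pytest.approx(h, abs=1e-12)
            assert st.C[u] == pytest.approx(C, abs=1e-12)

    def test_gate_activations_open_interval(self):
        rng = np.random.default_rng(1)
        p = {f"W_{g}": rng.standard_normal((3, 7)) for g in L.GATES}
        p.update({f"b_{g}": rng.standard_normal(3) for g in L.GATES})
        st = L.lstm_cell_step(
            rng.standard_normal(4),
            L.CellState(h=rng.standard_normal(3), C=rng.standard_normal(3)),
            p,
        )
        for gate in (st.f, st.i, st.o):
            assert np.all((gate > 0) & (gate < 1))
        assert np.allclose(st.h, st.o * np.tanh(st.C))

    def test_shape_mismatch_rejected(self):
        prev = L.CellState(h=np.zeros(3), C=np.zeros(3))
        with pytest.raises(ValueError, match="inconsistent"):
            L.lstm_cell_step(np.zeros(9), prev, zero_params(3, 4))


class TestBuildModel:
    def test_parameter_count_closed_form(self):
        cfg = L.LSTMConfig(seed=0)
        model = L.build_model(cfg, input_dim=21)
        expected, d = 0, 21
        for j, u in enumerate(cfg.layer_units):
            expected += 4 * u * (u + d + 1)  # four gates: W (u x (u+d)) + b
            if j < len(cfg.layer_units) - 1:
                expected += 2 * u  # batch-norm gamma/beta
            d = u
        for u in cfg.dense_units:
            expected += u * (d + 1)
            d = u
        expected += cfg.n_classes * (d + 1)
        assert model.parameter_count == expected

    def test_reduced_mode_strictly_smaller(self):
        full = L.build_model(L.LSTMConfig(seed=0), input_dim=21)
        small = L.build_model(L.LSTMConfig.reduced(seed=0), input_dim=21)
        assert small.parameter_count < full.parameter_count

    def test_forward_softmax_normalized(self):
        model = L.build_model(L.LSTMConfig.reduced(seed=1), input_dim=7)
        X = np.random.default_rng(2).standard_normal((9, 7))
        probs, _ = L._forward(model, L._as_3d(X), training=False)
        assert probs.shape == (9, 5)
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)


class TestKernelEquivalence:
    def test_batched_layer_matches_sequential_stepping(self):
        rng = np.random.default_rng(3)
        model = L.build_model(
            L.LSTMConfig(layer_units=(6, 4, 3), dense_units=(4,), seed=4),
            input_dim=5,
        )
        X = rng.standard_normal((3, 6, 5))
        out, _ = L._lstm_forward(X, model.lstm_layers[0], return_sequences=True)
        for b in range(3):
            prev = L.CellState(h=np.zeros(6), C=np.zeros(6))
            for t in range(6):
                prev = L.lstm_cell_step(X[b, t], prev, model.lstm_layers[0])
                assert np.allclose(prev.h, out[b, t], atol=1e-5)

    def test_bptt_gradients_match_finite_differences(self):
        rng = np.random.default_rng(5)
        cfg = L.LSTMConfig(
            layer_units=(4, 3, 3), dense_units=(3,), n_classes=3,
            seed=6, l2_factor=1e-3,
        )
        model = L.build_model(cfg, input_dim=2)
        X = rng.standard_normal((5, 3, 2))
        Y = np.eye(3)[rng.integers(0, 3, 5)]

        def loss():
            p, _ = L._forward(model, X, training=True)
            ce = -np.mean(np.sum(Y * np.log(p), axis=1))
            return ce + L._l2_penalty(model)

        probs, caches = L._forward(model, X, training=True)
        grads = L._backward(model, probs, caches, Y)
        for (container, key), g in zip(model._trainable(), grads):
            arr = container[key]
            idx = tuple(np.unravel_index(arr.size // 2, arr.shape))
            eps, old = 1e-6, arr[idx]
            arr[idx] = old + eps
            lp = loss()
            arr[idx] = old - eps
            lm = loss()
            arr[idx] = old
            num = (lp - lm) / (2 * eps)
            assert g[idx] == pytest.approx(num, abs=1e-6, rel=1e-4)


class TestTraining:
    def test_separable_blobs_high_training_accuracy(self):
        X, y = gaussian_blobs(100, 4, separation=4.0, seed=7)
        cfg = L.LSTMConfig.reduced(seed=8, n_classes=2, max_epochs=40)
        model = L.build_model(cfg, input_dim=4)
        history = L.train(model, X, y, cfg)
        assert history["accuracy"][-1] >= 0.95

    def test_early_stopping_contract(self):
        # nearly inseparable data, patience 1: must stop well before max
        rng = np.random.default_rng(9)
        X = rng.standard_normal((60, 3))
        y = rng.integers(1, 3, 60)
        cfg = L.LSTMConfig.reduced(seed=10, n_classes=2, patience=1, max_epochs=50)
        model = L.build_model(cfg, input_dim=3)
        history = L.train(model, X, y, cfg)
        assert history["stopped_epoch"] < 50

    def test_history_lengths_match_epochs_run(self):
        X, y = gaussian_blobs(40, 3, separation=2.0, seed=11)
        cfg = L.LSTMConfig.reduced(seed=12, n_classes=2, max_epochs=7, patience=7)
        model = L.build_model(cfg, input_dim=3)
        history = L.train(model, X, y, cfg)
        n = history["stopped_epoch"]
        for key in ("loss", "accuracy", "val_loss", "val_accuracy"):
            assert len(history[key]) == n

    def test_single_class_rejected(self):
        cfg = L.LSTMConfig.reduced(seed=13)
        model = L.build_model(cfg, input_dim=3)
        with pytest.raises(ValueError, match="2 classes"):
            L.train(model, np.zeros((10, 3)), np.ones(10), cfg)

    def test_seeded_training_bit_identical(self):
        X, y = gaussian_blobs(30, 3, separation=1.0, seed=14)
        cfg = L.LSTMConfig.reduced(seed=15, n_classes=2, max_epochs=5)
        h1 = L.train(L.build_model(cfg, input_dim=3), X, y, cfg)
        h2 = L.train(L.build_model(cfg, input_dim=3), X, y, cfg)
        assert h1["loss"] == h2["loss"]
        assert h1["val_loss"] == h2["val_loss"]

    def test_l2_term_increases_loss(self):
        cfg = L.LSTMConfig.reduced(seed=16)
        model = L.build_model(cfg, input_dim=4)
        assert L._l2_penalty(model) > 0.0


class TestPredict:
    def test_probability_rows_sum_to_one(self):
        X, y = gaussian_blobs(30, 3, separation=3.0, seed=17)
        cfg = L.LSTMConfig.reduced(seed=18, n_classes=2, max_epochs=5)
        model = L.build_model(cfg, input_dim=3)
        L.train(model, X, y, cfg)
        probs, labels = L.predict(model, X)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert set(labels) <= {1, 2}

    def test_duplicated_row_duplicated_prediction(self):
        cfg = L.LSTMConfig.reduced(seed=19)
        model = L.build_model(cfg, input_dim=4)
        x = np.random.default_rng(20).standard_normal(4)
        probs, _ = L.predict(model, np.vstack([x, x]))
        assert np.array_equal(probs[0], probs[1])

    def test_heldout_accuracy_above_chance(self):
        X, y = gaussian_blobs(150, 4, separation=3.0, seed=21)
        rng = np.random.default_rng(22)
        order = rng.permutation(300)
        tr, te = order[:240], order[240:]
        cfg = L.LSTMConfig.reduced(seed=23, n_classes=2, max_epochs=30)
        model = L.build_model(cfg, input_dim=4)
        L.train(model, X[tr], y[tr], cfg)
        _, pred = L.predict(model, X[te])
        assert np.mean(pred == y[te]) > 0.5

    def test_dimension_mismatch_rejected(self):
        model = L.build_model(L.LSTMConfig.reduced(seed=24), input_dim=4)
        with pytest.raises(ValueError, match="dimension"):
            L.predict(model, np.zeros((3, 6)))


def test_checkpoint_roundtrip(tmp_path):
    cfg = L.LSTMConfig.reduced(seed=25, n_classes=2, max_epochs=3)
    X, y = gaussian_blobs(20, 3, separation=2.0, seed=26)
    model = L.build_model(cfg, input_dim=3)
    L.train(model, X, y, cfg)
    model.save(tmp_path / "ckpt")
    back = L.LSTMModel.load(tmp_path / "ckpt")
    p1, _ = L.predict(model, X)
    p2, _ = L.predict(back, X)
    assert np.allclose(p1, p2, atol=1e-12)
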