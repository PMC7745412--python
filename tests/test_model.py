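"""Network architecture, LSTM recurrence, masking and gradients."""

import math

import numpy as np
import pytest

from kebind.errors import ConfigError, DatasetError
from kebind.model import (
    LSTMState,
    LSTMWeights,
    ModelConfig,
    build_model,
    load_model,
    lstm_step,
    pad_and_mask,
    save_model,
    unpad,
)
from kebind.nn import LSTMDirection, MaxPool1d


class TestLstmStep:
    def test_zero_weights_give_half_gates_and_zero_state(self):
        w = LSTMWeights.zeros(input_dim=3, units=2)
        state, gates = lstm_step(np.array([1.0, -2.0, 0.5]), LSTMState.zeros(2), w)
        np.testing.assert_allclose(gates["f"], 0.5)
        np.testing.assert_allclose(gates["i"], 0.5)
        np.testing.assert_allclose(gates["o"], 0.5)
        np.testing.assert_allclose(state.c, 0.0)
        np.testing.assert_allclose(state.h, 0.0)

    def test_scalar_step_matches_hand_computation(self):
        # 1-unit LSTM with hand-chosen scalar weights, checked against a
        # direct evaluation of the recurrence formulas
        w = LSTMWeights(
            W_f=np.array([[0.5]]), W_i=np.array([[-0.3]]),
            W_c=np.array([[0.8]]), W_o=np.array([[0.2]]),
            U_f=np.array([[0.1]]), U_i=np.array([[0.4]]),
            U_c=np.array([[-0.6]]), U_o=np.array([[0.7]]),
            b_f=np.array([0.05]), b_i=np.array([-0.1]),
            b_c=np.array([0.2]), b_o=np.array([0.0]),
        )
        x, h0, c0 = 1.3, 0.25, -0.4
        state, _ = lstm_step(np.array([x]), LSTMState(h=np.array([h0]), c=np.array([c0])), w)

        sig = lambda z: 1.0 / (1.0 + math.exp(-z))
        f = sig(0.5 * x + 0.1 * h0 + 0.05)
        i = sig(-0.3 * x + 0.4 * h0 - 0.1)
        g = math.tanh(0.8 * x - 0.6 * h0 + 0.2)
        o = sig(0.2 * x + 0.7 * h0 + 0.0)
        c = f * c0 + i * g
        h = o * math.tanh(c)
        assert abs(state.c[0] - c) < 1e-10
        assert abs(state.h[0] - h) < 1e-10

    def test_saturating_input_drives_gates_to_one(self):
        w = LSTMWeights.zeros(input_dim=1, units=1)
        for name in ("W_f", "W_i", "W_o"):
            setattr(w, name, np.array([[50.0]]))
        _, gates = lstm_step(np.array([10.0]), LSTMState.zeros(1), w)
        for g in ("f", "i", "o"):
            assert gates[g][0] > 1.0 - 1e-6

    def test_unrolled_steps_match_production_layer(self):
        # the didactic per-gate step and the packed-matrix layer implement
        # the same recurrence
        rng = np.random.default_rng(0)
        C, H, T = 3, 4, 6
        layer = LSTMDirection(C, H, rng, dtype=np.float64)
        X = rng.normal(size=(1, T, C))
        h_layer = layer.forward(X, np.array([T]))

        # unpack the (C, 4H) gate-ordered matrices into per-gate weights
        W, U, b = layer.W, layer.U, layer.b
        blocks = {name: slice(k * H, (k + 1) * H)
                  for k, name in enumerate(("i", "f", "c", "o"))}
        w = LSTMWeights(
            W_f=W[:, blocks["f"]].T, W_i=W[:, blocks["i"]].T,
            W_c=W[:, blocks["c"]].T, W_o=W[:, blocks["o"]].T,
            U_f=U[:, blocks["f"]].T, U_i=U[:, blocks["i"]].T,
            U_c=U[:, blocks["c"]].T, U_o=U[:, blocks["o"]].T,
            b_f=b[blocks["f"]], b_i=b[blocks["i"]],
            b_c=b[blocks["c"]], b_o=b[blocks["o"]],
        )
        state = LSTMState.zeros(H)
        for t in range(T):
            state, _ = lstm_step(X[0, t], state, w)
        np.testing.assert_allclose(state.h, h_layer[0], atol=1e-5)


class TestBuildModel:
    def test_bilstm_output_feature_size_is_twice_units(self):
        net = build_model(ModelConfig(lstm_units=32))
        assert net.feature_size == 64

    def test_cnn_only_has_no_recurrent_parameters(self):
        net = build_model(ModelConfig(variant="cnn_only"))
        assert not any("lstm" in name for name in net.parameters())

    def test_no_structure_variant_has_no_structure_branch(self):
        net = build_model(ModelConfig(variant="no_structure"))
        assert not any("struct" in name for name in net.parameters())

    def test_seeded_initialisation_is_deterministic(self):
        p1 = build_model(ModelConfig(seed=5)).parameters()
        p2 = build_model(ModelConfig(seed=5)).parameters()
        p3 = build_model(ModelConfig(seed=6)).parameters()
        for name in p1:
            np.testing.assert_array_equal(p1[name], p2[name])
        assert any(not np.array_equal(p1[n], p3[n]) for n in p1)

    def test_one_hot_requires_four_input_channels(self):
        with pytest.raises(ConfigError):
            ModelConfig(variant="one_hot", input_dim_seq=30)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ConfigError):
            ModelConfig(variant="transformer")


class TestPadAndMask:
    def test_pads_to_batch_maximum(self):
        mats = [np.ones((10, 3)), np.ones((7, 3)), np.ones((7, 3))]
        batch, lengths = pad_and_mask(mats)
        assert batch.shape == (3, 10, 3)
        assert lengths.tolist() == [10, 7, 7]
        assert np.all(batch[1, 7:] == 0)

    def test_single_example_noop(self):
        mats = [np.arange(12.0).reshape(4, 3)]
        batch, lengths = pad_and_mask(mats)
        np.testing.assert_array_equal(batch[0], mats[0])

    def test_empty_batch_rejected(self):
        with pytest.raises(DatasetError):
            pad_and_mask([])

    def test_unpad_round_trip(self):
        rng = np.random.default_rng(2)
        mats = [rng.normal(size=(int(rng.integers(4, 20)), 5)) for _ in range(6)]
        batch, lengths = pad_and_mask(mats)
        back = unpad(batch, lengths)
        for a, b in zip(mats, back):
            np.testing.assert_array_equal(a, b)


def _random_batch(rng, cfg, lengths):
    Xs = [rng.normal(size=(n, cfg.input_dim_seq)) for n in lengths]
    Xt = [rng.normal(size=(n, cfg.input_dim_struct)) for n in lengths]
    bs, ls = pad_and_mask(Xs)
    bt, _ = pad_and_mask(Xt)
    return bs, bt, ls


class TestForward:
    def test_outputs_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(0)
        cfg = ModelConfig(filters=8, lstm_units=4, fc_units=8, seed=0,
                          input_dim_seq=6, input_dim_struct=6)
        net = build_model(cfg)
        Xs, Xt, lengths = _random_batch(rng, cfg, [30, 22, 17])
        p = net.forward(Xs.astype(np.float32), lengths, X_struct=Xt.astype(np.float32))
        assert np.all(p > 0) and np.all(p < 1)

    def test_duplicated_example_identical_probability(self):
        rng = np.random.default_rng(1)
        cfg = ModelConfig(filters=8, lstm_units=4, fc_units=8, seed=1,
                          input_dim_seq=6, input_dim_struct=6)
        net = build_model(cfg)
        x = rng.normal(size=(25, 6)).astype(np.float32)
        t = rng.normal(size=(25, 6)).astype(np.float32)
        Xs, lengths = pad_and_mask([x, x])
        Xt, _ = pad_and_mask([t, t])
        p = net.forward(Xs, lengths, X_struct=Xt)
        assert p[0] == p[1]

    def test_padding_invariance(self):
        # the same example padded to different batch maxima scores identically
        rng = np.random.default_rng(2)
        cfg = ModelConfig(filters=8, lstm_units=4, fc_units=8, seed=2,
                          input_dim_seq=6, input_dim_struct=6)
        net = build_model(cfg)
        x = rng.normal(size=(20, 6)).astype(np.float32)
        t = rng.normal(size=(20, 6)).astype(np.float32)
        probs = []
        for pad_to in (20, 47, 80):
            Xs = np.zeros((1, pad_to, 6), dtype=np.float32)
            Xt = np.zeros((1, pad_to, 6), dtype=np.float32)
            Xs[0, :20], Xt[0, :20] = x, t
            probs.append(net.forward(Xs, np.array([20]), X_struct=Xt)[0])
        assert abs(probs[0] - probs[1]) < 1e-5
        assert abs(probs[0] - probs[2]) < 1e-5

    def test_too_short_example_rejected(self):
        cfg = ModelConfig(filters=4, lstm_units=2, fc_units=4, seed=0,
                          input_dim_seq=3, input_dim_struct=3)
        net = build_model(cfg)
        Xs = np.zeros((1, 3, 3), dtype=np.float32)
        with pytest.raises(DatasetError):
            net.forward(Xs, np.array([3]), X_struct=Xs)


def test_maxpool_output_length_is_floor_of_input_over_width():
    rng = np.random.default_rng(0)
    pool = MaxPool1d(width=2)
    for T in (7, 8, 9, 20):
        X = rng.normal(size=(2, T, 3)).astype(np.float32)
        Y, new_lengths = pool.forward(X, np.array([T, T - 1]))
        assert Y.shape[1] == T // 2
        assert new_lengths.tolist() == [T // 2, (T - 1) // 2]


def test_bce_gradient_matches_central_differences():
    rng = np.random.default_rng(3)
    cfg = ModelConfig(filters=6, lstm_units=3, fc_units=6, dropout=0.0,
                      conv_dropout=0.0, seed=3, input_dim_seq=4,
                      input_dim_struct=4)
    net = build_model(cfg, dtype=np.float64)
    Xs, Xt, lengths = _random_batch(rng, cfg, [18, 13])
    y = np.array([1.0, 0.0])

    def loss():
        p = np.clip(net.forward(Xs, lengths, X_struct=Xt), 1e-12, 1 - 1e-12)
        return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

    p = net.forward(Xs, lengths, X_struct=Xt)
    grads, _, _ = net.backward((p - y) / len(y))
    params = net.parameters()
    check_rng = np.random.default_rng(0)
    for name, arr in params.items():
        flat = arr.ravel()
        for _ in range(2):
            i = int(check_rng.integers(flat.size))
            eps = 1e-6
            old = flat[i]
            flat[i] = old + eps
            lp = loss()
            flat[i] = old - eps
            lm = loss()
            flat[i] = old
            num = (lp - lm) / (2 * eps)
            ana = grads[name].ravel()[i]
            denom = max(abs(num) + abs(ana), 1e-8)
            assert abs(num - ana) / denom < 1e-3, (name, num, ana)


def test_checkpoint_round_trip(tmp_path):
    rng = np.random.default_rng(4)
    cfg = ModelConfig(filters=6, lstm_units=3, fc_units=6, seed=4,
                      input_dim_seq=5, input_dim_struct=5)
    net = build_model(cfg)
    Xs, Xt, lengths = _random_batch(rng, cfg, [16, 12])
    p_before = net.forward(Xs.astype(np.float32), lengths, X_struct=Xt.astype(np.float32))
    path = tmp_path / "model.npz"
    save_model(net, path)
    back = load_model(path)
    assert back.config == cfg
    p_after = back.forward(Xs.astype(np.float32), lengths, X_struct=Xt.astype(np.float32))
    np.testing.assert_array_equal(p_before, p_after)
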