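"""Cell-level equations, attention, and the assembled predictors."""

import numpy as np
import pytest

from respigate import autodiff as ad
from respigate.autodiff import Tensor
from respigate.errors import ShapeError
from respigate.models import (
    BiLSTMModel,
    LSTMModel,
    PredictorSpec,
    TransformerModel,
    bilstm_combine,
    build_model,
    look_ahead_mask,
    lstm_cell_step,
    recurrent_forward,
    scaled_dot_attention,
    transformer_forward,
)


def _cell_params(rng, H, I):
    p = {}
    for w in ("W_f", "W_i", "W_c", "W_o"):
        p[w] = rng.normal(size=(H, H + I))
    for b in ("b_f", "b_i", "b_c", "b_o"):
        p[b] = rng.normal(size=H)
    return p


def _zero_cell_params(H, I):
    return {
        **{w: np.zeros((H, H + I)) for w in ("W_f", "W_i", "W_c", "W_o")},
        **{b: np.zeros(H) for b in ("b_f", "b_i", "b_c", "b_o")},
    }


def _scalar_cell_oracle(x, h, c, p):
    """Element-by-element evaluation of the gate equations (scalars only)."""
    H = h.size
    hx = np.concatenate([h, x])
    sig = lambda z: 1.0 / (1.0 + np.exp(-z))
    h_new = np.empty(H)
    c_new = np.empty(H)
    for j in range(H):
        f = sig(sum(p["W_f"][j, k] * hx[k] for k in range(hx.size)) + p["b_f"][j])
        i = sig(sum(p["W_i"][j, k] * hx[k] for k in range(hx.size)) + p["b_i"][j])
        g = np.tanh(sum(p["W_c"][j, k] * hx[k] for k in range(hx.size)) + p["b_c"][j])
        o = sig(sum(p["W_o"][j, k] * hx[k] for k in range(hx.size)) + p["b_o"][j])
        c_new[j] = f * c[j] + i * g
        h_new[j] = o * np.tanh(c_new[j])
    return h_new, c_new


class TestLstmCellStep:
    def test_zero_parameters_closed_form(self):
        p = _zero_cell_params(3, 2)
        h, c = lstm_cell_step(np.ones(2), np.zeros(3), np.zeros(3), p)
        np.testing.assert_allclose(c, 0.0, atol=1e-15)  # C = 0.5*0 + 0.5*0
        np.testing.assert_allclose(h, 0.0, atol=1e-15)

    def test_zero_parameters_with_prior_cell_state(self):
        p = _zero_cell_params(2, 1)
        c_prev = np.array([0.8, -0.4])
        h, c = lstm_cell_step(np.zeros(1), np.zeros(2), c_prev, p)
        np.testing.assert_allclose(c, 0.5 * c_prev, atol=1e-15)
        np.testing.assert_allclose(h, 0.5 * np.tanh(0.5 * c_prev), atol=1e-15)

    def test_matches_scalar_oracle(self, rng):
        p = _cell_params(rng, 2, 3)
        x, h0, c0 = rng.normal(size=3), rng.normal(size=2), rng.normal(size=2)
        h, c = lstm_cell_step(x, h0, c0, p)
        h_ref, c_ref = _scalar_cell_oracle(x, h0, c0, p)
        np.testing.assert_allclose(h, h_ref, atol=1e-10)
        np.testing.assert_allclose(c, c_ref, atol=1e-10)

    def test_tied_flag_uses_candidate_parameters_for_input_gate(self, rng):
        p = _cell_params(rng, 2, 2)
        x, h0, c0 = rng.normal(size=2), rng.normal(size=2), rng.normal(size=2)
        tied = lstm_cell_step(x, h0, c0, p, tied_input_candidate=True)
        p_equiv = dict(p, W_i=p["W_c"], b_i=p["b_c"])
        untied = lstm_cell_step(x, h0, c0, p_equiv)
        np.testing.assert_allclose(tied[0], untied[0], atol=1e-14)

    def test_dimension_mismatch_rejected(self, rng):
        p = _cell_params(rng, 2, 3)
        with pytest.raises(ShapeError):
            lstm_cell_step(np.zeros(5), np.zeros(2), np.zeros(2), p)


class TestBilstmCombine:
    def test_zero_backward_weights_reduce_to_forward_affine(self, rng):
        hf, hb = rng.normal(size=4), rng.normal(size=4)
        wf = rng.normal(size=(4, 2))
        p = {"W_fwd": wf, "W_bwd": np.zeros((4, 2)), "b": rng.normal(size=2)}
        np.testing.assert_allclose(
            bilstm_combine(hf, hb, p), hf @ wf + p["b"], atol=1e-14
        )

    def test_identity_backward_returns_backward_state(self, rng):
        hf, hb = rng.normal(size=3), rng.normal(size=3)
        p = {"W_fwd": np.zeros((3, 3)), "W_bwd": np.eye(3), "b": np.zeros(3)}
        np.testing.assert_allclose(bilstm_combine(hf, hb, p), hb, atol=1e-14)

    def test_palindrome_with_tied_directions_gives_mirrored_outputs(self, rng):
        # per-position combination y_t = W h_fwd(t) + W h_bwd(t) + b with
        # tied directional weights: a palindromic input makes the output
        # sequence itself palindromic
        T, H = 7, 3
        half = rng.normal(size=(1, (T + 1) // 2, 1))
        x = np.concatenate([half, half[:, :-1][:, ::-1]], axis=1)
        wx = Tensor(rng.normal(size=(1, 4 * H)))
        wh = Tensor(rng.normal(size=(H, 4 * H)) * 0.5)
        b = Tensor(rng.normal(size=4 * H))
        h_fwd = ad.lstm_layer(Tensor(x), wx, wh, b).data[0]
        h_bwd_run = ad.lstm_layer(Tensor(x[:, ::-1]), wx, wh, b).data[0]
        h_bwd = h_bwd_run[::-1]  # backward hidden aligned to original time
        w = rng.normal(size=(H, 2))
        p = {"W_fwd": w, "W_bwd": w, "b": rng.normal(size=2)}
        y = np.stack([bilstm_combine(h_fwd[t], h_bwd[t], p) for t in range(T)])
        np.testing.assert_allclose(y, y[::-1], atol=1e-12)


class TestScaledDotAttention:
    def test_single_key_value_returns_value(self, rng):
        q = rng.normal(size=(3, 4))
        k = rng.normal(size=(1, 4))
        v = rng.normal(size=(1, 5))
        out = scaled_dot_attention(q, k, v)
        np.testing.assert_allclose(out, np.repeat(v, 3, axis=0), atol=1e-12)

    def test_softmax_saturation_selects_matching_value(self, rng):
        k = np.eye(4)  # orthogonal keys
        v = rng.normal(size=(4, 3))
        q = 50.0 * k[[1]]
        out = scaled_dot_attention(q, k, v)
        np.testing.assert_allclose(out[0], v[1], atol=1e-8)

    def test_matches_brute_force_softmax_matmul(self, rng):
        q, k, v = (rng.normal(size=(3, 4)) for _ in range(3))
        scores = q @ k.T / np.sqrt(4)
        e = np.exp(scores - scores.max(axis=-1, keepdims=True))
        ref = (e / e.sum(axis=-1, keepdims=True)) @ v
        np.testing.assert_allclose(scaled_dot_attention(q, k, v), ref, atol=1e-10)

    @pytest.mark.parametrize("masked", [False, True])
    def test_weight_rows_sum_to_one(self, rng, masked):
        q, k, v = (rng.normal(size=(2, 6, 4)) for _ in range(3))
        mask = look_ahead_mask(6) if masked else None
        _, w = scaled_dot_attention(q, k, v, mask=mask, return_weights=True)
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-6)
        if masked:
            assert np.all(w[:, 0, 1:] < 1e-12)  # first query sees only itself

    def test_shape_validation(self, rng):
        with pytest.raises(ShapeError):
            scaled_dot_attention(rng.normal(size=(2, 3)), rng.normal(size=(2, 4)),
                                 rng.normal(size=(2, 4)))


class TestTransformerModel:
    spec = PredictorSpec(kind="transformer", n_encoder_layers=2,
                         n_decoder_layers=2, model_dim=16, feedforward_dim=32,
                         n_heads=4, seed=3, dtype="float64")

    def test_causal_mask_blocks_future_decoder_positions(self, rng):
        model = TransformerModel(self.spec)
        x = rng.normal(size=(1, 12))
        base = model.decoder_self_outputs(x)
        x2 = x.copy()
        x2[0, 5] += 1.0  # decoder input position 6
        pert = model.decoder_self_outputs(x2)
        np.testing.assert_allclose(base[0, :6], pert[0, :6], atol=1e-12)
        assert not np.allclose(base[0, 6:], pert[0, 6:])

    def test_inference_is_deterministic(self, rng):
        x = rng.normal(size=(4, 12))
        a = transformer_forward(x[0], self.spec)
        b = transformer_forward(x[0], self.spec)
        assert a == b

    def test_untrained_output_is_finite_and_bounded(self, rng):
        model = TransformerModel(self.spec)
        x = rng.normal(size=(32, 12))
        y = model.predict(x)
        assert np.all(np.isfinite(y))
        assert np.all(np.abs(y) < 10.0)

    def test_end_to_end_gradients(self, rng):
        model = TransformerModel(self.spec)
        x = rng.normal(size=(3, 8))
        y = rng.normal(size=3)

        def loss():
            for t in model.parameters():
                t.grad = None
            pred = model.forward(x)
            d = pred - y
            return (d * d).mean()

        names = ["enc0.a0.wq", "dec1.a1.wv", "dec0.ff.w1", "embed.w", "out.w"]
        loss().backward()
        grads = {n: model.params[n].grad.copy() for n in names}
        for name in names:
            t = model.params[name]
            g = grads[name]
            idx = (0,) * t.data.ndim
            eps = 1e-6
            t.data[idx] += eps
            fp = float(loss().data)
            t.data[idx] -= 2 * eps
            fm = float(loss().data)
            t.data[idx] += eps
            np.testing.assert_allclose(g[idx], (fp - fm) / (2 * eps),
                                       rtol=1e-4, atol=1e-7)


class TestRecurrentModels:
    def test_zero_parameters_predict_output_bias(self, rng):
        model = LSTMModel(PredictorSpec(kind="lstm", hidden_layers=2,
                                        hidden_size=4, seed=0, dtype="float64"))
        for t in model.parameters():
            t.data[...] = 0.0
        model.params["out.b"].data[...] = 0.7
        y = model.predict(rng.normal(size=(5, 10)))
        np.testing.assert_allclose(y, 0.7, atol=1e-12)

    def test_single_unit_stack_matches_cell_step_recurrence(self, rng):
        spec = PredictorSpec(kind="lstm", hidden_layers=1, hidden_size=1,
                             seed=7, dtype="float64")
        model = LSTMModel(spec)
        x = rng.normal(size=(1, 9))
        # fused layout [i, f, g, o] -> cell-step params over [h, x]
        wx = model.params["l0.wx"].data
        wh = model.params["l0.wh"].data
        b = model.params["l0.b"].data
        p = {
            "W_i": np.array([[wh[0, 0], wx[0, 0]]]),
            "W_f": np.array([[wh[0, 1], wx[0, 1]]]),
            "W_c": np.array([[wh[0, 2], wx[0, 2]]]),
            "W_o": np.array([[wh[0, 3], wx[0, 3]]]),
            "b_i": b[0:1], "b_f": b[1:2], "b_c": b[2:3], "b_o": b[3:4],
        }
        h = np.zeros(1)
        c = np.zeros(1)
        for t in range(9):
            h, c = lstm_cell_step(x[0, t:t + 1], h, c, p)
        expected = float(
            (h @ model.params["out.w"].data + model.params["out.b"].data)[0]
        )
        assert recurrent_forward(x[0], spec) == pytest.approx(expected, abs=1e-10)

    def test_bilstm_with_zeroed_backward_path_equals_lstm(self, rng):
        spec = PredictorSpec(kind="bilstm", hidden_layers=2, hidden_size=4,
                             seed=5, dtype="float64")
        bi = BiLSTMModel(spec)
        uni = LSTMModel(PredictorSpec(kind="lstm", hidden_layers=2, hidden_size=4,
                                      seed=5, dtype="float64"))
        # copy the forward stack and readout; silence the backward path
        for layer in range(2):
            for part in ("wx", "wh", "b"):
                bi.params[f"f{layer}.{part}"].data = uni.params[
                    f"l{layer}.{part}"].data.copy()
        bi.params["out.wf"].data = uni.params["out.w"].data.copy()
        bi.params["out.b"].data = uni.params["out.b"].data.copy()
        bi.params["out.wb"].data[...] = 0.0
        x = rng.normal(size=(6, 11))
        np.testing.assert_allclose(bi.predict(x), uni.predict(x), atol=1e-12)

    def test_seeded_construction_reproducible(self, rng):
        spec = PredictorSpec(kind="bilstm", hidden_layers=1, hidden_size=3, seed=9)
        x = rng.normal(size=(3, 8))
        np.testing.assert_array_equal(
            build_model(spec).predict(x), build_model(spec).predict(x)
        )
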