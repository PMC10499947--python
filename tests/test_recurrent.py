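"""BiLSTM, attention scoring/pooling, and the logistic classifier."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afnet.nn import (
    LSTM,
    Attention,
    AttentionParams,
    BiLSTM,
    RecurrentConfig,
    attention_pool,
    attention_score,
    classify,
)


class TestRecurrentConfig:
    def test_per_direction_is_half(self):
        assert RecurrentConfig(feature_len=128).per_direction == 64

    @pytest.mark.parametrize("n", [0, 1, 7])
    def test_rejects_odd_or_tiny(self, n):
        with pytest.raises(ValueError):
            RecurrentConfig(feature_len=n)

    def test_rejects_unknown_mode(self):
        with pytest.raises(ValueError):
            RecurrentConfig(scoring_mode="bilinear")


class TestBiLSTM:
    def test_default_step_vectors_have_length_128(self, rng):
        bi = BiLSTM(16, RecurrentConfig(), rng=rng)
        x = rng.standard_normal((2, 5, 16)).astype(np.float32)
        assert bi(x).shape == (2, 5, 128)

    def test_fused_path_matches_independent_directions(self, rng):
        bi = BiLSTM(6, RecurrentConfig(feature_len=8), rng=rng, dtype=np.float64)
        x = rng.standard_normal((3, 9, 6))
        fused = bi(x)
        hf = bi.fwd(x)
        hb = bi.bwd(x[:, ::-1])[:, ::-1]
        np.testing.assert_allclose(fused, np.concatenate([hf, hb], axis=2), atol=1e-12)

    def test_time_reversal_swaps_direction_halves(self, rng):
        """With tied weights, bilstm(reverse(x)) == reverse(bilstm(x)) with halves swapped."""
        cfg = RecurrentConfig(feature_len=8)
        bi = BiLSTM(5, cfg, rng=rng, dtype=np.float64)
        for key in bi.fwd.params:
            bi.bwd.params[key] = bi.fwd.params[key].copy()
        x = rng.standard_normal((2, 7, 5))
        h = cfg.per_direction
        y = bi(x)
        y_rev = bi(x[:, ::-1])
        swapped = np.concatenate([y[:, :, h:], y[:, :, :h]], axis=2)[:, ::-1]
        np.testing.assert_allclose(y_rev, swapped, atol=1e-12)

    def test_length_one_sequence(self, rng):
        bi = BiLSTM(4, RecurrentConfig(feature_len=6), rng=rng)
        y = bi(rng.standard_normal((1, 1, 4)).astype(np.float32))
        assert y.shape == (1, 1, 6)

    def test_empty_sequence_rejected(self, rng):
        bi = BiLSTM(4, RecurrentConfig(feature_len=6), rng=rng)
        with pytest.raises(ValueError):
            bi(np.zeros((1, 0, 4), dtype=np.float32))

    def test_lstm_gradients(self, rng):
        lstm = LSTM(3, 4, rng=rng, dtype=np.float64)
        x = rng.standard_normal((2, 6, 3))
        dy = rng.standard_normal((2, 6, 4))
        lstm.zero_grad()
        lstm(x)
        dx = lstm.backward(dy)
        eps = 1e-6
        def loss():
            return float(np.sum(lstm(x) * dy))
        for _, leaf, key in lstm.named_parameters():
            flat = leaf.params[key].ravel()
            for i in rng.choice(flat.size, size=4, replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp = loss()
                flat[i] = old - eps
                lm = loss()
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                assert abs(num - leaf.grads[key].ravel()[i]) < 1e-7 * max(1.0, abs(num))
        xf = x.ravel()
        for i in rng.choice(xf.size, size=4, replace=False):
            old = xf[i]
            xf[i] = old + eps
            lp = loss()
            xf[i] = old - eps
            lm = loss()
            xf[i] = old
            num = (lp - lm) / (2 * eps)
            assert abs(num - dx.ravel()[i]) < 1e-7 * max(1.0, abs(num))


def _params(mode, d=2, p=2):
    if mode == "multiplicative":
        return AttentionParams(W_alpha=np.eye(d), query=np.zeros(d))
    if mode == "cascade":
        return AttentionParams(W_alpha=np.ones(2 * d), query=np.zeros(d))
    return AttentionParams(W_alpha=np.eye(p), U_alpha=np.eye(p),
                           v_alpha=np.ones(p), query=np.zeros(d))


class TestAttentionScore:
    def test_multiplicative_identity_is_dot_product(self, rng):
        q = rng.standard_normal(5)
        k = rng.standard_normal(5)
        params = AttentionParams(W_alpha=np.eye(5), query=q)
        assert attention_score(q, k, params, "multiplicative") == pytest.approx(q @ k)

    def test_perceptron_zero_v_annihilates(self, rng):
        params = AttentionParams(W_alpha=rng.standard_normal((3, 3)),
                                 U_alpha=rng.standard_normal((3, 3)),
                                 v_alpha=np.zeros(3), query=np.zeros(3))
        for _ in range(5):
            assert attention_score(rng.standard_normal(3), rng.standard_normal(3),
                                   params, "perceptron") == 0.0

    def test_perceptron_two_dim_worked_case(self):
        """v^T tanh(W Q + U K) with identity maps, unit query/key = 2 tanh(1)."""
        params = AttentionParams(W_alpha=np.eye(2), U_alpha=np.eye(2),
                                 v_alpha=np.ones(2), query=np.array([1.0, 0.0]))
        score = attention_score(np.array([1.0, 0.0]), np.array([0.0, 1.0]),
                                params, "perceptron")
        assert score == pytest.approx(2 * np.tanh(1.0))

    def test_cascade_concatenation(self):
        params = AttentionParams(W_alpha=np.arange(4.0), query=np.array([1.0, 2.0]))
        score = attention_score(np.array([1.0, 2.0]), np.array([3.0, 4.0]),
                                params, "cascade")
        assert score == pytest.approx(0 * 1 + 1 * 2 + 2 * 3 + 3 * 4)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            attention_score(np.zeros(3), np.zeros(4), _params("multiplicative", 3), "multiplicative")

    def test_batched_module_matches_functional(self, rng):
        for mode in ("multiplicative", "cascade", "perceptron"):
            att = Attention(4, mode=mode, rng=rng, dtype=np.float64)
            keys = rng.standard_normal((2, 5, 4))
            att(keys)
            scores = att._scores(keys) if mode != "perceptron" else None
            params = att.as_params()
            expect = np.array([
                [attention_score(att.params["Q"], keys[n, t], params, mode)
                 for t in range(5)] for n in range(2)
            ])
            got = att._scores(keys)
            np.testing.assert_allclose(got, expect, atol=1e-10)


class TestAttentionPool:
    def test_uniform_scores_give_mean(self, rng):
        values = rng.standard_normal((6, 4))
        out = attention_pool(np.zeros(6), values)
        np.testing.assert_allclose(out.context, values.mean(axis=0), atol=1e-12)

    def test_dominant_score_saturates(self, rng):
        values = rng.standard_normal((5, 3))
        scores = np.zeros(5)
        scores[2] = 1000.0
        out = attention_pool(scores, values)
        np.testing.assert_allclose(out.context, values[2], atol=1e-6)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=20))
    def test_weights_are_probability_vector(self, scores):
        out = attention_pool(np.array(scores), np.ones((len(scores), 2)))
        assert np.all(out.weights >= 0)
        assert abs(out.weights.sum() - 1.0) < 1e-8

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            attention_pool(np.zeros(3), np.ones((4, 2)))


class TestClassify:
    def test_zero_parameters_give_half(self):
        assert classify(np.ones(4), np.zeros(4), 0.0) == pytest.approx(0.5)

    def test_monotone_in_logit(self, rng):
        w = rng.standard_normal(3)
        ctx = rng.standard_normal(3)
        probs = [classify(ctx, w, b) for b in np.linspace(-5, 5, 11)]
        assert np.all(np.diff(probs) > 0)

    def test_extreme_logits_stay_inside_unit_interval(self):
        lo = classify(np.array([1e9]), np.array([-1.0]))
        hi = classify(np.array([1e9]), np.array([1.0]))
        assert 0.0 < lo < hi < 1.0
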