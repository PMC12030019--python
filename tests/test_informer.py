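"""ProbSparse attention, distilling and the forecaster forward pass."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

import cropcast as cc
from cropcast.informer import (AttentionConfig, ForecastWindowConfig,
                               InformerModel, ModelConfig, distill_layer,
                               extrapolate_trend, informer_forward,
                               make_windows, n_dominant_queries,
                               probsparse_attention, sparsity_measure)

RNG = np.random.default_rng(42)


def _dense_oracle(Q, K, V):
    """Independent dense attention: naive per-row softmax in float64."""
    d = Q.shape[-1]
    S = Q @ K.T / math.sqrt(d)
    out = np.empty((Q.shape[0], V.shape[1]))
    for i in range(Q.shape[0]):
        e = np.exp(S[i] - S[i].max())
        out[i] = (e / e.sum()) @ V
    return out


class TestSparsityMeasure:
    def test_orthogonal_queries_zero(self):
        Q = np.array([[1.0, 0.0]])
        K = np.array([[0.0, 1.0], [0.0, 2.0]])
        np.testing.assert_allclose(sparsity_measure(Q, K), [0.0])

    def test_equal_inner_products_zero(self):
        # identical keys make every inner product equal, so max == mean
        Q = RNG.normal(size=(4, 3))
        K = np.tile(RNG.normal(size=(1, 3)), (6, 1))
        np.testing.assert_allclose(sparsity_measure(Q, K), 0.0, atol=1e-12)

    def test_matches_entrywise_brute_force(self):
        Q = RNG.normal(size=(6, 2))
        K = RNG.normal(size=(5, 2))
        expected = np.empty(6)
        for i in range(6):
            scores = [Q[i] @ K[j] / math.sqrt(2) for j in range(5)]
            expected[i] = max(scores) - sum(scores) / 5
        np.testing.assert_allclose(sparsity_measure(Q, K), expected, atol=1e-12)

    def test_zero_dim_rejected(self):
        with pytest.raises(ValueError):
            sparsity_measure(np.empty((3, 0)), np.empty((4, 0)))


class TestProbSparseAttention:
    def test_u_equals_lq_matches_dense(self):
        for _ in range(10):
            L_Q, L_K, d = RNG.integers(2, 16), RNG.integers(2, 16), RNG.integers(1, 5)
            Q, K = RNG.normal(size=(L_Q, d)), RNG.normal(size=(L_K, d))
            V = RNG.normal(size=(L_K, d))
            out = probsparse_attention(Q, K, V, u=L_Q)
            np.testing.assert_allclose(out, _dense_oracle(Q, K, V), atol=1e-6)

    def test_dominant_rows_are_convex_combinations(self):
        Q, K = RNG.normal(size=(8, 3)), RNG.normal(size=(6, 3))
        V = RNG.normal(size=(6, 3))
        u = 3
        out = probsparse_attention(Q, K, V, u=u)
        M = sparsity_measure(Q, K)
        dominant = np.argsort(-M)[:u]
        for i in dominant:
            np.testing.assert_allclose(out[i], _dense_oracle(Q, K, V)[i], atol=1e-6)
            assert (out[i] >= V.min(axis=0) - 1e-9).all()
            assert (out[i] <= V.max(axis=0) + 1e-9).all()

    def test_non_dominant_rows_get_value_mean(self):
        Q, K = RNG.normal(size=(8, 3)), RNG.normal(size=(6, 3))
        V = RNG.normal(size=(6, 3))
        out = probsparse_attention(Q, K, V, u=2)
        M = sparsity_measure(Q, K)
        lazy = np.argsort(-M)[2:]
        for i in lazy:
            np.testing.assert_allclose(out[i], V.mean(axis=0), atol=1e-9)

    def test_single_dominant_query_hand_case(self):
        # one sharply peaked query among flat ones: its row reproduces the
        # softmax weights over an identity-like V directly
        Q = np.array([[4.0, 0.0], [0.05, 0.05], [0.05, -0.05]])
        K = np.array([[4.0, 0.0], [0.0, 4.0], [-4.0, 0.0]])
        V = np.eye(3)
        out = probsparse_attention(Q, K, V, u=1)
        s = np.array([Q[0] @ K[j] / math.sqrt(2) for j in range(3)])
        w = np.exp(s - s.max())
        w /= w.sum()
        np.testing.assert_allclose(out[0], w, atol=1e-9)

    def test_u_below_one_rejected(self):
        Q = K = V = RNG.normal(size=(4, 2))
        with pytest.raises(ValueError):
            probsparse_attention(Q, K, V, u=0)

    def test_dominant_query_count_at_operating_point(self):
        # c=5, L_Q=164 under ceiling rounding
        assert n_dominant_queries(164, 5.0) == 26
        assert AttentionConfig(d=8).u(164) == 26
        assert n_dominant_queries(1) == 1
        assert n_dominant_queries(3, 100.0) == 3  # capped at L_Q


class TestDistillLayer:
    def test_halves_length_164_to_82(self):
        X = RNG.normal(size=(164, 8))
        assert distill_layer(X).shape == (82, 8)

    def test_identity_conv_on_ramp_closed_form(self):
        # identity convolution + ELU (identity on nonnegatives) + pool:
        # out[j] = max over window [2j, 2j+2] of the ramp = x[min(2j+2, L-1)]
        L = 12
        X = np.arange(float(L))[:, None]
        out = distill_layer(X)
        expected = np.array([min(2 * j + 2, L - 1) for j in range(6)], float)
        np.testing.assert_allclose(out[:, 0], expected)

    def test_three_stacked_lengths(self):
        X = RNG.normal(size=(164, 4))
        for expected in (82, 41, 21):
            X = distill_layer(X)
            assert X.shape[0] == expected

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            distill_layer(RNG.normal(size=(1, 4)))


def _feature_frame(hours=260, seed=0):
    rng = np.random.default_rng(seed)
    idx = pd.date_range("2024-04-01", periods=hours, freq="h")
    df = pd.DataFrame({
        "soil_moist_pct_n1": np.linspace(1, 0, hours) + 0.01 * rng.normal(size=hours),
        "air_temp_C": 0.5 + 0.3 * np.sin(np.arange(hours) / 24),
    }, index=idx)
    target = pd.Series(np.linspace(0.2, 0.8, hours), index=idx)
    return df, target


class TestInformerForward:
    CFG = ModelConfig(d_model=16, d_ff=32, n_heads=4,
                      window=ForecastWindowConfig(seq_len=48, label_len=36,
                                                  pred_len=24))

    def test_zero_weights_give_constant_output(self):
        df, target = _feature_frame()
        model = InformerModel(2, self.CFG, seed=0, n_dec_extra=1)
        model.zero_weights()
        bias = 0.125
        model.head.b.data[:] = bias
        out = informer_forward(model, df, target)
        expected = target.iloc[-1] + bias  # persistence residual + head bias
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_bitwise_deterministic(self):
        df, target = _feature_frame()
        model = InformerModel(2, self.CFG, seed=3, n_dec_extra=1)
        a = informer_forward(model, df, target)
        b = informer_forward(model, df, target)
        np.testing.assert_array_equal(a, b)

    def test_default_horizon_length_150(self):
        df, target = _feature_frame(hours=400)
        model = InformerModel(2, ModelConfig(d_model=16, d_ff=32, n_heads=4),
                              seed=0, n_dec_extra=1)
        assert informer_forward(model, df, target).shape == (150,)

    def test_permutation_sensitive(self):
        df, target = _feature_frame()
        model = InformerModel(2, self.CFG, seed=5, n_dec_extra=1)
        base = informer_forward(model, df, target)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(df))
        shuffled = df.iloc[perm].set_index(df.index)
        out = informer_forward(model, shuffled, target)
        assert np.abs(base - out).max() > 1e-6

    def test_short_history_rejected(self):
        df, target = _feature_frame(hours=30)
        model = InformerModel(2, self.CFG, seed=0, n_dec_extra=1)
        with pytest.raises(ValueError):
            informer_forward(model, df, target)


class TestWindows:
    def test_make_windows_shapes(self):
        df, target = _feature_frame(hours=120)
        w = ForecastWindowConfig(seq_len=48, label_len=36, pred_len=24)
        x_enc, x_dec, last, y = make_windows(df, target, w, stride=10)
        n = (120 - 72) // 10 + 1
        assert x_enc.shape == (n, 48, 2 + 3)           # features + time
        assert x_dec.shape == (n, 60, 1 + 3 + 1)       # status + time + moisture
        assert last.shape == (n, 1)
        assert y.shape == (n, 24)

    def test_window_config_validation(self):
        with pytest.raises(ValueError):
            ForecastWindowConfig(seq_len=10, label_len=20, pred_len=5)
        with pytest.raises(ValueError):
            ForecastWindowConfig(pred_len=0)

    def test_extrapolate_trend_tracks_linear_series(self):
        y = 10.0 - 0.05 * np.arange(200)
        out = extrapolate_trend(y, 50)
        expected = 10.0 - 0.05 * np.arange(200, 250)
        np.testing.assert_allclose(out, expected, atol=1e-9)
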