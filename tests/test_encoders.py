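"""Encoder tests: conv/pool/residual/dense oracles, LSTM/GRU cells,
attention, positional encoding and the visual backbones."""

import numpy as np
import pytest

from birdfuse.encoders import (
    AugmentationConfig,
    BackboneConfig,
    Conv2d,
    Dense,
    GlobalAvgPool,
    LSTMEncoder,
    MaxPool2d,
    ResidualBlock,
    Sequential,
    attention,
    build_backbone,
    conv2d,
    gru_step,
    init_gru_params,
    init_lstm_params,
    lstm_encode,
    lstm_step,
    max_pool,
    positional_encoding,
    preprocess_image,
    residual_forward,
    visual_embed,
)
from birdfuse.errors import FormatError, InvalidConfigError, ShapeError


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestConv2d:
    def test_identity_kernel(self):
        x = np.random.default_rng(0).normal(size=(6, 6, 1))
        layer = Conv2d(1, 1, 1, padding="valid")
        layer.W.value[...] = 1.0
        layer.b.value[...] = 0.0
        np.testing.assert_allclose(conv2d(x, layer), x)

    def test_relu_nonnegative(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(8, 8, 2))
        layer = Conv2d(2, 4, 3, activation="relu", rng=rng)
        assert np.all(conv2d(x, layer) >= 0.0)

    def test_matches_quadruple_loop_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(5, 5, 2))
        layer = Conv2d(2, 3, 3, padding="valid", rng=rng)
        out = conv2d(x, layer)
        W, b = layer.W.value, layer.b.value
        oracle = np.zeros((3, 3, 3))
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    acc = 0.0
                    for m in range(3):
                        for n in range(3):
                            for c in range(2):
                                acc += W[m, n, c, k] * x[i + m, j + n, c]
                    oracle[i, j, k] = acc + b[k]
        np.testing.assert_allclose(out, oracle, atol=1e-10)

    def test_channel_mismatch_is_shape_error(self):
        layer = Conv2d(3, 2, 3)
        with pytest.raises(ShapeError):
            conv2d(np.zeros((5, 5, 1)), layer)

    def test_backward_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(1, 4, 4, 2))
        layer = Conv2d(2, 2, 3, padding="same", rng=rng)
        out = layer.forward(x)
        g = rng.normal(size=out.shape)
        layer.zero_grad()
        dx = layer.backward(g)
        eps = 1e-6
        for idx in [(0, 1, 2, 0), (0, 3, 0, 1)]:
            xp, xm = x.copy(), x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            num = ((layer.forward(xp) * g).sum() - (layer.forward(xm) * g).sum()) / (2 * eps)
            assert dx[idx] == pytest.approx(num, abs=1e-5)


class TestMaxPool:
    def test_two_by_two(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]])[:, :, None]
        assert max_pool(x, 2)[0, 0, 0] == 4.0

    def test_constant_input(self):
        x = np.full((4, 4, 2), 7.0)
        np.testing.assert_array_equal(max_pool(x, 2), np.full((2, 2, 2), 7.0))

    def test_matches_window_scan_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(6, 6, 3))
        out = max_pool(x, 2, 2)
        for i in range(3):
            for j in range(3):
                for c in range(3):
                    assert out[i, j, c] == x[2 * i : 2 * i + 2, 2 * j : 2 * j + 2, c].max()

    def test_window_too_large(self):
        with pytest.raises(ShapeError):
            max_pool(np.zeros((2, 2, 1)), 5)


class TestResidualBlock:
    def test_zero_inner_is_identity(self):
        rng = np.random.default_rng(5)
        inner = Sequential(Conv2d(2, 2, 3, padding="same", rng=rng))
        inner.layers[0].W.value[...] = 0.0
        block = ResidualBlock(inner)
        x = rng.normal(size=(5, 5, 2))
        np.testing.assert_allclose(residual_forward(x, block), x)

    def test_additivity(self):
        rng = np.random.default_rng(6)
        inner = Sequential(Conv2d(2, 2, 3, padding="same", rng=rng))
        block = ResidualBlock(inner)
        x = rng.normal(size=(4, 4, 2))
        y = residual_forward(x, block)
        np.testing.assert_allclose(y - x, inner.forward(x), atol=1e-10)

    def test_input_gradient_has_identity_path(self):
        rng = np.random.default_rng(7)
        inner = Sequential(Conv2d(2, 2, 3, padding="same", rng=rng, init_scale=0.3))
        block = ResidualBlock(inner)
        x = rng.normal(size=(1, 4, 4, 2))
        out = block.forward(x)
        g = rng.normal(size=out.shape)
        block.inner.layers[0].zero_grad()
        dx = block.backward(g)
        eps = 1e-6
        idx = (0, 2, 1, 0)
        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        num = ((block.forward(xp) * g).sum() - (block.forward(xm) * g).sum()) / (2 * eps)
        assert dx[idx] == pytest.approx(num, abs=1e-4)

    def test_shape_mismatch_without_projection(self):
        rng = np.random.default_rng(8)
        inner = Sequential(Conv2d(2, 4, 3, padding="same", rng=rng))
        block = ResidualBlock(inner)
        with pytest.raises(ShapeError):
            residual_forward(np.zeros((4, 4, 2)), block)


class TestPreprocessImage:
    def test_deterministic_without_augmentation(self):
        rng = np.random.default_rng(9)
        img = rng.uniform(size=(50, 40, 3))
        a = preprocess_image(img, 224)
        b = preprocess_image(img, 224)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (224, 224, 3)

    def test_range_and_shape(self):
        rng = np.random.default_rng(10)
        img = rng.uniform(size=(64, 64, 3)) * 255.0
        out = preprocess_image(img, 224, AugmentationConfig(), np.random.default_rng(0))
        assert out.shape == (224, 224, 3)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_flip_is_involution(self):
        rng = np.random.default_rng(11)
        img = rng.uniform(size=(32, 32, 3))
        flipped_twice = img[:, ::-1][:, ::-1]
        np.testing.assert_array_equal(flipped_twice, img)

    def test_non_rgb_rejected(self):
        with pytest.raises(FormatError):
            preprocess_image(np.zeros((40, 40)), 224)
        with pytest.raises(FormatError):
            preprocess_image(np.zeros((10, 10, 3)), 224)


class TestVisualBackbone:
    def test_resnet50_ref_embedding_length(self):
        backbone = build_backbone(BackboneConfig("resnet50_ref", 2048), seed=0)
        img = np.random.default_rng(0).uniform(size=(224, 224, 3))
        emb = visual_embed(preprocess_image(img, 224), backbone)
        assert emb.shape == (2048,)
        assert np.all(np.isfinite(emb))

    def test_resnet50_ref_has_49_conv_layers(self):
        from birdfuse.encoders.layers import Conv2d as ConvLayer

        backbone = build_backbone(BackboneConfig("resnet50_ref", 2048), seed=0)

        def count(module):
            if isinstance(module, ConvLayer):
                return 1
            total = 0
            if isinstance(module, Sequential):
                total += sum(count(l) for l in module.layers)
            if isinstance(module, ResidualBlock):
                total += count(module.inner)  # projection shortcuts not counted
            return total

        assert count(backbone.stack) == 49

    def test_tiny_configurable_dim(self):
        backbone = build_backbone(BackboneConfig("tiny", 32), seed=1)
        emb = visual_embed(np.random.default_rng(1).uniform(size=(32, 32, 3)), backbone)
        assert emb.shape == (32,)

    def test_deterministic_embedding(self):
        config = BackboneConfig("tiny", 16)
        img = np.random.default_rng(2).uniform(size=(32, 32, 3))
        e1 = visual_embed(img, build_backbone(config, seed=3))
        e2 = visual_embed(img, build_backbone(config, seed=3))
        np.testing.assert_array_equal(e1, e2)

    def test_invalid_variant(self):
        with pytest.raises(InvalidConfigError):
            BackboneConfig("resnet152", 2048)


class TestLSTM:
    def test_zero_params_single_step(self):
        params = init_lstm_params(2, 3, np.random.default_rng(0))
        for p in params.params():
            p.value[...] = 0.0
        h, c = lstm_step(np.ones(2), np.zeros(3), np.zeros(3), params)
        # f = i = o = 0.5, c~ = 0 => c = 0, h = 0
        np.testing.assert_array_equal(c, 0.0)
        np.testing.assert_array_equal(h, 0.0)

    def test_single_step_matches_equation_oracle(self):
        rng = np.random.default_rng(12)
        params = init_lstm_params(4, 3, rng)
        x = rng.normal(size=4)
        h0 = rng.normal(size=3)
        c0 = rng.normal(size=3)
        h, c = lstm_step(x, h0, c0, params)
        z = np.concatenate([h0, x])
        f = _sigmoid(params.W_f.value @ z + params.b_f.value)
        i = _sigmoid(params.W_i.value @ z + params.b_i.value)
        ct = np.tanh(params.W_C.value @ z + params.b_C.value)
        c_exp = f * c0 + i * ct
        o = _sigmoid(params.W_o.value @ z + params.b_o.value)
        np.testing.assert_allclose(c, c_exp, atol=1e-10)
        np.testing.assert_allclose(h, o * np.tanh(c_exp), atol=1e-10)

    def test_frame_order_matters(self):
        rng = np.random.default_rng(13)
        params = init_lstm_params(2, 4, rng)
        head = Dense(4, 4, rng=rng)
        seq = rng.normal(size=(5, 2))
        swapped = seq.copy()
        swapped[[0, 4]] = swapped[[4, 0]]
        a = lstm_encode(seq, params, head)
        b = lstm_encode(swapped, params, head)
        assert np.max(np.abs(a - b)) > 1e-8

    def test_encoder_batch_matches_stepwise(self):
        rng = np.random.default_rng(14)
        enc = LSTMEncoder(3, 5, rng)
        seq = rng.normal(size=(6, 3))
        h = np.zeros(5)
        c = np.zeros(5)
        for t in range(6):
            h, c = lstm_step(seq[t], h, c, enc.cell)
        np.testing.assert_allclose(enc.forward(seq), h, atol=1e-12)

    def test_encoder_bptt_matches_finite_differences(self):
        rng = np.random.default_rng(15)
        enc = LSTMEncoder(2, 3, rng)
        seq = rng.normal(size=(1, 4, 2))
        g = rng.normal(size=(1, 3))
        enc.forward(seq)
        enc.zero_grad()
        enc.backward(g)
        p = enc.cell.W_C
        eps = 1e-6
        idx = (1, 2)
        orig = p.value[idx]
        p.value[idx] = orig + eps
        up = (enc.forward(seq) * g).sum()
        p.value[idx] = orig - eps
        down = (enc.forward(seq) * g).sum()
        p.value[idx] = orig
        assert p.grad[idx] == pytest.approx((up - down) / (2 * eps), abs=1e-5)

    def test_feature_size_mismatch(self):
        params = init_lstm_params(3, 2, np.random.default_rng(0))
        with pytest.raises(ShapeError):
            lstm_step(np.ones(5), np.zeros(2), np.zeros(2), params)


class TestGRU:
    def test_zero_weights_halves_hidden(self):
        params = init_gru_params(2, 3, np.random.default_rng(0))
        for p in params.params():
            p.value[...] = 0.0
        h_prev = np.array([1.0, -2.0, 4.0])
        np.testing.assert_allclose(gru_step(np.ones(2), h_prev, params), 0.5 * h_prev)

    def test_zero_hidden_zero_weights(self):
        params = init_gru_params(2, 3, np.random.default_rng(0))
        for p in params.params():
            p.value[...] = 0.0
        np.testing.assert_array_equal(gru_step(np.ones(2), np.zeros(3), params), 0.0)

    def test_matches_equation_oracle(self):
        rng = np.random.default_rng(16)
        params = init_gru_params(3, 4, rng)
        x = rng.normal(size=3)
        h = rng.normal(size=4)
        out = gru_step(x, h, params)
        z = _sigmoid(params.W_z.value @ x + params.U_z.value @ h)
        r = _sigmoid(params.W_r.value @ x + params.U_r.value @ h)
        h_tilde = np.tanh(params.W.value @ x + r * (params.U.value @ h))
        np.testing.assert_allclose(out, (1 - z) * h + z * h_tilde, atol=1e-10)

    def test_shape_errors(self):
        params = init_gru_params(3, 4, np.random.default_rng(0))
        with pytest.raises(ShapeError):
            gru_step(np.ones(2), np.zeros(4), params)
        with pytest.raises(ShapeError):
            gru_step(np.ones(3), np.zeros(2), params)


class TestAttention:
    def test_single_key_value_returns_value(self):
        Q = np.array([[3.0, -1.0]])
        K = np.array([[0.5, 0.5]])
        V = np.array([[7.0, 8.0, 9.0]])
        np.testing.assert_allclose(attention(Q, K, V), V)

    def test_identical_keys_average_values(self):
        rng = np.random.default_rng(17)
        Q = rng.normal(size=(2, 3))
        K = np.tile(rng.normal(size=(1, 3)), (4, 1))
        V = rng.normal(size=(4, 5))
        out = attention(Q, K, V)
        np.testing.assert_allclose(out, np.tile(V.mean(axis=0), (2, 1)), atol=1e-12)

    def test_weights_rows_sum_to_one(self):
        rng = np.random.default_rng(18)
        Q, K = rng.normal(size=(3, 4)), rng.normal(size=(6, 4))
        scores = Q @ K.T / np.sqrt(4)
        w = np.exp(scores - scores.max(axis=1, keepdims=True))
        w /= w.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-12)
        # and the module output equals the explicit weighted sum
        V = rng.normal(size=(6, 2))
        np.testing.assert_allclose(attention(Q, K, V), w @ V, atol=1e-12)

    def test_shape_errors(self):
        with pytest.raises(ShapeError):
            attention(np.zeros((2, 3)), np.zeros((2, 4)), np.zeros((2, 2)))
        with pytest.raises(ShapeError):
            attention(np.zeros((2, 3)), np.zeros((4, 3)), np.zeros((5, 2)))


class TestPositionalEncoding:
    def test_position_zero(self):
        pe = positional_encoding(3, 6)
        np.testing.assert_array_equal(pe[0, 0::2], 0.0)
        np.testing.assert_array_equal(pe[0, 1::2], 1.0)

    def test_bounded(self):
        pe = positional_encoding(50, 16)
        assert pe.min() >= -1.0 and pe.max() <= 1.0

    def test_closed_form_value(self):
        assert positional_encoding(2, 4)[1, 0] == pytest.approx(np.sin(1.0))

    def test_odd_dimension_rejected(self):
        with pytest.raises(InvalidConfigError):
            positional_encoding(4, 5)


class TestDense:
    def test_backward_matches_finite_differences(self):
        rng = np.random.default_rng(19)
        layer = Dense(4, 3, activation="relu", rng=rng)
        x = rng.normal(size=(2, 4))
        g = rng.normal(size=(2, 3))
        layer.forward(x)
        layer.zero_grad()
        layer.backward(g)
        eps = 1e-6
        idx = (1, 2)
        orig = layer.W.value[idx]
        layer.W.value[idx] = orig + eps
        up = (layer.forward(x) * g).sum()
        layer.W.value[idx] = orig - eps
        down = (layer.forward(x) * g).sum()
        layer.W.value[idx] = orig
        assert layer.W.grad[idx] == pytest.approx((up - down) / (2 * eps), abs=1e-5)

    def test_dimension_mismatch(self):
        with pytest.raises(ShapeError):
            Dense(4, 2).forward(np.zeros(3))


def test_global_avg_pool_backward():
    gap = GlobalAvgPool()
    x = np.arange(16.0).reshape(1, 2, 2, 4)
    out = gap.forward(x)
    np.testing.assert_allclose(out[0], x[0].mean(axis=(0, 1)))
    dx = gap.backward(np.ones((1, 4)))
    np.testing.assert_allclose(dx, 0.25)
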