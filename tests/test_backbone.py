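"""Backbone stages: attention, Transformer, CNN, BiLSTM, emission head."""

import numpy as np
import pytest

from sslabel.autodiff import Tensor
from sslabel.backbone import (
    Backbone, BackboneConfig, BiLSTM, ConvStack, Linear, TransformerEncoder,
    scaled_dot_attention,
)
from sslabel import autodiff as ad


class TestScaledDotAttention:
    def test_single_position_returns_value_row(self, rng):
        V = rng.standard_normal((1, 5))
        out = scaled_dot_attention(rng.standard_normal((1, 3)),
                                   rng.standard_normal((1, 3)), V)
        np.testing.assert_allclose(out, V, atol=1e-12)

    def test_identical_keys_average_values(self, rng):
        K = np.tile(rng.standard_normal(4), (6, 1))
        V = rng.standard_normal((6, 3))
        out = scaled_dot_attention(rng.standard_normal((2, 4)), K, V)
        np.testing.assert_allclose(out, np.tile(V.mean(axis=0), (2, 1)), atol=1e-12)

    def test_hand_evaluated_two_key_case(self):
        # weights = softmax(1/sqrt(2), 0); output = w @ V
        Q = np.array([[1.0, 0.0]])
        K = np.array([[1.0, 0.0], [0.0, 1.0]])
        V = np.array([[1.0, 0.0], [0.0, 1.0]])
        logits = np.array([1.0 / np.sqrt(2.0), 0.0])
        w = np.exp(logits) / np.exp(logits).sum()
        out = scaled_dot_attention(Q, K, V)
        np.testing.assert_allclose(out, w[None, :] @ V, atol=1e-12)

    def test_zero_key_dim_rejected(self):
        with pytest.raises(ValueError):
            scaled_dot_attention(np.zeros((2, 0)), np.zeros((2, 0)), np.zeros((2, 3)))


class TestConfig:
    def test_head_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divisible"):
            BackboneConfig(d_model=30, attention_heads=8)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            BackboneConfig(conv_kernel=4)

    def test_full_scale_defaults(self):
        cfg = BackboneConfig()
        assert (cfg.d_model, cfg.transformer_layers, cfg.attention_heads,
                cfg.conv_layers, cfg.lstm_hidden) == (512, 6, 8, 3, 256)


class TestTransformerEncoder:
    def test_shape_preserved_at_full_scale(self, rng):
        cfg = BackboneConfig(d_model=512, transformer_layers=6, attention_heads=8,
                             ffn_dim=512)
        enc = TransformerEncoder(rng, cfg)
        x = Tensor(rng.standard_normal((1, 10, 512)))
        out = enc(x, np.ones((1, 10)))
        assert out.shape == (1, 10, 512)

    def test_zeroed_output_projections_reduce_to_normalization(self, rng):
        cfg = BackboneConfig(d_model=8, transformer_layers=1, attention_heads=2,
                             ffn_dim=16, dropout=0.0)
        enc = TransformerEncoder(rng, cfg)
        blk = enc.blocks[0]
        blk.Wo.data[:] = 0.0
        blk.W2.data[:] = 0.0
        x_arr = rng.standard_normal((2, 5, 8))
        out = enc(Tensor(x_arr), np.ones((2, 5)))
        # with both residual branches zeroed the block is LN(LN(x))
        ln = lambda v: (v - v.mean(-1, keepdims=True)) / np.sqrt(
            v.var(-1, keepdims=True) + 1e-5)
        np.testing.assert_allclose(out.data, ln(ln(x_arr)), atol=1e-10)

    def test_padded_keys_do_not_influence_real_rows(self, rng):
        cfg = BackboneConfig(d_model=8, transformer_layers=2, attention_heads=2,
                             ffn_dim=16, dropout=0.0)
        enc = TransformerEncoder(rng, cfg)
        x = rng.standard_normal((1, 4, 8))
        out_short = enc(Tensor(x), np.ones((1, 4))).data
        padded = np.concatenate([x, rng.standard_normal((1, 3, 8))], axis=1)
        mask = np.array([[1.0] * 4 + [0.0] * 3])
        out_padded = enc(Tensor(padded), mask).data
        np.testing.assert_allclose(out_padded[0, :4], out_short[0], atol=1e-10)


class TestConvStack:
    def test_length_preserved(self, rng):
        cfg = BackboneConfig(d_model=6, conv_layers=2, conv_kernel=3,
                             attention_heads=2, dropout=0.0)
        conv = ConvStack(rng, cfg, d_in=6)
        out = conv(Tensor(rng.standard_normal((2, 9, 6))), np.ones((2, 9)))
        assert out.shape == (2, 9, 6)

    def test_kernel1_identity_weights_pass_nonnegative_input(self, rng):
        cfg = BackboneConfig(d_model=4, conv_layers=1, conv_kernel=1,
                             attention_heads=2, dropout=0.0)
        conv = ConvStack(rng, cfg, d_in=4)
        conv.weights[0].data = np.eye(4)[None, :, :]
        conv.biases[0].data[:] = 0.0
        x = np.abs(rng.standard_normal((1, 5, 4)))  # ReLU is identity here
        out = conv(Tensor(x), np.ones((1, 5)))
        np.testing.assert_allclose(out.data, x, atol=1e-12)

    def test_receptive_field_radius(self, rng):
        """Three stacked kernel-3 convolutions reach at most 3 positions."""
        cfg = BackboneConfig(d_model=4, conv_layers=3, conv_kernel=3,
                             attention_heads=2, dropout=0.0)
        conv = ConvStack(rng, cfg, d_in=4)
        for b in conv.biases:  # bias would light up every position
            b.data[:] = 0.0
        x = np.zeros((1, 11, 4))
        x[0, 5] = 1.0
        out = conv(Tensor(x), np.ones((1, 11))).data[0]
        nonzero = np.where(np.abs(out).sum(axis=1) > 0)[0]
        assert nonzero.size > 0
        assert nonzero.min() >= 2 and nonzero.max() <= 8


class TestBiLSTM:
    def _make(self, rng, d_in=5, hidden=4):
        cfg = BackboneConfig(d_model=6, lstm_hidden=hidden, attention_heads=2)
        return BiLSTM(rng, cfg, d_in)

    def test_output_width_is_twice_hidden(self, rng):
        lstm = self._make(rng)
        out = lstm(Tensor(rng.standard_normal((2, 7, 5))), np.array([7, 7]))
        assert out.shape == (2, 7, 8)

    def test_full_scale_width(self, rng):
        cfg = BackboneConfig(d_model=512, lstm_hidden=256, attention_heads=8)
        lstm = BiLSTM(rng, cfg, 512)
        out = lstm(Tensor(rng.standard_normal((1, 5, 512))), np.array([5]))
        assert out.shape == (1, 5, 512)

    def test_single_step(self, rng):
        lstm = self._make(rng)
        out = lstm(Tensor(rng.standard_normal((1, 1, 5))), np.array([1]))
        assert out.shape == (1, 1, 8)

    def test_reversal_equivariance(self, rng):
        """With tied direction weights, reversing the input swaps and
        reverses the two directional halves of the output."""
        lstm = self._make(rng, hidden=3)
        for suffix in ("Wx", "Wh", "b"):
            lstm._params[f"lstm_b.{suffix}"].data = (
                lstm._params[f"lstm_f.{suffix}"].data.copy()
            )
        x = rng.standard_normal((1, 6, 5))
        out = lstm(Tensor(x), np.array([6])).data[0]
        out_rev = lstm(Tensor(x[:, ::-1, :].copy()), np.array([6])).data[0]
        np.testing.assert_allclose(out_rev[::-1, 3:], out[:, :3], atol=1e-12)
        np.testing.assert_allclose(out_rev[::-1, :3], out[:, 3:], atol=1e-12)


class TestFullBackbone:
    def _backbone(self, rng, **kw):
        cfg = BackboneConfig(d_model=8, transformer_layers=1, attention_heads=2,
                             ffn_dim=16, conv_layers=1, conv_kernel=3,
                             conv_channels=8, lstm_hidden=4, dropout=0.0,
                             emission_dim=3)
        return Backbone(rng, cfg, d_in=10, **kw)

    def test_length_preserving_map_to_emissions(self, rng):
        bb = self._backbone(rng)
        out = bb(rng.standard_normal((2, 12, 10)), np.array([12, 12]))
        assert out.shape == (2, 12, 3)

    def test_emission_head_zero_weights_gives_bias(self, rng):
        bb = self._backbone(rng)
        bb.head.W.data[:] = 0.0
        bb.head.b.data[:] = [1.0, 2.0, 3.0]
        out = bb(rng.standard_normal((1, 4, 10)), np.array([4]))
        np.testing.assert_allclose(out.data[0], np.tile([1, 2, 3], (4, 1)), atol=1e-12)

    @pytest.mark.parametrize("K", [3, 8])
    def test_emission_width_matches_alphabet(self, rng, K):
        cfg = BackboneConfig(d_model=8, transformer_layers=1, attention_heads=2,
                             ffn_dim=16, conv_layers=1, lstm_hidden=4,
                             emission_dim=K, dropout=0.0)
        bb = Backbone(rng, cfg, d_in=6)
        out = bb(rng.standard_normal((1, 5, 6)), np.array([5]))
        assert out.shape == (1, 5, K)

    def test_padding_invariance_of_real_positions(self, rng):
        """Extending the batch with padding moves no real emission > 1e-5."""
        bb = self._backbone(rng)
        x = rng.standard_normal((1, 6, 10))
        alone = bb(x, np.array([6])).data[0]
        other = rng.standard_normal((1, 9, 10))
        batch = np.zeros((2, 9, 10))
        batch[0, :6] = x[0]
        batch[1] = other[0]
        together = bb(batch, np.array([6, 9])).data[0, :6]
        np.testing.assert_allclose(together, alone, atol=1e-5)

    def test_frozen_parameters_give_bitwise_deterministic_output(self, rng):
        bb = self._backbone(rng)
        x = rng.standard_normal((2, 5, 10))
        a = bb(x, np.array([5, 3])).data
        b = bb(x, np.array([5, 3])).data
        assert np.array_equal(a, b)

    @pytest.mark.parametrize(
        "kw", [{"use_transformer": False}, {"use_cnn": False},
               {"use_bilstm": False},
               {"use_transformer": False, "use_cnn": False, "use_bilstm": False}],
    )
    def test_ablated_stacks_still_map_to_emissions(self, rng, kw):
        bb = self._backbone(rng, **kw)
        out = bb(rng.standard_normal((1, 7, 10)), np.array([7]))
        assert out.shape == (1, 7, 3)

    def test_end_to_end_gradient_flows_to_all_parameters(self, rng):
        bb = self._backbone(rng)
        out = bb(rng.standard_normal((1, 5, 10)), np.array([5]))
        (out ** 2).sum().backward()
        for name, p in bb.named_parameters().items():
            assert p.grad is not None and np.abs(p.grad).max() > 0, name
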