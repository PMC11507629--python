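"""Neural backbone: fused features -> per-residue emission scores.

Stages, in order: an input projection to d_model, a stack of Transformer
encoder blocks (multi-head scaled dot-product attention + position-wise
feed-forward, post-norm residuals) for feature enhancement, a stack of
same-length 1-D convolutions for local motifs, a bidirectional LSTM for
long-range context, and an affine emission head producing the L x K
"firing scores" the CRF consumes (no softmax — the CRF normalizes
globally).

Batches are right-padded; a boolean mask is threaded through every
stage (additive -inf bias on attention keys, zeroed rows before each
convolution, length-aware reversal in the backward LSTM) so that a real
position's emission never depends on how much padding the batch carries.

Every stage preserves sequence length: the whole backbone is a
per-sequence L x D_in -> L x K map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "BackboneConfig", "scaled_dot_attention", "Linear", "TransformerEncoder",
    "ConvStack", "BiLSTM", "Backbone",
]

_NEG_INF = -1e30


@dataclass
class BackboneConfig:
    """Architecture hyperparameters.

    Defaults are the published operating point (d_model 512, 6 encoder
    layers with 8 heads, 3 convolutional layers, 256 LSTM units per
    direction); :meth:`desk_scale` returns a configuration small enough
    to train in seconds on one CPU for tests and synthetic studies.
    """

    d_model: int = 512
    transformer_layers: int = 6
    attention_heads: int = 8
    ffn_dim: Optional[int] = None  # defaults to 4 * d_model
    conv_layers: int = 3
    conv_kernel: int = 3
    conv_channels: Optional[int] = None  # defaults to d_model
    lstm_hidden: int = 256
    dropout: float = 0.1
    emission_dim: int = 3

    def __post_init__(self) -> None:
        if self.ffn_dim is None:
            self.ffn_dim = 4 * self.d_model
        if self.conv_channels is None:
            self.conv_channels = self.d_model
        if self.d_model % self.attention_heads != 0:
            raise ValueError(
                f"d_model={self.d_model} not divisible by "
                f"attention_heads={self.attention_heads}"
            )
        if self.conv_kernel % 2 == 0:
            raise ValueError("conv_kernel must be odd for same-length output")
        for name in ("transformer_layers", "attention_heads", "conv_layers",
                     "lstm_hidden", "d_model"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.emission_dim not in (3, 8):
            raise ValueError("emission_dim must be 3 or 8")

    @classmethod
    def desk_scale(cls, emission_dim: int = 3) -> "BackboneConfig":
        """Small configuration for CPU-scale training and tests."""
        return cls(
            d_model=32, transformer_layers=1, attention_heads=2, ffn_dim=64,
            conv_layers=1, conv_kernel=3, conv_channels=32, lstm_hidden=32,
            dropout=0.1, emission_dim=emission_dim,
        )


def scaled_dot_attention(Q, K, V, mask_bias: Optional[np.ndarray] = None):
    """Softmax(Q K^T / sqrt(d_k)) V with row-wise softmax over key positions.

    Accepts plain arrays (returns an array) or tape Tensors (returns a
    Tensor).  ``mask_bias`` is an additive pre-softmax term (use a large
    negative value at padded keys).
    """
    plain = not isinstance(Q, Tensor)
    Qt, Kt, Vt = ad.astensor(Q), ad.astensor(K), ad.astensor(V)
    d_k = Qt.shape[-1]
    if d_k == 0:
        raise ValueError("d_k must be positive")
    swap = tuple(range(Kt.ndim - 2)) + (Kt.ndim - 1, Kt.ndim - 2)
    scores = (Qt @ Kt.transpose(swap)) * (1.0 / math.sqrt(d_k))
    if mask_bias is not None:
        scores = scores + mask_bias
    out = ad.softmax(scores, axis=-1) @ Vt
    return out.data if plain else out


class Layer:
    """Base for parameterized layers; tracks trainable Tensors by name."""

    def __init__(self) -> None:
        self._params: dict[str, Tensor] = {}

    def param(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        return t

    def parameters(self) -> List[Tensor]:
        return list(self._params.values())

    def named_parameters(self) -> dict:
        return dict(self._params)


def _dense_init(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    return rng.standard_normal((fan_in, fan_out)) / math.sqrt(fan_in)


class Linear(Layer):
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int,
                 name: str = "linear"):
        super().__init__()
        self.W = self.param(f"{name}.W", _dense_init(rng, d_in, d_out))
        self.b = self.param(f"{name}.b", np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class _EncoderBlock(Layer):
    def __init__(self, rng, cfg: BackboneConfig, idx: int):
        super().__init__()
        d, name = cfg.d_model, f"enc{idx}"
        self.heads = cfg.attention_heads
        self.d_k = d // cfg.attention_heads
        for proj in ("Wq", "Wk", "Wv", "Wo"):
            setattr(self, proj, self.param(f"{name}.{proj}", _dense_init(rng, d, d)))
        self.bo = self.param(f"{name}.bo", np.zeros(d))
        self.ln1_g = self.param(f"{name}.ln1_g", np.ones(d))
        self.ln1_b = self.param(f"{name}.ln1_b", np.zeros(d))
        self.W1 = self.param(f"{name}.W1", _dense_init(rng, d, cfg.ffn_dim))
        self.b1 = self.param(f"{name}.b1", np.zeros(cfg.ffn_dim))
        self.W2 = self.param(f"{name}.W2", _dense_init(rng, cfg.ffn_dim, d))
        self.b2 = self.param(f"{name}.b2", np.zeros(d))
        self.ln2_g = self.param(f"{name}.ln2_g", np.ones(d))
        self.ln2_b = self.param(f"{name}.ln2_b", np.zeros(d))
        self.p_drop = cfg.dropout

    def __call__(self, x: Tensor, mask_bias: np.ndarray, *,
                 training: bool = False, rng=None) -> Tensor:
        B, L, d = x.shape
        qh = (x @ self.Wq).reshape(B, L, self.heads, self.d_k).transpose(0, 2, 1, 3)
        kh = (x @ self.Wk).reshape(B, L, self.heads, self.d_k).transpose(0, 2, 1, 3)
        vh = (x @ self.Wv).reshape(B, L, self.heads, self.d_k).transpose(0, 2, 1, 3)
        ctx = scaled_dot_attention(qh, kh, vh, mask_bias=mask_bias)
        ctx = ctx.transpose(0, 2, 1, 3).reshape(B, L, d) @ self.Wo + self.bo
        ctx = ad.dropout(ctx, self.p_drop, rng, training)
        x = ad.layer_norm(x + ctx, self.ln1_g, self.ln1_b)
        ffn = ad.relu(x @ self.W1 + self.b1) @ self.W2 + self.b2
        ffn = ad.dropout(ffn, self.p_drop, rng, training)
        return ad.layer_norm(x + ffn, self.ln2_g, self.ln2_b)


class TransformerEncoder(Layer):
    """Stack of post-norm encoder blocks with key-side padding masking."""

    def __init__(self, rng, cfg: BackboneConfig):
        super().__init__()
        self.blocks = [_EncoderBlock(rng, cfg, i) for i in range(cfg.transformer_layers)]
        for blk in self.blocks:
            self._params.update(blk.named_parameters())

    def __call__(self, x: Tensor, mask: np.ndarray, *,
                 training: bool = False, rng=None) -> Tensor:
        # additive bias: 0 at real keys, -inf at padded keys
        mask_bias = np.where(mask[:, None, None, :] > 0, 0.0, _NEG_INF)
        for blk in self.blocks:
            x = blk(x, mask_bias, training=training, rng=rng)
        return x


class ConvStack(Layer):
    """Stacked same-length 1-D convolutions with ReLU."""

    def __init__(self, rng, cfg: BackboneConfig, d_in: int):
        super().__init__()
        self.kernel = cfg.conv_kernel
        self.weights, self.biases = [], []
        ch_in = d_in
        for i in range(cfg.conv_layers):
            w = self.param(
                f"conv{i}.W",
                rng.standard_normal((cfg.conv_kernel, ch_in, cfg.conv_channels))
                / math.sqrt(cfg.conv_kernel * ch_in),
            )
            b = self.param(f"conv{i}.b", np.zeros(cfg.conv_channels))
            self.weights.append(w)
            self.biases.append(b)
            ch_in = cfg.conv_channels
        self.d_out = ch_in
        self.p_drop = cfg.dropout

    def __call__(self, x: Tensor, mask: np.ndarray, *,
                 training: bool = False, rng=None) -> Tensor:
        m = mask[:, :, None]
        for w, b in zip(self.weights, self.biases):
            x = x * m  # padded rows must be exact zeros before each conv
            x = ad.relu(ad.conv1d(x, w, b))
            x = ad.dropout(x, self.p_drop, rng, training)
        return x


class BiLSTM(Layer):
    """Forward and backward LSTM passes, concatenated per position.

    The backward pass reverses each sequence within its own length, so
    padding never leaks into real positions from the right.
    """

    def __init__(self, rng, cfg: BackboneConfig, d_in: int):
        super().__init__()
        h = cfg.lstm_hidden
        self.hidden = h
        for tag in ("f", "b"):
            self._params[f"lstm_{tag}.Wx"] = Tensor(
                _dense_init(rng, d_in, 4 * h), requires_grad=True)
            self._params[f"lstm_{tag}.Wh"] = Tensor(
                _dense_init(rng, h, 4 * h), requires_grad=True)
            bias = np.zeros(4 * h)
            bias[h : 2 * h] = 1.0  # forget-gate bias
            self._params[f"lstm_{tag}.b"] = Tensor(bias, requires_grad=True)
        self.d_out = 2 * h

    def _run(self, x: Tensor, tag: str) -> Tensor:
        Wx = self._params[f"lstm_{tag}.Wx"]
        Wh = self._params[f"lstm_{tag}.Wh"]
        b = self._params[f"lstm_{tag}.b"]
        B, L, _ = x.shape
        h_dim = self.hidden
        h = Tensor(np.zeros((B, h_dim)))
        c = Tensor(np.zeros((B, h_dim)))
        outs = []
        for t in range(L):
            a = x[:, t, :] @ Wx + h @ Wh + b
            i = ad.sigmoid(a[:, :h_dim])
            f = ad.sigmoid(a[:, h_dim : 2 * h_dim])
            g = ad.tanh(a[:, 2 * h_dim : 3 * h_dim])
            o = ad.sigmoid(a[:, 3 * h_dim :])
            c = f * c + i * g
            h = o * ad.tanh(c)
            outs.append(h.reshape(B, 1, h_dim))
        return ad.concat(outs, axis=1)

    @staticmethod
    def _reverse_index(lengths: np.ndarray, L: int) -> np.ndarray:
        idx = np.tile(np.arange(L), (len(lengths), 1))
        for b, Lb in enumerate(lengths):
            idx[b, :Lb] = Lb - 1 - np.arange(Lb)
        return idx

    def __call__(self, x: Tensor, lengths: np.ndarray) -> Tensor:
        fwd = self._run(x, "f")
        rev_idx = self._reverse_index(np.asarray(lengths, dtype=np.intp), x.shape[1])
        bwd = ad.gather_rows(self._run(ad.gather_rows(x, rev_idx), "b"), rev_idx)
        return ad.concat([fwd, bwd], axis=-1)


class Backbone(Layer):
    """Input projection -> Transformer -> CNN -> BiLSTM -> emission head.

    Any of the three middle stages can be disabled (ablation); the
    emission head always maps the last active stage's width to K.
    """

    def __init__(
        self,
        rng: np.random.Generator,
        cfg: BackboneConfig,
        d_in: int,
        use_transformer: bool = True,
        use_cnn: bool = True,
        use_bilstm: bool = True,
    ):
        super().__init__()
        self.cfg = cfg
        self.project = Linear(rng, d_in, cfg.d_model, name="project")
        self._params.update(self.project.named_parameters())
        width = cfg.d_model
        self.transformer = TransformerEncoder(rng, cfg) if use_transformer else None
        if self.transformer:
            self._params.update(self.transformer.named_parameters())
        self.conv = ConvStack(rng, cfg, width) if use_cnn else None
        if self.conv:
            self._params.update(self.conv.named_parameters())
            width = self.conv.d_out
        self.bilstm = BiLSTM(rng, cfg, width) if use_bilstm else None
        if self.bilstm:
            self._params.update(self.bilstm.named_parameters())
            width = self.bilstm.d_out
        self.head = Linear(rng, width, cfg.emission_dim, name="emission")
        # small head init keeps initial emissions near zero -> near-uniform model
        self.head.W.data *= 0.01
        self._params.update(self.head.named_parameters())

    def __call__(self, features, lengths: np.ndarray, *,
                 training: bool = False, rng=None) -> Tensor:
        """Map padded features (B, L, D_in) to emission scores (B, L, K)."""
        lengths = np.asarray(lengths, dtype=np.intp)
        B, L, _ = features.shape
        mask = (np.arange(L)[None, :] < lengths[:, None]).astype(np.float64)
        x = self.project(ad.astensor(features))
        x = x * mask[:, :, None]
        if self.transformer:
            x = self.transformer(x, mask, training=training, rng=rng)
            x = x * mask[:, :, None]
        if self.conv:
            x = self.conv(x, mask, training=training, rng=rng)
        if self.bilstm:
            x = x * mask[:, :, None]
            x = self.bilstm(x, lengths)
        return self.head(x)
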