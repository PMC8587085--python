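"""Channel-attention deep regression network for insole sensor windows.

The forward model is a composition of four stages:

1. **Channel-wise attention** — ``O = sigmoid(S_in @ W_in + b_in)`` with
   ``S_in`` a (t x i) window; the attention vector ``Att`` is the time average
   of ``O`` and the reweighted signal is ``S_att = Att (x) S_in`` (channel-wise
   product). ``Att`` lies strictly in (0, 1) and is the quantity later used to
   rank sensors.
2. **1-D DenseNet** — a stem convolution followed by dense blocks in which
   every layer's output is concatenated with its input along the channel axis;
   transition layers compress channels and average-pool time. No global
   pooling at the end: the output is a (T x c1) feature sequence.
3. **Bi-GRU** — a gated recurrent unit run forward and backward over the
   feature sequence; per-step hidden states of the two directions are
   concatenated (width c2 = 2 x hidden).
4. **GAP head** — the prediction is the time average of the per-step linear
   readout, ``mean_t(h_t @ W_out + b_out)``.

The attention layer can be bypassed (ablation arm); forcing the attention
vector to all-ones is exactly equivalent to the bypass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .channels import N_CHANNELS
from .nn.autodiff import Tensor, avg_pool1d, concat, gru_sequence
from .nn.layers import BatchNorm1d, Conv1d, Linear, Module, uniform_fan_in


# ---------------------------------------------------------------------------
# Configuration and closed-form shape arithmetic
# ---------------------------------------------------------------------------

@dataclass
class DenseNetConfig:
    """Shape of the 1-D DenseNet feature extractor.

    The default (3 blocks of 4 layers, growth 12, compression 0.5, stem
    kernel 7 stride 2, stride-2 average pooling at each of the two
    transitions) is the smallest standard DenseNet that keeps T >= 20 for a
    333-sample window.
    """

    n_blocks: int = 3
    layers_per_block: int = 4
    growth_rate: int = 12
    kernel_size: int = 3
    initial_channels: int = 24
    compression: float = 0.5
    stem_kernel: int = 7
    stem_stride: int = 2
    pool_kernel: int = 2
    pool_stride: int = 2

    def __post_init__(self) -> None:
        for name in ("n_blocks", "layers_per_block", "growth_rate", "kernel_size",
                     "initial_channels", "stem_kernel", "stem_stride",
                     "pool_kernel", "pool_stride"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not 0 < self.compression <= 1:
            raise ValueError("compression must be in (0, 1]")


def feature_channels(config: DenseNetConfig) -> int:
    """c1: output channel count implied by concatenative growth + compression."""
    c = config.initial_channels
    for block in range(config.n_blocks):
        c += config.layers_per_block * config.growth_rate
        if block < config.n_blocks - 1:
            c = int(np.floor(c * config.compression))
    return c


def temporal_length(t: int, config: DenseNetConfig) -> int:
    """T: time length after the stem stride and the transition poolings.

    Raises ValueError (stating the minimum t) when the window is too short
    for the pooling chain.
    """
    pad = config.stem_kernel // 2
    L = (t + 2 * pad - config.stem_kernel) // config.stem_stride + 1
    for _ in range(config.n_blocks - 1):
        L = (L - config.pool_kernel) // config.pool_stride + 1
    if L < 1:
        raise ValueError(
            f"window of {t} samples too short for the pooling chain; "
            f"minimum is {min_input_length(config)} samples"
        )
    return L


def min_input_length(config: DenseNetConfig) -> int:
    """Smallest window length (samples) the pooling chain accepts."""
    for t in range(1, 10_000):
        pad = config.stem_kernel // 2
        L = (t + 2 * pad - config.stem_kernel) // config.stem_stride + 1
        ok = L >= 1
        for _ in range(config.n_blocks - 1):
            L = (L - config.pool_kernel) // config.pool_stride + 1
            ok = ok and L >= 1
        if ok:
            return t
    raise ValueError("no valid input length below 10000 samples")


# ---------------------------------------------------------------------------
# Parameter containers for the functional, single-window API
# ---------------------------------------------------------------------------

@dataclass
class AttentionLayerParams:
    """Trainable attention-layer weights: W_in (i x i) and per-channel bias.

    The bias is one value per channel broadcast over time, which keeps the
    layer independent of the window length.
    """

    w_in: np.ndarray
    b_in: np.ndarray

    def __post_init__(self) -> None:
        self.w_in = np.asarray(self.w_in, dtype=float)
        self.b_in = np.asarray(self.b_in, dtype=float)
        i = self.w_in.shape[0]
        if self.w_in.shape != (i, i) or self.b_in.shape != (i,):
            raise ValueError("attention params must be (i, i) and (i,)")


@dataclass
class AttentionOutput:
    """o = sigmoid(S_in W + b) (t x i); att = time-mean of o; s_att = att (x) S_in."""

    o: np.ndarray
    att: np.ndarray
    s_att: np.ndarray


@dataclass
class GruParams:
    """Gate weights acting on the concatenation [h_prev, x] (no gate biases)."""

    w_r: np.ndarray
    w_z: np.ndarray
    w_h: np.ndarray

    @property
    def hidden_size(self) -> int:
        return self.w_r.shape[1]


@dataclass
class HeadParams:
    w_out: np.ndarray  # (c2,)
    b_out: float


def attention_forward(s_in: np.ndarray, params: AttentionLayerParams) -> AttentionOutput:
    """Channel-wise attention on a single (t x i) window."""
    s_in = np.asarray(s_in, dtype=float)
    if s_in.ndim != 2 or s_in.shape[1] != params.w_in.shape[0]:
        raise ValueError(
            f"s_in shape {s_in.shape} incompatible with W_in {params.w_in.shape}"
        )
    if not np.isfinite(s_in).all():
        raise ValueError("s_in contains non-finite values")
    o = 1.0 / (1.0 + np.exp(-(s_in @ params.w_in + params.b_in)))
    att = o.mean(axis=0)
    return AttentionOutput(o=o, att=att, s_att=att * s_in)


def gru_step(x_t: np.ndarray, h_prev: np.ndarray, params: GruParams) -> np.ndarray:
    """One GRU update: gates on [h_prev, x], convex blend of old and candidate."""
    x_t = np.asarray(x_t, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    hx = np.concatenate([h_prev, x_t])
    r = 1.0 / (1.0 + np.exp(-(hx @ params.w_r)))
    z = 1.0 / (1.0 + np.exp(-(hx @ params.w_z)))
    h_cand = np.tanh(np.concatenate([r * h_prev, x_t]) @ params.w_h)
    return (1.0 - z) * h_prev + z * h_cand


def bigru_forward(f_dense: np.ndarray, fwd: GruParams, bwd: GruParams) -> np.ndarray:
    """Bidirectional GRU over a (T x c1) sequence -> (T x 2h) hidden sequence."""
    f_dense = np.asarray(f_dense, dtype=float)
    T = f_dense.shape[0]
    h = fwd.hidden_size

    def run(seq: np.ndarray, params: GruParams) -> np.ndarray:
        state = np.zeros(h)
        out = np.empty((len(seq), h))
        for t, x_t in enumerate(seq):
            state = gru_step(x_t, state, params)
            out[t] = state
        return out

    forward = run(f_dense, fwd)
    backward = run(f_dense[::-1], bwd)[::-1]
    return np.concatenate([forward, backward], axis=1)


def gap_head(f_bigru: np.ndarray, head: HeadParams) -> float:
    """Prediction = time average of the per-step linear readout."""
    f_bigru = np.asarray(f_bigru, dtype=float)
    return float((f_bigru @ head.w_out + head.b_out).mean())


# ---------------------------------------------------------------------------
# Trainable modules (batched, differentiable)
# ---------------------------------------------------------------------------

class ChannelAttention(Module):
    def __init__(self, rng: np.random.Generator, n_channels: int = N_CHANNELS):
        super().__init__()
        self.w_in = self.param("w_in", uniform_fan_in(rng, (n_channels, n_channels),
                                                      n_channels))
        self.b_in = self.param("b_in", np.zeros(n_channels))

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """x (B, t, i) -> (s_att (B, t, i), att (B, i))."""
        o = (x @ self.w_in + self.b_in).sigmoid()
        att = o.mean(axis=1)  # (B, i)
        B, _, i = x.shape
        s_att = att.reshape(B, 1, i) * x
        return s_att, att


class _DenseLayer(Module):
    """Pre-activation BN -> ReLU -> conv(kernel, growth); output concatenated."""

    def __init__(self, rng, in_ch: int, growth: int, kernel: int):
        super().__init__()
        self.bn = self.add_module("bn", BatchNorm1d(in_ch))
        self.conv = self.add_module(
            "conv", Conv1d(rng, in_ch, growth, kernel, pad=kernel // 2)
        )

    def forward(self, x: Tensor) -> Tensor:
        new = self.conv.forward(self.bn.forward(x).relu())
        return concat([x, new], axis=1)


class _Transition(Module):
    """BN -> ReLU -> 1-wide conv (channel compression) -> average pool."""

    def __init__(self, rng, in_ch: int, out_ch: int, pool_kernel: int, pool_stride: int):
        super().__init__()
        self.bn = self.add_module("bn", BatchNorm1d(in_ch))
        self.conv = self.add_module("conv", Conv1d(rng, in_ch, out_ch, 1))
        self.pool_kernel, self.pool_stride = pool_kernel, pool_stride

    def forward(self, x: Tensor) -> Tensor:
        x = self.conv.forward(self.bn.forward(x).relu())
        return avg_pool1d(x, self.pool_kernel, self.pool_stride)


class DenseNet1d(Module):
    """1-D DenseNet feature extractor without a final global pooling."""

    def __init__(self, rng, in_channels: int, config: DenseNetConfig):
        super().__init__()
        self.config = config
        c = config.initial_channels
        self.stem = self.add_module(
            "stem",
            Conv1d(rng, in_channels, c, config.stem_kernel,
                   stride=config.stem_stride, pad=config.stem_kernel // 2),
        )
        for b in range(config.n_blocks):
            for l in range(config.layers_per_block):
                self.add_module(f"block{b}_layer{l}",
                                _DenseLayer(rng, c, config.growth_rate,
                                            config.kernel_size))
                c += config.growth_rate
            if b < config.n_blocks - 1:
                out_ch = int(np.floor(c * config.compression))
                self.add_module(f"transition{b}",
                                _Transition(rng, c, out_ch,
                                            config.pool_kernel, config.pool_stride))
                c = out_ch
        self.final_bn = self.add_module("final_bn", BatchNorm1d(c))
        self.out_channels = c

    def forward(self, x: Tensor) -> Tensor:
        """x (B, C, L) -> feature sequence (B, c1, T)."""
        temporal_length(x.shape[2], self.config)  # raises if too short
        cfg = self.config
        h = self.stem.forward(x)
        for b in range(cfg.n_blocks):
            for l in range(cfg.layers_per_block):
                h = self._modules[f"block{b}_layer{l}"].forward(h)
            if b < cfg.n_blocks - 1:
                h = self._modules[f"transition{b}"].forward(h)
        return self.final_bn.forward(h).relu()


class _GruDirection(Module):
    def __init__(self, rng, input_size: int, hidden_size: int):
        super().__init__()
        self.h = hidden_size
        n = hidden_size + input_size
        self.w_r = self.param("w_r", uniform_fan_in(rng, (n, hidden_size), n))
        self.w_z = self.param("w_z", uniform_fan_in(rng, (n, hidden_size), n))
        self.w_h = self.param("w_h", uniform_fan_in(rng, (n, hidden_size), n))

    def forward(self, x: Tensor, reverse: bool = False) -> Tensor:
        """x (B, T, c) -> hidden sequence (B, T, h), in input time order."""
        return gru_sequence(x, self.w_r, self.w_z, self.w_h, reverse=reverse)


class BiGRU(Module):
    def __init__(self, rng, input_size: int, hidden_size: int):
        super().__init__()
        self.fwd = self.add_module("fwd", _GruDirection(rng, input_size, hidden_size))
        self.bwd = self.add_module("bwd", _GruDirection(rng, input_size, hidden_size))
        self.out_size = 2 * hidden_size

    def forward(self, x: Tensor) -> Tensor:
        """x (B, T, c1) -> (B, T, 2h): forward (+) backward per aligned step."""
        f = self.fwd.forward(x)
        b = self.bwd.forward(x, reverse=True)
        return concat([f, b], axis=2)

    def mean_hidden(self, x: Tensor) -> Tensor:
        """Time average of the hidden sequence, (B, 2h)."""
        return self.forward(x).mean(axis=1)


class EstimatorNet(Module):
    """Full attention -> DenseNet -> Bi-GRU -> GAP regression model."""

    def __init__(
        self,
        seed: int = 0,
        n_channels: int = N_CHANNELS,
        densenet: DenseNetConfig | None = None,
        hidden_size: int = 32,
        attention_enabled: bool = True,
        n_outputs: int = 1,
    ):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.seed = seed
        self.n_channels = n_channels
        self.attention_enabled = attention_enabled
        self.densenet_config = densenet or DenseNetConfig()
        self.attention = self.add_module("attention", ChannelAttention(rng, n_channels))
        self.densenet = self.add_module(
            "densenet", DenseNet1d(rng, n_channels, self.densenet_config)
        )
        self.bigru = self.add_module(
            "bigru", BiGRU(rng, self.densenet.out_channels, hidden_size)
        )
        self.head = self.add_module(
            "head", Linear(rng, self.bigru.out_size, n_outputs)
        )
        self.hidden_size = hidden_size
        self.n_outputs = n_outputs

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor | None]:
        """x (B, t, i) -> (predictions (B,) or (B, n_outputs), att (B, i) | None)."""
        if x.shape[2] != self.n_channels:
            raise ValueError(
                f"expected {self.n_channels} channels, got {x.shape[2]}"
            )
        att = None
        if self.attention_enabled:
            x, att = self.attention.forward(x)
        feats = self.densenet.forward(x.transpose(0, 2, 1))  # (B, c1, T)
        pooled = self.bigru.mean_hidden(feats.transpose(0, 2, 1))  # GAP over time
        pred = self.head.forward(pooled)  # linear readout
        if self.n_outputs == 1:
            pred = pred.reshape(pred.shape[0])
        return pred, att


def model_forward(
    model: EstimatorNet, s_in: np.ndarray
) -> tuple[np.ndarray, np.ndarray | None]:
    """Single-window forward pass (evaluation mode); returns (prediction, att)."""
    s_in = np.asarray(s_in, dtype=float)
    if s_in.ndim != 2:
        raise ValueError("s_in must be a (t x i) matrix")
    was_training = model.training
    model.set_training(False)
    try:
        pred, att = model.forward(Tensor(s_in[None]))
    finally:
        model.set_training(was_training)
    return pred.data.reshape(-1)[0], None if att is None else att.data[0]


def extract_attention_weights(model: EstimatorNet, windows) -> np.ndarray:
    """Attention vectors for a list of windows -> (n_windows, 20) matrix.

    Column means are the per-sensor average attention weights used by the
    sensor-ranking analysis. Works whether or not the model's downstream
    stages use attention (the attention layer itself is always evaluated).
    """
    from .preprocessing import WindowedSample  # local import avoids a cycle

    mats = []
    for w in windows:
        s_in = w.s_in if isinstance(w, WindowedSample) else np.asarray(w, dtype=float)
        _, att = model.attention.forward(Tensor(s_in[None]))
        mats.append(att.data[0])
    return np.array(mats).reshape(len(mats), model.n_channels)


def densenet1d_forward(s_att: np.ndarray, net: DenseNet1d) -> np.ndarray:
    """Single-window DenseNet features: (t x i) -> (T x c1) sequence."""
    s_att = np.asarray(s_att, dtype=float)
    was_training = net.training
    net.set_training(False)
    try:
        out = net.forward(Tensor(s_att.T[None]))
    finally:
        net.set_training(was_training)
    return out.data[0].T
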