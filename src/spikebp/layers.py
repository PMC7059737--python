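"""Spiking network layers: convolution, average pooling, fully connected,
spiking dropout, and residual blocks.

Each layer consumes a binary spike tensor of shape ``(T, B, ...)`` (time,
batch, units), runs its internal LIF/IF dynamics over the full window, and
emits the output spike tensor.  Alongside the forward pass every trainable
layer records the time-summed quantities the single backward pass needs:
the total input spike count per pre-unit (``x``), the total input current
per post-unit (``net``), and the output spike train from which the
post-unit spike counts and the leak-corrected activation derivative are
computed.

Spiking dropout draws one random unit mask per iteration and holds it
fixed across all T time steps; masks are applied to a layer's input spikes
(scaled by 1/(1-p)) during training only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .lif import NeuronParams

__all__ = [
    "DropoutConfig",
    "ConvLayer",
    "FCLayer",
    "OutputLayer",
    "AvgPoolLayer",
    "FlattenLayer",
    "ResidualBlock",
    "apply_dropout",
    "conv2d",
    "conv2d_input_grad",
    "conv2d_weight_grad",
    "avgpool_forward",
]

POOL_WEIGHT = 0.25
POOL_THRESHOLD = 0.75


# ---------------------------------------------------------------------------
# dense 2-D correlation primitives (batch, channel, height, width)
# ---------------------------------------------------------------------------

def _pad(x: np.ndarray, padding: int) -> np.ndarray:
    if padding == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))


def conv2d(x: np.ndarray, w: np.ndarray, stride: int = 1, padding: int = 0) -> np.ndarray:
    """Cross-correlate ``x`` (B, C, H, W) with kernels ``w`` (K, C, kh, kw)."""
    kh, kw = w.shape[2], w.shape[3]
    xp = _pad(np.asarray(x, dtype=np.float64), padding)
    if xp.shape[2] < kh or xp.shape[3] < kw:
        raise ValueError("input smaller than kernel")
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    return np.einsum("bchwij,kcij->bkhw", win, w, optimize=True)


def conv2d_input_grad(
    delta: np.ndarray, w: np.ndarray, input_hw: tuple[int, int],
    stride: int = 1, padding: int = 0,
) -> np.ndarray:
    """Adjoint of :func:`conv2d` with respect to the input (full correlation)."""
    B, K, Ho, Wo = delta.shape
    _, C, kh, kw = w.shape
    H, W = input_hw
    dxp = np.zeros((B, C, H + 2 * padding, W + 2 * padding))
    for i in range(kh):
        for j in range(kw):
            contrib = np.einsum("bkhw,kc->bchw", delta, w[:, :, i, j], optimize=True)
            dxp[:, :, i : i + Ho * stride : stride, j : j + Wo * stride : stride] += contrib
    if padding:
        dxp = dxp[:, :, padding:-padding, padding:-padding]
    return dxp


def conv2d_weight_grad(
    x: np.ndarray, delta: np.ndarray, kernel_hw: tuple[int, int],
    stride: int = 1, padding: int = 0,
) -> np.ndarray:
    """Adjoint of :func:`conv2d` with respect to the kernel weights."""
    kh, kw = kernel_hw
    xp = _pad(np.asarray(x, dtype=np.float64), padding)
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    return np.einsum("bkhw,bchwij->kcij", delta, win, optimize=True)


def conv_output_hw(h: int, w: int, kh: int, kw: int, stride: int, padding: int) -> tuple[int, int]:
    return ((h + 2 * padding - kh) // stride + 1, (w + 2 * padding - kw) // stride + 1)


# ---------------------------------------------------------------------------
# spiking dropout
# ---------------------------------------------------------------------------

@dataclass
class DropoutConfig:
    """Spiking-dropout settings: omission probability and per-iteration mask.

    The binary keep-mask is drawn once per training iteration (before the
    first time step) and reused for every forward step of that iteration.
    """

    p: float = 0.0
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p < 1.0:
            raise ValueError(f"dropout probability must lie in [0, 1), got {self.p}")

    @property
    def scale(self) -> float:
        return 1.0 / (1.0 - self.p)

    def draw_mask(self, shape: tuple[int, ...], rng: np.random.Generator) -> None:
        self.mask = (rng.random(shape) >= self.p).astype(np.float64)


def apply_dropout(values: np.ndarray, cfg: DropoutConfig, training: bool) -> np.ndarray:
    """Mask and rescale unit values; identity at inference or when p = 0."""
    if not training or cfg.p == 0.0:
        return values
    if cfg.mask is None:
        raise RuntimeError("dropout mask not drawn for this iteration")
    return values * (cfg.mask * cfg.scale)


# ---------------------------------------------------------------------------
# shared LIF population helper used inside layers
# ---------------------------------------------------------------------------

class _Population:
    """Vectorized LIF population stepped once per time step inside a layer."""

    def __init__(self, params: NeuronParams):
        self.params = params

    def begin(self, shape: tuple[int, ...], T: int) -> None:
        self.v = np.zeros(shape)
        self.out = np.zeros((T,) + shape, dtype=np.int8)
        self.net_sum = np.zeros(shape)
        self._t = 0

    def step(self, current: np.ndarray) -> np.ndarray:
        self.v = self.v + current
        self.net_sum += current
        spikes = self.v > self.params.v_th
        self.v = np.where(spikes, 0.0, self.v * self.params.decay)
        s = spikes.astype(np.int8)
        self.out[self._t] = s
        self._t += 1
        return s

    def spike_counts(self) -> np.ndarray:
        return self.out.astype(np.int64).sum(axis=0)


def _pseudo_derivative(out_spikes: np.ndarray, params: NeuronParams) -> np.ndarray:
    """Leak-corrected straight-through derivative from a recorded spike train.

    See :func:`spikebp.backprop.lif_pseudo_derivative` for the formula; this
    is the vectorized form evaluated from the (T, B, ...) output train.
    """
    T = out_spikes.shape[0]
    gamma = out_spikes.astype(np.float64).sum(axis=0)
    if params.leak_enabled and not math.isinf(params.tau_m):
        decay_w = np.exp(-(T - np.arange(1, T + 1)) / params.tau_m)
        trace = np.tensordot(decay_w, out_spikes.astype(np.float64), axes=([0], [0]))
        f_prime = -trace / params.tau_m
    else:
        f_prime = np.zeros_like(gamma)
    with np.errstate(divide="ignore", invalid="ignore"):
        val = (1.0 + np.where(gamma > 0, f_prime / np.where(gamma > 0, gamma, 1.0), 0.0))
    val = val / params.v_th
    val = np.where(gamma > 0, val, 0.0)
    return np.clip(val, 0.0, 1.0 / params.v_th)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Layer:
    """Base class; non-trainable, stateless between iterations."""

    trainable = False

    def begin_iteration(self, rng: np.random.Generator | None, training: bool) -> None:
        """Reset per-iteration state; trainable layers draw dropout masks."""

    def forward(self, spikes: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_units(self) -> int:
        """Number of output units (post-neurons), if defined for the layer."""
        raise NotImplementedError


class _TrainableLayer(Layer):
    trainable = True

    def __init__(self, params: NeuronParams, dropout_p: float = 0.0):
        self.params = params
        self.dropout = DropoutConfig(p=dropout_p)
        self.pop = _Population(params)
        self.grad_w: np.ndarray | None = None
        self._training = False
        self._pending_rng: np.random.Generator | None = None

    def begin_iteration(self, rng, training):
        self._training = training
        if training and self.dropout.p > 0.0:
            if rng is None:
                raise ValueError("training with dropout requires an RNG")
            self._pending_rng = rng  # mask drawn at forward once input shape is known
        else:
            self._pending_rng = None

    def _ensure_mask(self, input_shape: tuple[int, ...]) -> None:
        if self._pending_rng is not None:
            self.dropout.draw_mask(input_shape, self._pending_rng)
            self._pending_rng = None

    def _masked(self, spikes_t: np.ndarray) -> np.ndarray:
        return apply_dropout(spikes_t.astype(np.float64), self.dropout, self._training)

    def _mask_grad(self, g_in: np.ndarray) -> np.ndarray:
        if self._training and self.dropout.p > 0.0:
            g_in = g_in * (self.dropout.mask * self.dropout.scale)
        return g_in

    def pseudo_derivative(self) -> np.ndarray:
        return _pseudo_derivative(self.pop.out, self.params)


class ConvLayer(_TrainableLayer):
    """Spiking convolutional layer: per-step correlation followed by LIF units."""

    def __init__(
        self,
        weights: np.ndarray,
        stride: int = 1,
        padding: int = 0,
        params: NeuronParams = NeuronParams(),
        dropout_p: float = 0.0,
    ):
        super().__init__(params, dropout_p)
        self.w = np.asarray(weights, dtype=np.float64)
        if self.w.ndim != 4:
            raise ValueError("conv weights must be (out, in, kh, kw)")
        self.stride = stride
        self.padding = padding
        self._out_hw: tuple[int, int] | None = None
        self._in_hw: tuple[int, int] | None = None

    def forward(self, spikes, training=False):
        T, B, C, H, W = spikes.shape
        if C != self.w.shape[1]:
            raise ValueError(f"expected {self.w.shape[1]} input channels, got {C}")
        self._in_hw = (H, W)
        self._ensure_mask((C, H, W))
        kh, kw = self.w.shape[2:]
        self._out_hw = conv_output_hw(H, W, kh, kw, self.stride, self.padding)
        self.pop.begin((B, self.w.shape[0]) + self._out_hw, T)
        self.x_sum = np.zeros((B, C, H, W))
        for t in range(T):
            xin = self._masked(spikes[t])
            self.x_sum += xin
            current = conv2d(xin, self.w, self.stride, self.padding)
            self.pop.step(current)
        return self.pop.out

    def backward(self, g_out):
        delta = g_out * self.pseudo_derivative()
        B = delta.shape[0]
        self.grad_w = conv2d_weight_grad(
            self.x_sum, delta, self.w.shape[2:], self.stride, self.padding
        ) / B
        g_in = conv2d_input_grad(delta, self.w, self._in_hw, self.stride, self.padding)
        return self._mask_grad(g_in)

    @property
    def n_units(self) -> int:
        if self._out_hw is None:
            raise RuntimeError("layer has not been run forward yet")
        return self.w.shape[0] * self._out_hw[0] * self._out_hw[1]


class FCLayer(_TrainableLayer):
    """Spiking fully connected layer; weights shape (n_out, n_in)."""

    def __init__(
        self,
        weights: np.ndarray,
        params: NeuronParams = NeuronParams(),
        dropout_p: float = 0.0,
    ):
        super().__init__(params, dropout_p)
        self.w = np.asarray(weights, dtype=np.float64)
        if self.w.ndim != 2:
            raise ValueError("fc weights must be (n_out, n_in)")

    def forward(self, spikes, training=False):
        T, B, n_in = spikes.shape
        if n_in != self.w.shape[1]:
            raise ValueError(f"expected {self.w.shape[1]} inputs, got {n_in}")
        self._ensure_mask((n_in,))
        self.pop.begin((B, self.w.shape[0]), T)
        self.x_sum = np.zeros((B, n_in))
        for t in range(T):
            xin = self._masked(spikes[t])
            self.x_sum += xin
            self.pop.step(xin @ self.w.T)
        return self.pop.out

    def backward(self, g_out):
        delta = g_out * self.pseudo_derivative()
        self.grad_w = np.einsum("bo,bi->oi", delta, self.x_sum) / delta.shape[0]
        return self._mask_grad(delta @ self.w)

    @property
    def n_units(self) -> int:
        return self.w.shape[0]


class OutputLayer(FCLayer):
    """Final classification layer: non-spiking (infinite threshold) leaky
    accumulator whose activation is ``V_mem(T) / T``.

    The backward derivative of the activation with respect to the total
    input current is taken as ``1/T`` (the accumulated potential is treated
    as the total current, the leak being regarded as noise).
    """

    def __init__(self, weights: np.ndarray, params: NeuronParams | None = None,
                 dropout_p: float = 0.0):
        if params is None:
            params = NeuronParams(v_th=math.inf, tau_m=100.0)
        if not math.isinf(params.v_th):
            raise ValueError("output layer must use the infinite-threshold sentinel")
        super().__init__(weights, params, dropout_p)

    def forward(self, spikes, training=False):
        super().forward(spikes, training)
        self.T = spikes.shape[0]
        self.output = self.pop.v / self.T
        return self.output

    def backward(self, e):
        delta = e / self.T
        self.grad_w = np.einsum("bo,bi->oi", delta, self.x_sum) / delta.shape[0]
        return self._mask_grad(delta @ self.w)


class AvgPoolLayer(Layer):
    """Thresholded 2x2 average pooling over non-overlapping windows.

    Each input spike contributes a fixed weight of 0.25 to a leak-free
    accumulator; the pooled unit fires when the accumulated value strictly
    exceeds 0.75 and then resets to zero, otherwise the residue carries to
    the next time step.
    """

    def __init__(self, threshold: float = POOL_THRESHOLD) -> None:
        self.threshold = threshold
        self._shape: tuple[int, ...] | None = None

    def forward(self, spikes, training=False):
        T, B, C, H, W = spikes.shape
        if H % 2 or W % 2:
            raise ValueError("average pooling requires even spatial dimensions")
        self._shape = (B, C, H, W)
        acc = np.zeros((B, C, H // 2, W // 2))
        out = np.zeros((T, B, C, H // 2, W // 2), dtype=np.int8)
        pooled_in = spikes.astype(np.float64).reshape(T, B, C, H // 2, 2, W // 2, 2)
        pooled_in = pooled_in.sum(axis=(4, 6)) * POOL_WEIGHT
        for t in range(T):
            acc = acc + pooled_in[t]
            fired = acc > self.threshold
            out[t] = fired
            acc = np.where(fired, 0.0, acc)
        self.out = out
        self.residue = acc
        return out

    def backward(self, g_out):
        # fixed 0.25 linear map with unit activation derivative
        B, C, Ho, Wo = g_out.shape
        g_in = np.repeat(np.repeat(g_out, 2, axis=2), 2, axis=3) * POOL_WEIGHT
        return g_in

    @property
    def n_units(self) -> int:
        if self._shape is None:
            raise RuntimeError("layer has not been run forward yet")
        B, C, H, W = self._shape
        return C * (H // 2) * (W // 2)


def avgpool_forward(spikes: np.ndarray, pool_threshold: float = POOL_THRESHOLD):
    """Functional form of :class:`AvgPoolLayer` on a (T, B, C, H, W) train.

    Returns the pooled spike train and the final accumulator residue.
    """
    layer = AvgPoolLayer(threshold=pool_threshold)
    out = layer.forward(spikes)
    return out, layer.residue


class FlattenLayer(Layer):
    """Reshape (T, B, C, H, W) spike maps to (T, B, C*H*W) vectors."""

    def forward(self, spikes, training=False):
        self._spatial = spikes.shape[2:]
        T, B = spikes.shape[:2]
        return spikes.reshape(T, B, -1)

    def backward(self, g_out):
        return g_out.reshape((g_out.shape[0],) + self._spatial)

    @property
    def n_units(self) -> int:
        return int(np.prod(self._spatial))


class ResidualBlock(Layer):
    """Spiking residual block: two stacked convolutions with a skip path.

    The main path is conv1 -> LIF -> conv2; the skip path is the identity
    (when channel counts and stride allow) or a 1x1 convolution.  Both
    paths' currents are integrated into one shared output LIF population,
    and the backward pass sums the adjoints of both paths into the block
    input's gradient.
    """

    trainable = True

    def __init__(
        self,
        w1: np.ndarray,
        w2: np.ndarray,
        w_skip: np.ndarray | None,
        stride: int = 1,
        params: NeuronParams = NeuronParams(),
        dropout_p: float = 0.0,
    ):
        self.w1 = np.asarray(w1, dtype=np.float64)
        self.w2 = np.asarray(w2, dtype=np.float64)
        self.w_skip = None if w_skip is None else np.asarray(w_skip, dtype=np.float64)
        if self.w_skip is None:
            if self.w1.shape[1] != self.w2.shape[0] or stride != 1:
                raise ValueError("identity skip requires matching channels and stride 1")
        self.stride = stride
        self.params = params
        self.pop_mid = _Population(params)
        self.pop_out = _Population(params)
        self.drop_in = DropoutConfig(p=dropout_p)
        self.drop_mid = DropoutConfig(p=dropout_p)
        self.grad_w1 = self.grad_w2 = self.grad_w_skip = None
        self._training = False
        self._pending_rng = None

    def begin_iteration(self, rng, training):
        self._training = training
        self._in_hw = getattr(self, "_in_hw", None)
        if training and self.drop_in.p > 0.0:
            if rng is None:
                raise ValueError("training with dropout requires an RNG")
            self._pending_rng = rng
        else:
            self._pending_rng = None

    def forward(self, spikes, training=False):
        T, B, C, H, W = spikes.shape
        kh1, kw1 = self.w1.shape[2:]
        mid_hw = conv_output_hw(H, W, kh1, kw1, 1, 1)
        kh2, kw2 = self.w2.shape[2:]
        out_hw = conv_output_hw(*mid_hw, kh2, kw2, self.stride, 1)
        if self._pending_rng is not None:
            self.drop_in.draw_mask((C, H, W), self._pending_rng)
            self.drop_mid.draw_mask((self.w1.shape[0],) + mid_hw, self._pending_rng)
            self._pending_rng = None
        self._in_hw, self._mid_hw, self._out_hw = (H, W), mid_hw, out_hw
        self.pop_mid.begin((B, self.w1.shape[0]) + mid_hw, T)
        self.pop_out.begin((B, self.w2.shape[0]) + out_hw, T)
        self.x_sum = np.zeros((B, C, H, W))
        self.mid_sum = np.zeros((B, self.w1.shape[0]) + mid_hw)
        for t in range(T):
            xin = apply_dropout(spikes[t].astype(np.float64), self.drop_in, self._training)
            self.x_sum += xin
            s_mid = self.pop_mid.step(conv2d(xin, self.w1, 1, 1))
            m = apply_dropout(s_mid.astype(np.float64), self.drop_mid, self._training)
            self.mid_sum += m
            current = conv2d(m, self.w2, self.stride, 1)
            if self.w_skip is not None:
                current = current + conv2d(xin, self.w_skip, self.stride, 0)
            else:
                current = current + xin
            self.pop_out.step(current)
        return self.pop_out.out

    def backward(self, g_out):
        B = g_out.shape[0]
        delta_out = g_out * _pseudo_derivative(self.pop_out.out, self.params)
        self.grad_w2 = conv2d_weight_grad(
            self.mid_sum, delta_out, self.w2.shape[2:], self.stride, 1
        ) / B
        g_mid = conv2d_input_grad(delta_out, self.w2, self._mid_hw, self.stride, 1)
        if self._training and self.drop_mid.p > 0.0:
            g_mid = g_mid * (self.drop_mid.mask * self.drop_mid.scale)
        if self.w_skip is not None:
            self.grad_w_skip = conv2d_weight_grad(
                self.x_sum, delta_out, self.w_skip.shape[2:], self.stride, 0
            ) / B
            g_in_skip = conv2d_input_grad(
                delta_out, self.w_skip, self._in_hw, self.stride, 0
            )
        else:
            g_in_skip = delta_out
        delta_mid = g_mid * _pseudo_derivative(self.pop_mid.out, self.params)
        self.grad_w1 = conv2d_weight_grad(self.x_sum, delta_mid, self.w1.shape[2:], 1, 1) / B
        g_in = conv2d_input_grad(delta_mid, self.w1, self._in_hw, 1, 1) + g_in_skip
        if self._training and self.drop_in.p > 0.0:
            g_in = g_in * (self.drop_in.mask * self.drop_in.scale)
        return g_in

    @property
    def n_units(self) -> int:
        return self.w2.shape[0] * self._out_hw[0] * self._out_hw[1]
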