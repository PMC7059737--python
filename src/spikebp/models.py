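"""Architecture presets and network construction for deep spiking models.

Provides the tabulated LeNet-style, VGG-style, and residual spiking
topologies used on the MNIST/SVHN/CIFAR-10-scale benchmarks, the
He-style kappa-scaled Gaussian weight initializer, and a ``SpikingNetwork``
container that wires :mod:`spikebp.layers` components together for one
forward window and one backward pass per iteration.

Conventions: hidden layers use a unit firing threshold, the final layer
uses the infinite-threshold (never-spiking) sentinel; 3x3 kernels use
padding 1 (size-preserving), 5x5 and 1x1 kernels use no padding; units
carry no bias term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .backprop import loss_and_error, sgd_update
from .layers import (
    AvgPoolLayer,
    ConvLayer,
    FCLayer,
    FlattenLayer,
    Layer,
    OutputLayer,
    ResidualBlock,
    conv_output_hw,
)
from .lif import NeuronParams

__all__ = [
    "Conv",
    "Pool",
    "Residual",
    "FC",
    "Output",
    "ArchitectureSpec",
    "InitConfig",
    "init_weights",
    "build",
    "SpikingNetwork",
    "PRESETS",
]


# ---------------------------------------------------------------------------
# layer descriptors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Conv:
    maps: int
    kernel: int = 3
    stride: int = 1

    @property
    def padding(self) -> int:
        # 3x3 kernels preserve spatial size; 5x5 and 1x1 use no padding
        return 1 if self.kernel == 3 else 0


@dataclass(frozen=True)
class Pool:
    pass


@dataclass(frozen=True)
class Residual:
    """Residual block descriptor: conv(in->maps, s1) -> conv(maps->maps,
    stride) with a skip path (1x1 conv, same stride, unless the identity
    applies)."""

    maps: int
    stride: int = 1


@dataclass(frozen=True)
class FC:
    units: int


@dataclass(frozen=True)
class Output:
    units: int = 10


LayerSpec = Conv | Pool | Residual | FC | Output


@dataclass(frozen=True)
class ArchitectureSpec:
    """Ordered layer descriptors plus a name; presets mirror the printed
    benchmark topologies."""

    name: str
    layers: tuple[LayerSpec, ...]
    residual: bool = False

    @property
    def kappa_default(self) -> float:
        return 1.0 if self.residual else 2.0


PRESETS: dict[str, ArchitectureSpec] = {
    # LeNet-derived 4-trainable-layer network (MNIST / N-MNIST scale)
    "lenet-snn": ArchitectureSpec(
        "lenet-snn",
        (
            Conv(20, kernel=5), Pool(),
            Conv(50, kernel=5), Pool(),
            FC(200), Output(10),
        ),
    ),
    "vgg7": ArchitectureSpec(
        "vgg7",
        (
            Conv(64), Conv(64, stride=2), Pool(),
            Conv(128), Conv(128, stride=2), Conv(128, stride=2), Pool(),
            FC(1024), Output(10),
        ),
    ),
    "resnet7": ArchitectureSpec(
        "resnet7",
        (
            Conv(64), Pool(),
            Residual(128, stride=2),
            Residual(256, stride=2),
            FC(1024), Output(10),
        ),
        residual=True,
    ),
    "vgg9": ArchitectureSpec(
        "vgg9",
        (
            Conv(64), Conv(64), Pool(),
            Conv(128), Conv(128), Pool(),
            Conv(256), Conv(256), Conv(256), Pool(),
            FC(1024), Output(10),
        ),
    ),
    "resnet9": ArchitectureSpec(
        "resnet9",
        (
            Conv(64), Pool(),
            Residual(128),
            Residual(256, stride=2),
            Residual(512, stride=2),
            FC(1024), Output(10),
        ),
        residual=True,
    ),
    "resnet11": ArchitectureSpec(
        "resnet11",
        (
            Conv(64), Pool(),
            Residual(128),
            Residual(256, stride=2),
            Residual(512),
            Residual(512, stride=2),
            FC(1024), Output(10),
        ),
        residual=True,
    ),
    # vgg5/vgg6 are depth-study reconstructions (vgg7 truncated by two/one
    # convolutional layers); no canonical layer table exists for them.
    "vgg6": ArchitectureSpec(
        "vgg6",
        (
            Conv(64), Conv(64, stride=2), Pool(),
            Conv(128), Conv(128, stride=2), Pool(),
            FC(1024), Output(10),
        ),
    ),
    "vgg5": ArchitectureSpec(
        "vgg5",
        (
            Conv(64), Conv(64, stride=2), Pool(),
            Conv(128, stride=2), Pool(),
            FC(1024), Output(10),
        ),
    ),
}


# ---------------------------------------------------------------------------
# weight initialization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InitConfig:
    """Gaussian initializer settings: scale constant kappa and RNG seed."""

    kappa: float = 2.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.kappa > 0:
            raise ValueError("kappa must be positive")


def init_weights(
    shape: tuple[int, ...],
    fan_in: int,
    cfg: InitConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw zero-mean Gaussian weights with standard deviation sqrt(kappa/n).

    ``fan_in`` is the number of incoming synapses per unit; no bias term is
    created anywhere in the network.
    """
    if fan_in < 1:
        raise ValueError("fan-in must be >= 1")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    return rng.normal(0.0, math.sqrt(cfg.kappa / fan_in), size=shape)


# ---------------------------------------------------------------------------
# network container
# ---------------------------------------------------------------------------

@dataclass
class SpikingNetwork:
    """An ordered stack of spiking layers ending in a non-spiking output
    layer, trained with one backward pass per forward window."""

    layers: list[Layer]
    spec: ArchitectureSpec | None = None
    T_default: int = 100
    _last_input_counts: np.ndarray | None = field(default=None, repr=False)

    def begin_iteration(self, rng: np.random.Generator | None, training: bool) -> None:
        for layer in self.layers:
            layer.begin_iteration(rng, training)

    def forward(
        self,
        input_spikes: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Run one full window; returns the (B, n_out) output distribution.

        ``input_spikes`` has shape (T, B, C, H, W) or (T, B, N) with values
        in {0, 1} (or {-1, 0, 1} for bipolar input).
        """
        self.begin_iteration(rng, training)
        self._last_input_counts = np.abs(input_spikes.astype(np.int64)).sum()
        x = input_spikes
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x  # OutputLayer returns (B, n_out)

    def backward(self, e: np.ndarray) -> np.ndarray:
        """Single backward pass from the final output error ``e``.

        Populates each trainable layer's weight gradients and returns the
        gradient with respect to the input spike counts.
        """
        g = e
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def train_step(
        self,
        input_spikes: np.ndarray,
        labels_onehot: np.ndarray,
        eta: float,
        rng: np.random.Generator | None = None,
    ) -> tuple[float, np.ndarray]:
        """One iteration: forward window, loss, backward pass, SGD update."""
        out = self.forward(input_spikes, training=True, rng=rng)
        E, e = loss_and_error(out, labels_onehot)
        self.backward(e)
        self.apply_sgd(eta)
        return E, out

    def apply_sgd(self, eta: float) -> None:
        for layer in self.layers:
            if isinstance(layer, ResidualBlock):
                layer.w1 = sgd_update(layer.w1, layer.grad_w1, eta)
                layer.w2 = sgd_update(layer.w2, layer.grad_w2, eta)
                if layer.w_skip is not None:
                    layer.w_skip = sgd_update(layer.w_skip, layer.grad_w_skip, eta)
            elif layer.trainable:
                layer.w = sgd_update(layer.w, layer.grad_w, eta)

    def parameters(self) -> list[np.ndarray]:
        params = []
        for layer in self.layers:
            if isinstance(layer, ResidualBlock):
                params.extend([layer.w1, layer.w2])
                if layer.w_skip is not None:
                    params.append(layer.w_skip)
            elif layer.trainable:
                params.append(layer.w)
        return params

    def gradients(self) -> list[np.ndarray]:
        grads = []
        for layer in self.layers:
            if isinstance(layer, ResidualBlock):
                grads.extend([layer.grad_w1, layer.grad_w2])
                if layer.w_skip is not None:
                    grads.append(layer.grad_w_skip)
            elif layer.trainable:
                grads.append(layer.grad_w)
        return grads

    def set_parameters(self, params: list[np.ndarray]) -> None:
        it = iter(params)
        for layer in self.layers:
            if isinstance(layer, ResidualBlock):
                layer.w1 = next(it)
                layer.w2 = next(it)
                if layer.w_skip is not None:
                    layer.w_skip = next(it)
            elif layer.trainable:
                layer.w = next(it)


def build(
    preset: str | ArchitectureSpec,
    input_dims: tuple[int, int, int],
    init: InitConfig | None = None,
    tau_m: float = 100.0,
    v_th: float = 1.0,
    dropout_p: float = 0.0,
    n_classes: int | None = None,
) -> SpikingNetwork:
    """Instantiate a preset (or custom descriptor list) for given input dims.

    ``input_dims`` is (channels, height, width).  Hidden layers get
    ``NeuronParams(v_th, tau_m)``; the final layer is a non-spiking leaky
    accumulator.  ``n_classes`` overrides the preset's output width.
    """
    if isinstance(preset, str):
        try:
            spec = PRESETS[preset]
        except KeyError:
            raise ValueError(f"unknown preset {preset!r}; known: {sorted(PRESETS)}")
    else:
        spec = preset
    if init is None:
        init = InitConfig(kappa=spec.kappa_default)
    rng = np.random.default_rng(init.seed)
    hidden = NeuronParams(v_th=v_th, tau_m=tau_m)

    C, H, W = input_dims
    layers: list[Layer] = []
    flattened = False
    for d in spec.layers:
        if isinstance(d, Conv):
            fan_in = C * d.kernel * d.kernel
            w = init_weights((d.maps, C, d.kernel, d.kernel), fan_in, init, rng)
            layers.append(ConvLayer(w, stride=d.stride, padding=d.padding,
                                    params=hidden, dropout_p=dropout_p))
            H, W = conv_output_hw(H, W, d.kernel, d.kernel, d.stride, d.padding)
            C = d.maps
        elif isinstance(d, Pool):
            if H % 2 or W % 2:
                raise ValueError(f"odd spatial dims ({H}, {W}) before pooling")
            layers.append(AvgPoolLayer())
            H, W = H // 2, W // 2
        elif isinstance(d, Residual):
            w1 = init_weights((d.maps, C, 3, 3), C * 9, init, rng)
            w2 = init_weights((d.maps, d.maps, 3, 3), d.maps * 9, init, rng)
            if C == d.maps and d.stride == 1:
                w_skip = None
            else:
                w_skip = init_weights((d.maps, C, 1, 1), C, init, rng)
            layers.append(ResidualBlock(w1, w2, w_skip, stride=d.stride,
                                        params=hidden, dropout_p=dropout_p))
            H, W = conv_output_hw(H, W, 3, 3, d.stride, 1)
            C = d.maps
        elif isinstance(d, (FC, Output)):
            if not flattened:
                layers.append(FlattenLayer())
                flattened = True
                n_in = C * H * W
            else:
                n_in = prev_units
            units = d.units
            if isinstance(d, Output) and n_classes is not None:
                units = n_classes
            w = init_weights((units, n_in), n_in, init, rng)
            if isinstance(d, Output):
                layers.append(OutputLayer(w))
            else:
                layers.append(FCLayer(w, params=hidden, dropout_p=dropout_p))
            prev_units = units
        else:
            raise TypeError(f"unknown layer descriptor {d!r}")
    if not isinstance(layers[-1], OutputLayer):
        raise ValueError("architecture must end with an Output descriptor")
    return SpikingNetwork(layers=layers, spec=spec)
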