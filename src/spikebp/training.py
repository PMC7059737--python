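"""Mini-batch training loop, learning-rate schedule, and evaluation.

Each training iteration encodes a mini-batch of images into Poisson spike
trains, runs the network forward over the full window (with the
per-iteration dropout masks held fixed across time), executes one backward
pass at the last time step, and applies one weight update.  The inference
window always equals the training window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .backprop import loss_and_error
from .encoding import EncoderConfig, bipolar_encode, poisson_encode
from .models import SpikingNetwork

__all__ = ["TrainingConfig", "train", "predict", "evaluate", "encode_batch"]


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters for spike-based backpropagation training.

    Defaults follow the benchmark settings: tau_m = 100 steps, a 50-step
    window for MNIST-scale data (100 otherwise), mini-batches of 16,
    learning rate 0.002, dropout 0.2, SGD with 10x learning-rate drops at
    epochs 70/100/125 (40/80/120 for Adam).
    """

    T: int = 50
    batch_size: int = 16
    eta: float = 0.002
    epochs: int = 150
    optimizer: str = "sgd"
    lr_drop_epochs: tuple[int, ...] = (70, 100, 125)
    lr_drop_factor: float = 0.1
    dropout_p: float = 0.2
    bipolar: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 1 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("T, batch_size and epochs must be positive")
        if self.eta < 0:
            raise ValueError("learning rate must be non-negative")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")

    @classmethod
    def adam_defaults(cls, **kw) -> "TrainingConfig":
        return cls(optimizer="adam", lr_drop_epochs=(40, 80, 120), **kw)

    def lr_at_epoch(self, epoch: int) -> float:
        """Stepped learning rate for a 1-based epoch index."""
        drops = sum(1 for d in self.lr_drop_epochs if epoch >= d)
        return self.eta * self.lr_drop_factor**drops


def encode_batch(images: np.ndarray, T: int, rng: np.random.Generator,
                 bipolar: bool = False) -> np.ndarray:
    """Poisson-encode a batch of images into a (T, B, ...) spike tensor."""
    cfg = EncoderConfig(duration=T, mode="bipolar" if bipolar else "unipolar")
    enc = bipolar_encode if bipolar else poisson_encode
    return enc(images, cfg, rng=rng).values


class _Adam:
    """Standard Adam accumulator over the network's parameter list."""

    def __init__(self, shapes, beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params, grads, eta):
        self.t += 1
        out = []
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g**2
            mhat = self.m[i] / (1 - self.beta1**self.t)
            vhat = self.v[i] / (1 - self.beta2**self.t)
            out.append(p - eta * mhat / (np.sqrt(vhat) + self.eps))
        return out


def train(
    network: SpikingNetwork,
    images: np.ndarray,
    labels: np.ndarray,
    cfg: TrainingConfig,
    n_classes: int | None = None,
) -> list[dict]:
    """Train in place; returns the per-epoch history.

    ``images`` are pixel intensities in [0, 1] (or signed intensities in
    [-1, 1] with ``cfg.bipolar``), shaped (N, C, H, W); ``labels`` are
    integer class indices.  History rows record epoch, learning rate, mean
    loss, and training accuracy measured on the training forward passes.
    """
    n = images.shape[0]
    if n == 0:
        raise ValueError("empty data source")
    labels = np.asarray(labels)
    if n_classes is None:
        n_classes = network.layers[-1].w.shape[0]
    rng = np.random.default_rng(cfg.seed)
    adam = (
        _Adam([p.shape for p in network.parameters()])
        if cfg.optimizer == "adam"
        else None
    )
    history: list[dict] = []
    for epoch in range(1, cfg.epochs + 1):
        lr = cfg.lr_at_epoch(epoch)
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            spikes = encode_batch(images[idx], cfg.T, rng, cfg.bipolar)
            onehot = np.eye(n_classes)[labels[idx]]
            out = network.forward(spikes, training=True, rng=rng)
            E, e = loss_and_error(out, onehot)
            if not np.isfinite(E):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: training diverged "
                    "(reduce the learning rate or check the input scaling)"
                )
            network.backward(e)
            if lr > 0:
                if adam is None:
                    network.apply_sgd(lr)
                else:
                    network.set_parameters(
                        adam.step(network.parameters(), network.gradients(), lr)
                    )
            losses.append(E)
            correct += int(np.sum(np.argmax(out, axis=1) == labels[idx]))
        history.append(
            {
                "epoch": epoch,
                "lr": lr,
                "loss": float(np.mean(losses)),
                "train_accuracy": correct / n,
            }
        )
    return history


def predict(
    network: SpikingNetwork,
    image: np.ndarray,
    T: int,
    rng: np.random.Generator | None = None,
    bipolar: bool = False,
) -> int:
    """Classify one image: argmax over the output distribution (ties break
    to the lowest index)."""
    rng = np.random.default_rng(0) if rng is None else rng
    spikes = encode_batch(image[None], T, rng, bipolar)
    out = network.forward(spikes, training=False)
    return int(np.argmax(out[0]))


def evaluate(
    network: SpikingNetwork,
    images: np.ndarray,
    labels: np.ndarray,
    cfg: TrainingConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """Top-1 accuracy with dropout disabled; batched over the data source."""
    if images.shape[0] == 0:
        raise ValueError("empty data source")
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    labels = np.asarray(labels)
    correct = 0
    for start in range(0, images.shape[0], cfg.batch_size):
        batch = images[start : start + cfg.batch_size]
        spikes = encode_batch(batch, cfg.T, rng, cfg.bipolar)
        out = network.forward(spikes, training=False)
        correct += int(np.sum(np.argmax(out, axis=1) == labels[start : start + len(batch)]))
    return correct / images.shape[0]
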