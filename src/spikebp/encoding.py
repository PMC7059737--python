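"""Input spike generation: Poisson rate coding and AER event binning.

Static images are rate-coded: at every time step each pixel's intensity is
compared against an independent uniform random draw in [0, 1] and a spike
is emitted when the intensity is larger, so a pixel of intensity ``p``
produces Binomial(T, p) spikes over a window of T steps.  Color images are
standardized per channel, rescaled to [-1, 1], and encoded as bipolar
(signed) spikes whose per-step magnitude probability is |intensity|.

Event-camera streams (x, y, polarity, timestamp) are binned into a fixed
window of T equal-width time bins per polarity channel, with at most one
spike per (bin, polarity, pixel).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .lif import SpikeTrain

__all__ = [
    "EncoderConfig",
    "EventStream",
    "poisson_encode",
    "normalize_scale",
    "bipolar_encode",
    "bin_events",
]

ON, OFF = 1, 0


@dataclass(frozen=True)
class EncoderConfig:
    """Spike-encoder settings: window length, polarity mode, RNG seed."""

    duration: int = 100
    mode: Literal["unipolar", "bipolar"] = "unipolar"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.duration < 1:
            raise ValueError("duration must be >= 1")
        if self.mode not in ("unipolar", "bipolar"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class EventStream:
    """AER-style event record: arrays x, y, polarity (1=ON, 0=OFF), t (µs)."""

    x: np.ndarray
    y: np.ndarray
    polarity: np.ndarray
    timestamp: np.ndarray
    width: int = 34
    height: int = 34

    def __post_init__(self) -> None:
        x, y = np.asarray(self.x), np.asarray(self.y)
        p, t = np.asarray(self.polarity), np.asarray(self.timestamp)
        n = {x.size, y.size, p.size, t.size}
        if len(n) != 1:
            raise ValueError("event field lengths differ")
        if x.size:
            if x.min() < 0 or x.max() >= self.width or y.min() < 0 or y.max() >= self.height:
                raise ValueError("event coordinates outside sensor dimensions")
            if t.min() < 0:
                raise ValueError("negative event timestamp")
            if not set(np.unique(p).tolist()) <= {ON, OFF}:
                raise ValueError("polarity must be 0 (OFF) or 1 (ON)")
        for name, arr in (("x", x), ("y", y), ("polarity", p), ("timestamp", t)):
            object.__setattr__(self, name, arr.astype(np.int64))

    def __len__(self) -> int:
        return self.x.size


def poisson_encode(
    intensities: np.ndarray,
    config: EncoderConfig,
    rng: np.random.Generator | None = None,
) -> SpikeTrain:
    """Rate-code intensities in [0, 1] into a unipolar Poisson spike train.

    At each of the ``config.duration`` steps a spike is generated wherever
    ``intensity > u`` for an independent ``u ~ Uniform(0, 1)``, so the
    expected spike count per unit is ``intensity * T``.
    """
    intens = np.asarray(intensities, dtype=np.float64)
    if intens.size and (intens.min() < 0 or intens.max() > 1):
        raise ValueError("intensities must lie in [0, 1]")
    rng = config.rng() if rng is None else rng
    u = rng.random(size=(config.duration,) + intens.shape)
    return SpikeTrain((intens > u).astype(np.int8))


def normalize_scale(
    images: np.ndarray,
    mean: np.ndarray | None = None,
    std: np.ndarray | None = None,
    channel_axis: int = 1,
) -> np.ndarray:
    """Standardize per channel and rescale into [-1, 1].

    ``mean``/``std`` are per-channel dataset statistics; when omitted they
    are computed from ``images`` itself.  The z-scores are divided by the
    maximum absolute z-value so the output occupies the full [-1, 1] range.
    """
    images = np.asarray(images, dtype=np.float64)
    axes = tuple(ax for ax in range(images.ndim) if ax != channel_axis)
    if mean is None:
        mean = images.mean(axis=axes, keepdims=True)
    if std is None:
        std = images.std(axis=axes, keepdims=True)
    mean = np.asarray(mean, dtype=np.float64)
    std = np.asarray(std, dtype=np.float64)
    if mean.ndim == 1:
        shape = [1] * images.ndim
        shape[channel_axis] = -1
        mean = mean.reshape(shape)
        std = std.reshape(shape)
    if np.any(std == 0):
        raise ValueError("zero-variance channel: degenerate input")
    z = (images - mean) / std
    peak = np.abs(z).max()
    if peak == 0:
        return z
    return z / peak


def bipolar_encode(
    signed: np.ndarray,
    config: EncoderConfig,
    rng: np.random.Generator | None = None,
) -> SpikeTrain:
    """Encode signed intensities in [-1, 1] as {-1, 0, +1} spike trains.

    A spike of ``sign(v)`` is emitted per step with probability ``|v|``, so
    the magnitude stream is distributed as the unipolar encoding of |v|.
    """
    v = np.asarray(signed, dtype=np.float64)
    if v.size and np.abs(v).max() > 1:
        raise ValueError("signed intensities must lie in [-1, 1]")
    rng = config.rng() if rng is None else rng
    u = rng.random(size=(config.duration,) + v.shape)
    spikes = (np.abs(v) > u) * np.sign(v)
    return SpikeTrain(spikes.astype(np.int8), signed=True)


def bin_events(
    stream: EventStream,
    config: EncoderConfig,
    span: int | None = None,
) -> SpikeTrain:
    """Bin an event stream into a (T, 2, height, width) binary spike tensor.

    The recording span [0, span] (``span`` defaults to the largest event
    timestamp) is divided into ``config.duration`` equal-width bins; a cell
    is 1 iff at least one event of that polarity/pixel falls in the bin
    (binary clipping).  Channel 0 carries OFF events, channel 1 ON events.
    """
    T = config.duration
    out = np.zeros((T, 2, stream.height, stream.width), dtype=np.int8)
    if len(stream) == 0:
        return SpikeTrain(out)
    if span is None:
        span = int(stream.timestamp.max())
    if span <= 0:
        raise ValueError("zero-duration recording span")
    if int(stream.timestamp.max()) > span:
        raise ValueError("event timestamp beyond recording span")
    bins = np.minimum((T * stream.timestamp) // span, T - 1)
    out[bins, stream.polarity, stream.y, stream.x] = 1
    return SpikeTrain(out)
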