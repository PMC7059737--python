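"""Synthetic data and deterministic spike fixtures.

Generates small labeled toy image sets (class-dependent bright quadrants
plus bounded noise), deterministic periodic/explicit spike trains for unit
tests of the neuron and layer dynamics, and uniformly random AER event
streams emulating the 34x34x2 ON/OFF event-camera layout.  Everything is
reproducible bit-for-bit from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .encoding import EventStream
from .lif import SpikeTrain

__all__ = ["ToySpec", "make_toy_images", "make_fixed_spike_trains", "make_synthetic_events"]


@dataclass(frozen=True)
class ToySpec:
    """Toy image-set description.

    Classes are separable by construction whenever ``contrast > noise``:
    class ``k`` lights its own quadrant at intensity ``contrast`` while
    noise adds at most ``noise`` everywhere.
    """

    n_samples: int = 128
    n_classes: int = 2
    height: int = 8
    width: int = 8
    channels: int = 1
    contrast: float = 1.0
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_classes <= 4:
            raise ValueError("quadrant patterns support 1-4 classes")
        if self.height % 2 or self.width % 2:
            raise ValueError("toy images need even dimensions")
        if not 0 < self.contrast <= 1 or not 0 <= self.noise <= 1:
            raise ValueError("contrast in (0, 1], noise in [0, 1]")


_QUADRANTS = [(0, 0), (0, 1), (1, 0), (1, 1)]  # (row-half, col-half) per class


def make_toy_images(spec: ToySpec) -> tuple[np.ndarray, np.ndarray]:
    """Labeled toy images in [0, 1], shape (N, C, H, W); balanced labels.

    Class ``k``'s deterministic pattern is a bright quadrant of intensity
    ``spec.contrast``; uniform noise in [0, spec.noise] is added and the
    result clipped to [0, 1].
    """
    rng = np.random.default_rng(spec.seed)
    labels = np.arange(spec.n_samples) % spec.n_classes
    rng.shuffle(labels)
    h2, w2 = spec.height // 2, spec.width // 2
    images = np.zeros((spec.n_samples, spec.channels, spec.height, spec.width))
    for k in range(spec.n_classes):
        r, c = _QUADRANTS[k]
        sel = labels == k
        images[sel, :, r * h2 : (r + 1) * h2, c * w2 : (c + 1) * w2] = spec.contrast
    if spec.noise > 0:
        images += rng.uniform(0.0, spec.noise, size=images.shape)
    return np.clip(images, 0.0, 1.0), labels


def make_fixed_spike_trains(
    pattern: Sequence[int] | dict | None,
    T: int,
    shape: tuple[int, ...] = (),
) -> SpikeTrain:
    """Deterministic spike trains for unit tests.

    ``pattern`` is either an explicit sequence of firing time indices in
    [1, T], a dict ``{"period": k, "offset": j}`` (spikes at steps j+k,
    j+2k, ...), or None/empty for an all-zero train.  Every unit in
    ``shape`` carries the same times.
    """
    values = np.zeros((T,) + tuple(shape), dtype=np.int8)
    if pattern:
        if isinstance(pattern, dict):
            period = int(pattern["period"])
            offset = int(pattern.get("offset", 0))
            if period < 1:
                raise ValueError("period must be >= 1")
            times = range(offset + period, T + 1, period)
        else:
            times = [int(t) for t in pattern]
        for t in times:
            if not 1 <= t <= T:
                raise ValueError(f"spike time {t} outside [1, {T}]")
            values[t - 1] = 1
    return SpikeTrain(values)


def make_synthetic_events(
    n_events: int,
    dims: tuple[int, int] = (34, 34),
    span: int = 300_000,
    seed: int = 0,
) -> EventStream:
    """Uniformly random ON/OFF events within ``dims`` and a [0, span] window
    of microsecond timestamps; seeded and sorted by time."""
    rng = np.random.default_rng(seed)
    w, h = dims
    t = np.sort(rng.integers(0, max(span, 1), size=n_events))
    return EventStream(
        x=rng.integers(0, w, size=n_events),
        y=rng.integers(0, h, size=n_events),
        polarity=rng.integers(0, 2, size=n_events),
        timestamp=t,
        width=w,
        height=h,
    )
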