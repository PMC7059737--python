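"""Discrete-time leaky integrate-and-fire (LIF) neuron dynamics.

The membrane potential of each unit integrates a per-time-step input
current.  When the potential exceeds the firing threshold ``v_th`` the unit
emits a binary spike and the potential resets to zero; otherwise the
potential decays by a factor ``exp(-1/tau_m)`` per step.  Setting
``tau_m = inf`` (or disabling the leak) yields the integrate-and-fire (IF)
limit.  The final classification layer of a network uses an infinite
threshold so that it never spikes and simply accumulates (leaky) current.

Update order per step: integrate the current, test the threshold, and only
on non-spike steps apply the decay to the post-integration potential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NeuronParams",
    "NeuronState",
    "CurrentTrace",
    "SpikeTrain",
    "lif_step",
    "if_step",
    "run_window",
]


@dataclass(frozen=True)
class NeuronParams:
    """Parameters of a population of identical LIF units.

    Parameters
    ----------
    v_th
        Firing threshold in membrane-potential units.  ``math.inf`` is the
        sentinel for a non-spiking (final) layer.
    tau_m
        Membrane time constant in time-steps.  ``math.inf`` gives the IF
        (no-leak) limit.
    leak_enabled
        If False the decay step is skipped entirely (equivalent to
        ``tau_m = inf``); used for pooling units and the IF limit.
    """

    v_th: float = 1.0
    tau_m: float = 100.0
    leak_enabled: bool = True

    def __post_init__(self) -> None:
        if not self.v_th > 0:
            raise ValueError(f"v_th must be positive, got {self.v_th}")
        if not self.tau_m > 0:
            raise ValueError(f"tau_m must be positive, got {self.tau_m}")

    @property
    def decay(self) -> float:
        """Per-step membrane decay factor ``exp(-1/tau_m)``."""
        if not self.leak_enabled or math.isinf(self.tau_m):
            return 1.0
        return math.exp(-1.0 / self.tau_m)


@dataclass
class NeuronState:
    """Membrane potential plus spike bookkeeping for a neuron population.

    ``spike_times`` records, per neuron, the strictly increasing firing time
    indices in ``[1, T]``; it is what the approximate activation derivative
    is evaluated from at the end of the window.
    """

    v_mem: np.ndarray
    spike_count: np.ndarray
    spike_times: list = field(default_factory=list)

    @classmethod
    def zeros(cls, shape) -> "NeuronState":
        v = np.zeros(shape, dtype=np.float64)
        return cls(
            v_mem=v,
            spike_count=np.zeros(shape, dtype=np.int64),
            spike_times=[[] for _ in range(v.size)],
        )

    def record_spikes(self, spikes: np.ndarray, t: int) -> None:
        flat = spikes.reshape(-1)
        for idx in np.flatnonzero(flat):
            self.spike_times[idx].append(t)


@dataclass(frozen=True)
class CurrentTrace:
    """Per-time-step input current for a neuron population over a window.

    ``values`` has shape ``(T,) + neuron_shape``.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim < 1 or v.shape[0] < 1:
            raise ValueError("CurrentTrace needs at least one time step")
        if not np.all(np.isfinite(v)):
            raise ValueError("CurrentTrace values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def duration(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class SpikeTrain:
    """Binary spatiotemporal spike record over a fixed window.

    ``values`` has shape ``(T,) + unit_shape`` with entries in {0, 1} for
    hidden/output layers, or {-1, 0, 1} at the (bipolar) input layer.
    """

    values: np.ndarray
    signed: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        allowed = {-1, 0, 1} if self.signed else {0, 1}
        present = set(np.unique(v).tolist())
        if not present <= allowed:
            raise ValueError(f"spike values {present - allowed} outside {allowed}")
        object.__setattr__(self, "values", v.astype(np.int8))

    @property
    def duration(self) -> int:
        return self.values.shape[0]

    def counts(self) -> np.ndarray:
        """Per-unit spike count over the window (signed sum for bipolar)."""
        return self.values.astype(np.int64).sum(axis=0)


def _check_step(current: np.ndarray, t: int, duration: int | None = None) -> np.ndarray:
    current = np.asarray(current, dtype=np.float64)
    if not np.all(np.isfinite(current)):
        raise ValueError("input current must be finite")
    if t < 1 or (duration is not None and t > duration):
        raise ValueError(f"time index {t} outside window")
    return current


def lif_step(
    state: NeuronState,
    current: np.ndarray,
    params: NeuronParams,
    t: int,
    duration: int | None = None,
) -> np.ndarray:
    """Advance one LIF time step in place; return the binary spike array.

    Integrates ``current`` into the membrane potential, emits a spike and
    resets to zero wherever the potential strictly exceeds ``v_th``, and
    decays the potential of the remaining units.
    """
    current = _check_step(current, t, duration)
    v = state.v_mem + current
    spikes = v > params.v_th
    v = np.where(spikes, 0.0, v * params.decay)
    state.v_mem = v
    if spikes.any():
        state.spike_count += spikes
        state.record_spikes(spikes, t)
    return spikes.astype(np.int8)


def if_step(
    state: NeuronState,
    current: np.ndarray,
    params: NeuronParams,
    t: int,
    duration: int | None = None,
) -> np.ndarray:
    """IF (no-leak) limit of :func:`lif_step`."""
    no_leak = NeuronParams(v_th=params.v_th, tau_m=params.tau_m, leak_enabled=False)
    return lif_step(state, current, no_leak, t, duration)


def run_window(currents: CurrentTrace, params: NeuronParams) -> tuple[SpikeTrain, NeuronState]:
    """Simulate a population over a full window of input currents.

    Membrane potentials start at zero.  Returns the emitted spike train and
    the final neuron state; the state's spike counts equal the time sums of
    the returned train.
    """
    T = currents.duration
    state = NeuronState.zeros(currents.values.shape[1:])
    out = np.empty_like(currents.values, dtype=np.int8)
    for t in range(1, T + 1):
        out[t - 1] = lif_step(state, currents.values[t - 1], params, t, duration=T)
    return SpikeTrain(out), state
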