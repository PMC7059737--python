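"""Spike-activity profiling and energy/latency accounting.

A conventional network performs one multiply-accumulate (MAC) per synaptic
connection per inference; event-driven spiking hardware performs one
accumulate (AC) per synaptic connection only when a pre-synaptic spike
arrives.  With per-layer average spiking activity ``a_l`` (mean spikes per
neuron per time-step at the layer's input) and shape-derived synaptic
counts ``#MAC_l``:

    #MAC/inference = sum_l #MAC_l
    #AC/inference  = (sum_l #MAC_l * a_l) * T

Energy uses published per-operation constants for a 45 nm process:
4.6 pJ / 0.9 pJ per 32-bit floating-point MAC / AC, and 3.2 pJ / 0.1 pJ
for 32-bit integer operations (the default).  Relative efficiency between
two networks is the quotient of their per-inference energies, and can be
computed either from measured operation counts or from pre-normalized
operation ratios (AC : AC : MAC) when a baseline's counts are taken from a
published table rather than re-measured.  Inference speedup is simply the
quotient of the inference time windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import AvgPoolLayer, ConvLayer, FCLayer, OutputLayer, ResidualBlock
from .models import SpikingNetwork

__all__ = [
    "EnergyModel",
    "ActivityProfile",
    "EfficiencyReport",
    "profile_activity",
    "synaptic_ops",
    "energy_per_inference",
    "energy_ratio",
    "speedup",
]


@dataclass(frozen=True)
class EnergyModel:
    """Per-operation energy constants in pJ (45 nm node), overridable."""

    mac_fp32: float = 4.6
    ac_fp32: float = 0.9
    mac_int32: float = 3.2
    ac_int32: float = 0.1

    def __post_init__(self) -> None:
        for name in ("mac_fp32", "ac_fp32", "mac_int32", "ac_int32"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def mac(self, precision: str = "int32") -> float:
        return {"int32": self.mac_int32, "fp32": self.mac_fp32}[precision]

    def ac(self, precision: str = "int32") -> float:
        return {"int32": self.ac_int32, "fp32": self.ac_fp32}[precision]


@dataclass
class ActivityProfile:
    """Per-site spike activity of one network over a set of inputs.

    Sites are the input layer plus every spiking population, in network
    order.  ``spike_totals`` are spikes per inference (averaged over the
    profiled samples, input spikes counted by magnitude); ``activities``
    are mean spikes per neuron per time-step.
    """

    layer_names: list[str]
    neuron_counts: list[int]
    spike_totals: list[float]
    T: int
    n_samples: int = 1

    @property
    def activities(self) -> np.ndarray:
        return np.array(
            [s / (n * self.T) for s, n in zip(self.spike_totals, self.neuron_counts)]
        )

    @property
    def total_spikes_per_inference(self) -> float:
        return float(sum(self.spike_totals))


@dataclass(frozen=True)
class EfficiencyReport:
    """Operation counts and energies per inference for one network."""

    mac_ops: float
    ac_ops: float
    T: int
    model: EnergyModel = field(default_factory=EnergyModel)
    precision: str = "int32"

    @property
    def energy_ann_pj(self) -> float:
        """Energy if the same topology ran as a conventional (MAC) network."""
        return self.mac_ops * self.model.mac(self.precision)

    @property
    def energy_snn_pj(self) -> float:
        """Energy of the spiking (AC) execution."""
        return self.ac_ops * self.model.ac(self.precision)

    @property
    def snn_vs_ann(self) -> float:
        """How many times less energy the spiking execution uses vs the ANN."""
        return self.energy_ann_pj / self.energy_snn_pj


def profile_activity(
    network: SpikingNetwork, input_spikes: np.ndarray
) -> ActivityProfile:
    """Run one inference window and record per-site spiking activity.

    ``input_spikes`` has shape (T, B, ...); activity is averaged over the
    batch.  Input spikes are counted by magnitude (a bipolar -1 counts as
    one spike); the non-spiking output layer contributes no site.
    """
    T, B = input_spikes.shape[:2]
    network.forward(input_spikes, training=False)
    names = ["input"]
    counts = [int(np.prod(input_spikes.shape[2:]))]
    totals = [float(np.abs(input_spikes.astype(np.int64)).sum()) / B]
    for i, layer in enumerate(network.layers):
        if isinstance(layer, OutputLayer):
            continue  # never spikes
        if isinstance(layer, ResidualBlock):
            for tag, pop in (("mid", layer.pop_mid), ("out", layer.pop_out)):
                names.append(f"{i}:residual-{tag}")
                counts.append(int(np.prod(pop.out.shape[2:])))
                totals.append(float(pop.out.astype(np.int64).sum()) / B)
        elif isinstance(layer, (ConvLayer, FCLayer)):
            kind = "conv" if isinstance(layer, ConvLayer) else "fc"
            names.append(f"{i}:{kind}")
            counts.append(int(np.prod(layer.pop.out.shape[2:])))
            totals.append(float(layer.pop.out.astype(np.int64).sum()) / B)
        elif isinstance(layer, AvgPoolLayer):
            names.append(f"{i}:pool")
            counts.append(int(np.prod(layer.out.shape[2:])))
            totals.append(float(layer.out.astype(np.int64).sum()) / B)
    return ActivityProfile(names, counts, totals, T=T, n_samples=B)


def _mac_entries(network: SpikingNetwork) -> list[tuple[str, float]]:
    """(input-site name, #MAC) per trainable linear map, in forward order.

    The site name identifies which profiled activity drives the map's
    accumulate operations.
    """
    entries = []
    prev_site = "input"
    for i, layer in enumerate(network.layers):
        if isinstance(layer, (ConvLayer, OutputLayer, FCLayer)):
            if isinstance(layer, ConvLayer):
                K, C, kh, kw = layer.w.shape
                ho, wo = layer._out_hw
                macs = K * ho * wo * C * kh * kw
                site = f"{i}:conv"
            else:
                macs = layer.w.shape[0] * layer.w.shape[1]
                site = None if isinstance(layer, OutputLayer) else f"{i}:fc"
            entries.append((prev_site, float(macs)))
            if site is not None:
                prev_site = site
        elif isinstance(layer, ResidualBlock):
            K1, C, _, _ = layer.w1.shape
            mh, mw = layer._mid_hw
            oh, ow = layer._out_hw
            entries.append((prev_site, float(K1 * mh * mw * C * 9)))
            entries.append((f"{i}:residual-mid", float(layer.w2.shape[0] * oh * ow * K1 * 9)))
            if layer.w_skip is not None:
                entries.append((prev_site, float(layer.w_skip.shape[0] * oh * ow * C)))
            else:
                entries.append((prev_site, float(layer.w2.shape[0] * oh * ow)))
            prev_site = f"{i}:residual-out"
        elif isinstance(layer, AvgPoolLayer):
            prev_site = f"{i}:pool"
    return entries


def synaptic_ops(
    network: SpikingNetwork, profile: ActivityProfile
) -> tuple[float, float]:
    """Per-inference (#MAC, #AC) counts for a profiled network.

    #MAC is the shape-derived multiply-accumulate count of the equivalent
    conventional network; #AC weights each layer's synaptic count by the
    spiking activity at its input and by the window length.
    """
    act = dict(zip(profile.layer_names, profile.activities))
    entries = _mac_entries(network)
    for site, _ in entries:
        if site not in act:
            raise ValueError(f"profile has no activity for site {site!r}")
    mac_total = sum(m for _, m in entries)
    ac_total = sum(m * act[site] for site, m in entries) * profile.T
    return mac_total, ac_total


def energy_per_inference(
    mac_ops: float,
    ac_ops: float,
    model: EnergyModel | None = None,
    precision: str = "int32",
) -> tuple[float, float]:
    """(ANN energy, SNN energy) in pJ for given per-inference op counts."""
    model = EnergyModel() if model is None else model
    return mac_ops * model.mac(precision), ac_ops * model.ac(precision)


def energy_ratio(
    snn_ac: float,
    conversion_ac: float | None = None,
    ann_mac: float = 1.0,
    model: EnergyModel | None = None,
    precision: str = "int32",
) -> dict[str, float]:
    """Energy-efficiency factors from pre-normalized operation ratios.

    ``snn_ac`` / ``conversion_ac`` are AC-operation counts and ``ann_mac``
    the MAC-operation count, all on a common (typically ANN-normalized)
    scale — e.g. a published AC : AC : MAC ratio triple.  Returns the
    pairwise energy quotients; a factor above 1 means the first-named
    network is that many times more energy-efficient.
    """
    if snn_ac <= 0 or ann_mac <= 0 or (conversion_ac is not None and conversion_ac <= 0):
        raise ValueError("operation ratios must be positive")
    model = EnergyModel() if model is None else model
    e_snn = snn_ac * model.ac(precision)
    e_ann = ann_mac * model.mac(precision)
    out = {"snn_vs_ann": e_ann / e_snn}
    if conversion_ac is not None:
        e_conv = conversion_ac * model.ac(precision)
        out["snn_vs_conversion"] = e_conv / e_snn
        out["conversion_vs_ann"] = e_ann / e_conv
    return out


def speedup(timesteps_reference: float, timesteps_snn: float) -> float:
    """Inference speedup as the quotient of inference time windows."""
    if timesteps_reference <= 0 or timesteps_snn <= 0:
        raise ValueError("time-step counts must be positive")
    return timesteps_reference / timesteps_snn
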