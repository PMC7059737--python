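# spikebp

Spike-based backpropagation for deep convolutional spiking neural networks
(SNNs), implemented in numpy.

Spiking networks communicate through discrete binary events over time
rather than continuous activations, which makes them attractive for
event-driven neuromorphic hardware: a synapse performs work only when a
spike arrives. The catch is that the spike generation function is
discontinuous, so the standard backpropagation chain rule does not apply.
`spikebp` trains deep networks of leaky integrate-and-fire (LIF) neurons
*directly on spike trains* by replacing the activation derivative with a
leak-corrected straight-through estimate, and provides the spike-count,
energy, and latency accounting used to compare direct-trained SNNs against
conventional networks and ANN-to-SNN conversions.

## The model

Each neuron integrates a weighted sum of pre-synaptic spikes into its
membrane potential `V_mem`, which decays by `exp(-1/τ_m)` per time-step
(τ_m = 100 steps by default). When `V_mem` exceeds the firing threshold
`V_th` the neuron emits a spike and resets to zero. Input images are
rate-coded: a pixel of intensity *p* fires with probability *p* at each of
the `T` time-steps of the simulation window (T = 50–100). The final
classification layer never spikes (infinite threshold); its output is
`V_mem(T)/T`.

Training runs one backward pass per iteration, at the last time step,
from time-summed quantities. With per-neuron output spike count γ and
spike times t_k, the hidden-layer activation derivative is

    a′_LIF = (1/V_th) · (1 + f′(T)/γ),   f′(T) = −(1/τ_m) Σ_k e^−(T−t_k)/τ_m

i.e. the integrate-and-fire straight-through slope `1/V_th` shrunk by a
correction derived from the low-pass-filtered spike trace, clamped to
`[0, 1/V_th]`; silent neurons get derivative 0. The loss is the sum of
squared output errors; gradients propagate through the transposed linear
maps, and weight gradients are outer/correlation products of time-summed
input spike counts with the next layer's error gradient. Spiking dropout
draws one random unit mask per iteration and holds it fixed across all T
steps.

The package ships the benchmark topologies (a LeNet-derived 4-layer
network, VGG5–VGG9, ResNet7–ResNet11 with spiking residual blocks),
thresholded average pooling, Poisson/bipolar encoders, an AER event-stream
binner for event-camera data, IDX/AER file readers, and synthetic toy
fixtures so everything is testable offline.

## Worked example

Train a small fully connected spiking network on the built-in two-class
toy set (bright-quadrant patterns, zero noise, 8×8 pixels), with a 50-step
window:

```python
import spikebp as sp
from spikebp.models import FC, ArchitectureSpec, Output, build

images, labels = sp.make_toy_images(sp.ToySpec(n_samples=64, n_classes=2, seed=3))
flat = images.reshape(-1, 1, 1, 64)

arch = ArchitectureSpec("toy-fc", (FC(20), Output(2)))
net = build(arch, (1, 1, 64), init=sp.InitConfig(kappa=2.0, seed=0), dropout_p=0.1)

cfg = sp.TrainingConfig(T=50, batch_size=16, eta=0.02, epochs=10, dropout_p=0.1, seed=1)
history = sp.train(net, flat, labels, cfg, n_classes=2)
for h in history[::3]:
    print(f"epoch {h['epoch']:2d}  loss {h['loss']:.4f}  train acc {h['train_accuracy']:.3f}")
print(f"top-1 accuracy: {sp.evaluate(net, flat, labels, cfg):.3f}")
```

```
epoch  1  loss 0.4893  train acc 0.266
epoch  4  loss 0.2005  train acc 0.500
epoch  7  loss 0.0974  train acc 1.000
epoch 10  loss 0.0381  train acc 1.000
top-1 accuracy: 1.000
```

The loss is the mean ½Σe² over iterations; accuracy is the argmax of the
output distribution `V_mem(T)/T`. The same `train`/`evaluate`/`predict`
API drives the convolutional and residual presets
(`sp.build("vgg9", (3, 32, 32))` etc.).

Energy/latency accounting works either from profiled spike activity
(`profile_activity` + `synaptic_ops`) or directly from published
operation-ratio triples. With the 32-bit integer constants (3.2 pJ per
multiply-accumulate, 0.1 pJ per accumulate), a VGG9-class SNN whose
AC : AC : MAC operation ratio against a conversion baseline and an ANN is
28.18 : 3.61 : 1 comes out 7.81× more energy-efficient than the
conversion and 8.86× more efficient than the ANN:

```python
sp.energy_ratio(snn_ac=3.61, conversion_ac=28.18)
# {'snn_vs_ann': 8.864, 'snn_vs_conversion': 7.806, 'conversion_vs_ann': 1.136}
sp.speedup(180, 50)   # 3.6x fewer inference time-steps than the baseline
```

A thin CLI mirrors the library: `spikebp train|eval|encode|analyze`
(YAML run configs, CSV epoch logs, `.npz` checkpoints, JSON efficiency
reports).

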