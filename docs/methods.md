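# Methods

This note documents the model, the numerical choices, and the open design
decisions behind `spikebp`, in the order a reader meets them in the code.

## Neuron model and discretization

Neurons are discrete-time leaky integrate-and-fire (LIF) units with
Δt = 1 time-step and no bias term. The per-step update order follows the
integrate–threshold–decay convention: the input current is added to the
membrane potential, the threshold test `V_mem > V_th` is applied
(strictly greater), and only on non-spike steps is the post-integration
potential multiplied by the decay factor `exp(-1/τ_m)`. On a spike the
potential resets to zero (reset-to-zero, not threshold subtraction), and
there is no refractory period. Membrane potentials start at zero at the
beginning of every window. Setting `τ_m = ∞` (or `leak_enabled=False`)
gives the integrate-and-fire (IF) limit bit-for-bit.

A consequence of applying the decay to the post-integration potential is
that a constant sub-threshold current c accumulates to
`V(T) = c·r·(1−r^T)/(1−r)` with `r = exp(−1/τ_m)` — each step's input is
decayed at least once. The alternative convention (decay before
integration) would drop the leading factor r; the implemented order is the
one the forward pass and its tests assume throughout.

Defaults: `τ_m = 100` steps everywhere; `V_th = 1` for hidden neurons; the
final classification layer uses an infinite-threshold sentinel so it never
spikes and simply accumulates leaky current, reported as `V_mem(T)/T`.

## Input encoding

Static images are Poisson rate-coded: at each step each pixel's intensity
(in [0, 1]) is compared with an independent Uniform(0, 1) draw and a spike
is emitted when the intensity is larger, so spike counts are
Binomial(T, p). Color-style inputs are standardized per channel with
dataset statistics, rescaled by the global maximum absolute z-score into
[−1, 1], and encoded as bipolar spikes: sign(v) with per-step probability
|v|. Per-channel (not per-image) statistics are the convention for the
color benchmarks this emulates; a zero-variance channel is rejected as
degenerate rather than silently mapped to zero.

Event-camera streams (x, y, ON/OFF polarity, µs timestamp) are binned
into T equal-width bins over the recording span with binary clipping (at
most one spike per bin/polarity/pixel). The binning scheme is a design
choice of this package — equal-width bins are the simplest scheme that
preserves event order — and the span is an explicit argument because a
single event carries no span information of its own.

## Layers

*Convolution*: per step, the input spike frame is cross-correlated with
the kernel to produce the input current of a LIF population. 3×3 kernels
use padding 1 (size-preserving); 5×5 and 1×1 kernels use none. This
reproduces the feature-map bookkeeping of the tabulated topologies.

*Average pooling*: fixed, non-trainable 2×2/stride-2 kernel with weight
0.25 per input and a leak-free accumulator; the pooled unit fires only
when the accumulated value strictly exceeds 0.75 (three simultaneous
spikes give exactly 0.75 and do not fire) and then resets to zero,
otherwise the residue carries forward. Pool state, like neuron state, is
cleared between input windows.

*Residual blocks*: conv(3×3, stride 1) → LIF → conv(3×3, stride s), with
a skip path that is the identity when channel counts match at stride 1
and a 1×1 convolution (stride s) otherwise. Both paths' currents are
integrated into one shared output LIF population. Stride-2 blocks replace
explicit pooling layers.

*Spiking dropout*: the binary keep-mask (omission probability p, default
0.2) is drawn once per iteration before the first time step and reused at
every step; it is applied to a layer's input spikes with 1/(1−p) scaling
during training and is a no-op at inference. The mask is shared across
the mini-batch — one random sub-network per iteration, which is the
literal reading of drawing the mask outside the time loop; per-sample
masks would satisfy the same time-constancy requirement.

## Backward pass

One backward pass per iteration, after the full window, from three
time-summed per-layer quantities: total input spike count per pre-neuron
(x), total input current per post-neuron (net), and the output spike
train (which yields per-neuron spike counts γ and spike times t_k).

The final layer treats its accumulated potential as the total input
current (leak regarded as noise), so its activation derivative is 1/T and
`δ^L = e/T` with `e = output − label`, `E = ½Σe²` (averaged over the
mini-batch).

Hidden layers use the approximate LIF derivative

    a′ = (1/V_th) · (1 + f′(T)/γ),  f′(T) = −(1/τ_m) Σ_k exp(−(T−t_k)/τ_m),

evaluated once at t = T from all recorded spike times. The sign is
subtractive: the low-pass-filtered spike trace f(t) decays between
spikes, so its right-sided time derivative is negative and the combined
value is strictly below 1/V_th whenever the leak acted — consistent with
the effective-threshold picture in which the LIF threshold `V_th + ε`
exceeds the IF threshold. The value is clamped to [0, 1/V_th] to guard
the pathological case of a correction exceeding one (a negative
activation slope has no reading in the model), and silent neurons get
exactly zero — which is also the mechanism by which too-short windows
fail to train: if no spikes reach the output, every gradient is zero.

Gradients propagate through the transposed linear maps (full-correlation
adjoint for convolutions; the fixed 0.25 map with unit activation
derivative for pooling, which is leak-free and therefore closest to the
IF straight-through case; summed adjoints of both paths for residual
blocks, the skip convolution receiving its own weight gradient). Weight
gradients are outer/correlation products of time-summed input spike
counts with the next layer's error gradient, averaged (not summed) over
the mini-batch so that learning-rate ranges are batch-size-free. Dropout
masks and their 1/(1−p) scaling apply identically in the backward pass.
Conv-layer weight gradients use the time-summed input spike maps; once
time is summed this is algebraically interchangeable with per-step
accumulation for the quantities involved.

## Architectures and initialization

The preset table covers a LeNet-derived 4-trainable-layer network
(5×5 convs, 20/50 maps, two pooling stages, 200-unit FC head), VGG7/VGG9
(3×3 convs, some at stride 2), and ResNet7/9/11 (residual blocks as
above, 1024-unit FC head). VGG5/VGG6 are reconstructions for depth
studies — the VGG7 stack truncated by two/one convolutional layers — and
are flagged non-canonical in the preset comments; no authoritative layer
table exists for them. All presets end in a 10-way output by default
(overridable), and a forward window through any preset at its native
input size yields a 10-dimensional output with no shape errors.

Weights are drawn from N(0, √(κ/n)) with n the fan-in, the He-style
scaling; κ = 2 for plain (non-residual) networks and κ = 1 for residual
networks. No biases anywhere.

## Training loop

Mini-batch SGD (no momentum; none is specified for this method) or Adam
with standard moments. Defaults: T = 50 for MNIST-scale inputs (100 for
the color-scale presets), batch 16, η = 0.002, 150 epochs, dropout 0.2,
learning rate stepped ×0.1 at epochs 70/100/125 (40/80/120 under Adam).
The drop factor 0.1 is this package's choice of conventional step
schedule; the source settings leave it open. Inference always uses the
training window length. A non-finite loss aborts with a diagnostic. All
randomness (shuffling, encoding, dropout, init) flows from named seeds.

## Efficiency accounting

Per-layer activity a_l is defined as mean spikes per neuron per time-step
at the layer's *input*, so that `#MAC_l × a_l × T` has the unit
"accumulate operations per inference" (the driving spikes are what
trigger synaptic work). `#MAC/inference = Σ_l #MAC_l` from layer shapes;
`#AC/inference = (Σ_l #MAC_l × a_l) × T`. Input spikes count toward
#spikes/inference, bipolar spikes by magnitude. Energy uses 45 nm
per-operation constants — 3.2/0.1 pJ per 32-bit integer MAC/AC by
default, 4.6/0.9 pJ floating-point selectable — and efficiency factors
are energy quotients. `energy_ratio` also accepts pre-normalized
operation-ratio triples directly, since conversion baselines are external
published numbers rather than re-measured pipelines. Inference speedup is
the quotient of window lengths.

## Synthetic fixtures

The toy generator emulates only the *structure* of a supervised
image-classification task: class k lights a distinct quadrant at a fixed
contrast, plus bounded uniform noise, balanced labels, everything
seed-reproducible. At zero noise the classes are linearly separable by
construction, so convergence on the toy set demonstrates that the
gradient machinery works end-to-end — it says nothing about natural-image
statistics, augmentation, or the accuracy attainable on real benchmarks,
which require external datasets and long training runs. Fixture sizes
(≤16×16 images, ≤512 samples, T ≤ 50) keep the full test suite in the
minutes range on one CPU; the end-to-end learnability test uses 64
samples of 8×8 at T = 50 with a 20-unit hidden layer.

## Known limitations

* Forward simulation is dense per time-step (numpy); it is meant for
  desk-scale experiments, not GPU-scale benchmark training.
* Whether decay should also apply on the spike step before the reset is
  unspecified in the underlying method; the branch structure implemented
  (decay only on non-spike steps) is the literal reading.
* ANN-to-SNN conversion pipelines are out of scope; their operation
  ratios and time-step counts enter only as external inputs to the
  efficiency calculator.
* Max pooling, batch normalization, trainable thresholds, synaptic
  delays, and backpropagation-through-time are deliberately not
  implemented.
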