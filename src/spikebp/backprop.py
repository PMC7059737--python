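"""Spike-based backpropagation with an approximate LIF activation derivative.

The network is run forward over the full time window; exactly one backward
pass is executed afterwards, at the last time step, using time-summed
quantities (no unrolling through time):

* Final layer output: ``output = V_mem(T) / T`` for the non-spiking,
  infinite-threshold classification units.
* Loss: ``E = 1/2 * sum_j (output_j - label_j)^2``; the per-neuron error
  is ``e = output - label``.
* Final-layer error gradient: ``delta^L = e / T`` (the accumulated
  potential is treated as the total input current, so the activation
  derivative with respect to ``net`` is ``1/T``).
* Hidden-layer activation derivative: a straight-through slope ``1/v_th``
  (the IF limit) shrunk by a leak correction obtained from the low-pass
  filtered output spike trace ``f(t) = sum_k exp(-(t - t_k)/tau_m)``,
  evaluated from the right at the end of the window:

      a'_LIF = (1/v_th) * (1 + f'(T)/gamma),
      f'(T)  = -(1/tau_m) * sum_k exp(-(T - t_k)/tau_m),

  where ``gamma`` is the neuron's output spike count.  ``f(t)`` decays
  between spikes, so the correction is subtractive and the derivative is
  strictly below ``1/v_th`` whenever the leak acted.  Silent neurons
  (``gamma = 0``) have derivative exactly zero, and the value is clamped to
  ``[0, 1/v_th]``.
* Hidden-layer gradients propagate recursively through the transposed
  linear maps; weight gradients are the outer/correlation products of the
  time-summed input spike counts with the next layer's error gradient.
"""

from __future__ import annotations

import math

import numpy as np

from .lif import NeuronParams, NeuronState

__all__ = [
    "final_output",
    "loss_and_error",
    "lif_pseudo_derivative",
    "final_layer_grad",
    "hidden_layer_grad",
    "weight_gradient",
    "sgd_update",
]


def final_output(state: NeuronState, T: int) -> np.ndarray:
    """Final-layer activation: accumulated membrane potential over T steps."""
    if T <= 0:
        raise ValueError("window length must be positive")
    return state.v_mem / T


def loss_and_error(output: np.ndarray, label: np.ndarray) -> tuple[float, np.ndarray]:
    """Sum-of-squared-error loss and per-neuron error ``e = output - label``.

    For batched inputs (leading batch axis) the loss is averaged over the
    batch; the error keeps its per-sample shape.
    """
    output = np.asarray(output, dtype=np.float64)
    label = np.asarray(label, dtype=np.float64)
    if output.shape != label.shape:
        raise ValueError(f"output shape {output.shape} != label shape {label.shape}")
    e = output - label
    if e.ndim <= 1:
        E = 0.5 * float(np.sum(e**2))
    else:
        E = 0.5 * float(np.sum(e**2)) / e.shape[0]
    return E, e


def lif_pseudo_derivative(state: NeuronState, params: NeuronParams, T: int) -> np.ndarray:
    """Approximate derivative of the LIF activation, one value per neuron.

    Evaluated once at the end of the window from the recorded spike times.
    Returns 0 for silent neurons, exactly ``1/v_th`` in the no-leak (IF)
    limit, and otherwise the leak-corrected straight-through value clamped
    to ``[0, 1/v_th]``.
    """
    leak = params.leak_enabled and not math.isinf(params.tau_m)
    out = np.zeros(state.spike_count.size, dtype=np.float64)
    counts = state.spike_count.reshape(-1)
    for i, times in enumerate(state.spike_times):
        gamma = counts[i]
        if gamma == 0:
            continue
        if leak:
            tk = np.asarray(times, dtype=np.float64)
            f_prime = -np.sum(np.exp(-(T - tk) / params.tau_m)) / params.tau_m
        else:
            f_prime = 0.0
        out[i] = (1.0 + f_prime / gamma) / params.v_th
    np.clip(out, 0.0, 1.0 / params.v_th, out=out)
    return out.reshape(state.spike_count.shape)


def final_layer_grad(e: np.ndarray, T: int) -> np.ndarray:
    """Error gradient with respect to the final layer's total input current."""
    if T <= 0:
        raise ValueError("window length must be positive")
    return np.asarray(e, dtype=np.float64) / T


def hidden_layer_grad(
    weights: np.ndarray, delta_next: np.ndarray, pseudo_derivs: np.ndarray
) -> np.ndarray:
    """Recursive hidden-layer gradient for a fully connected layer.

    ``delta^l = (w^T delta^{l+1}) * a'_LIF`` with ``weights`` of shape
    (n_out, n_in) mapping this layer's outputs to the next layer's units.
    Convolutional and pooling layers realize the same rule through the
    adjoints of their linear maps (see :mod:`spikebp.layers`).
    """
    weights = np.asarray(weights, dtype=np.float64)
    delta_next = np.asarray(delta_next, dtype=np.float64)
    back = delta_next @ weights if delta_next.ndim > 1 else weights.T @ delta_next
    if back.shape != np.shape(pseudo_derivs):
        raise ValueError("shape mismatch between propagated gradient and derivatives")
    return back * pseudo_derivs


def weight_gradient(x: np.ndarray, delta_next: np.ndarray) -> np.ndarray:
    """Weight gradient: outer product of time-summed input spike counts with
    the next layer's error gradient; batched inputs are averaged."""
    x = np.asarray(x, dtype=np.float64)
    delta_next = np.asarray(delta_next, dtype=np.float64)
    if x.ndim == 1 and delta_next.ndim == 1:
        return np.outer(delta_next, x)
    if x.ndim == 2 and delta_next.ndim == 2:
        if x.shape[0] != delta_next.shape[0]:
            raise ValueError("batch sizes differ")
        return np.einsum("bo,bi->oi", delta_next, x) / x.shape[0]
    raise ValueError("x and delta must both be 1-D (single sample) or 2-D (batch)")


def sgd_update(w: np.ndarray, dw: np.ndarray, eta: float) -> np.ndarray:
    """Plain gradient-descent step ``w - eta * dw``."""
    if eta <= 0:
        raise ValueError("learning rate must be positive")
    w = np.asarray(w, dtype=np.float64)
    dw = np.asarray(dw, dtype=np.float64)
    if w.shape != dw.shape:
        raise ValueError("weight and gradient shapes differ")
    return w - eta * dw
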