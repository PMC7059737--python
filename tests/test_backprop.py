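"""Tests for the spike-based backward pass and the approximate derivative."""

import math

import numpy as np
import pytest

from spikebp.backprop import (
    final_layer_grad,
    final_output,
    hidden_layer_grad,
    lif_pseudo_derivative,
    loss_and_error,
    sgd_update,
    weight_gradient,
)
from spikebp.lif import CurrentTrace, NeuronParams, NeuronState, run_window


class TestFinalOutput:
    def test_zero_input(self):
        state = NeuronState.zeros((4,))
        assert not final_output(state, 100).any()

    def test_no_leak_limit(self):
        params = NeuronParams(v_th=math.inf, tau_m=math.inf)
        currents = np.zeros((100, 1))
        currents[:37, 0] = 1.0  # total current 37
        _, state = run_window(CurrentTrace(currents), params)
        assert final_output(state, 100)[0] == pytest.approx(0.37)

    def test_rejects_zero_window(self):
        with pytest.raises(ValueError):
            final_output(NeuronState.zeros((1,)), 0)


class TestLossAndError:
    def test_zero_at_target(self):
        out = np.array([0.0, 1.0, 0.0])
        E, e = loss_and_error(out, out)
        assert E == 0.0
        assert not e.any()

    def test_half_squared_error(self):
        E, e = loss_and_error(np.array([0.6]), np.array([1.0]))
        assert e[0] == pytest.approx(-0.4)
        assert E == pytest.approx(0.08)

    def test_quadratic_scaling(self, rng):
        label = np.zeros(5)
        out = rng.random(5)
        E1, _ = loss_and_error(out, label)
        E2, _ = loss_and_error(2 * out, label)
        assert E2 == pytest.approx(4 * E1)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            loss_and_error(np.zeros(3), np.zeros(4))


class TestPseudoDerivative:
    def test_silent_neuron_zero(self):
        state = NeuronState.zeros((3,))
        assert not lif_pseudo_derivative(state, NeuronParams(), 100).any()

    def test_no_leak_limit_is_straight_through(self):
        state = NeuronState.zeros((1,))
        state.spike_count[:] = 3
        state.spike_times = [[10, 50, 90]]
        params = NeuronParams(v_th=1.0, tau_m=math.inf)
        assert lif_pseudo_derivative(state, params, 100)[0] == 1.0

    def test_single_spike_closed_form(self):
        # one spike at T-10, tau 100: 1 - (1/100) e^{-0.1}
        state = NeuronState.zeros((1,))
        state.spike_count[:] = 1
        state.spike_times = [[90]]
        val = lif_pseudo_derivative(state, NeuronParams(v_th=1.0, tau_m=100.0), 100)
        assert val[0] == pytest.approx(1 - 0.01 * math.exp(-0.1), rel=1e-12)
        assert val[0] == pytest.approx(0.990952, abs=5e-7)

    def test_bounded_by_inverse_threshold(self, rng):
        # randomly driven neurons: value in (0, 1/v_th] for spiking units
        params = NeuronParams(v_th=1.0, tau_m=100.0)
        currents = rng.uniform(0, 0.8, size=(100, 200))
        _, state = run_window(CurrentTrace(currents), params)
        deriv = lif_pseudo_derivative(state, params, 100)
        spiking = state.spike_count > 0
        assert spiking.any()
        assert (deriv[spiking] > 0).all()
        assert (deriv[spiking] <= 1.0).all()
        assert (deriv[spiking] < 1.0).all()  # leak acted, so strictly below
        assert not deriv[~spiking].any()

    def test_respects_threshold_scaling(self):
        state = NeuronState.zeros((1,))
        state.spike_count[:] = 1
        state.spike_times = [[100]]
        params = NeuronParams(v_th=2.0, tau_m=math.inf)
        assert lif_pseudo_derivative(state, params, 100)[0] == 0.5


class TestGradientOps:
    def test_final_layer_grad(self):
        assert final_layer_grad(np.array([1.0]), 100)[0] == pytest.approx(0.01)
        assert not final_layer_grad(np.zeros(3), 10).any()
        e = np.array([0.2, -0.4])
        assert np.allclose(final_layer_grad(2 * e, 50), 2 * final_layer_grad(e, 50))
        with pytest.raises(ValueError):
            final_layer_grad(e, 0)

    def test_hidden_layer_grad_matrix_arithmetic(self):
        # 2-unit -> 1-unit layer, explicit matrix oracle
        w = np.array([[0.5, -1.0]])  # (n_out=1, n_in=2)
        delta_next = np.array([0.2])
        pseudo = np.array([0.9, 0.8])
        expected = np.array([0.5 * 0.2 * 0.9, -1.0 * 0.2 * 0.8])
        assert np.allclose(hidden_layer_grad(w, delta_next, pseudo), expected)

    def test_silent_neuron_blocks_gradient(self):
        w = np.array([[1.0, 1.0]])
        delta = hidden_layer_grad(w, np.array([0.5]), np.array([0.0, 0.7]))
        assert delta[0] == 0.0
        assert delta[1] != 0.0

    def test_zero_delta_propagates_zero(self):
        assert not hidden_layer_grad(np.ones((3, 4)), np.zeros(3), np.ones(4)).any()

    def test_weight_gradient_outer_product(self):
        dw = weight_gradient(np.array([3.0, 1.0]), np.array([0.02]))
        assert np.allclose(dw, [[0.06, 0.02]])

    def test_weight_gradient_zero_input(self):
        assert not weight_gradient(np.zeros(4), np.array([0.5, -0.5])).any()

    def test_weight_gradient_batch_average(self):
        x = np.array([[1.0, 0.0], [3.0, 2.0]])
        d = np.array([[1.0], [2.0]])
        expected = (np.outer(d[0], x[0]) + np.outer(d[1], x[1])) / 2
        assert np.allclose(weight_gradient(x, d), expected)

    def test_weight_gradient_linear_in_delta(self, rng):
        x = rng.random(6)
        d = rng.random(3)
        assert np.allclose(weight_gradient(x, 2 * d), 2 * weight_gradient(x, d))

    def test_sgd_update(self):
        assert sgd_update(np.array([0.5]), np.array([0.1]), 0.003)[0] == pytest.approx(0.4997)
        w = np.array([1.0, -2.0])
        assert np.array_equal(sgd_update(w, np.zeros(2), 0.1), w)
        with pytest.raises(ValueError):
            sgd_update(w, np.zeros(2), 0.0)

    def test_sgd_updates_commute_with_summed_gradients(self, rng):
        w = rng.random(5)
        g1, g2 = rng.random(5), rng.random(5)
        seq = sgd_update(sgd_update(w, g1, 0.01), g2, 0.01)
        summed = sgd_update(w, g1 + g2, 0.01)
        assert np.allclose(seq, summed)


class TestNetworkBackward:
    def test_zero_error_gives_zero_gradients(self, fc_network_factory, rng):
        net = fc_network_factory(6, [8], 3, seed=1)
        spikes = (rng.random((20, 1, 1, 1, 6)) < 0.5).astype(np.int8)
        out = net.forward(spikes)
        net.backward(np.zeros_like(out))
        for g in net.gradients():
            assert not g.any()

    def test_all_silent_network_zero_gradients(self, fc_network_factory, rng):
        # scale hidden weights down so no hidden neuron ever fires: the
        # zero-derivative rule then blocks every gradient, including the
        # first layer's (despite its nonzero input spikes)
        net = fc_network_factory(6, [8, 5], 2, seed=2)
        params = net.parameters()
        net.set_parameters([w * 1e-4 for w in params])
        spikes = (rng.random((30, 1, 1, 1, 6)) < 0.8).astype(np.int8)
        out = net.forward(spikes)
        assert not out.any()  # no spikes reach the accumulator
        _, e = (None, out - np.array([[1.0, 0.0]]))
        net.backward(e)
        for g in net.gradients():
            assert not g.any()

    def test_layered_backward_matches_dense_oracle(self, fc_network_factory, rng):
        """Layered backward pass vs an independent dense-matrix oracle."""
        net = fc_network_factory(5, [7, 6], 3, seed=3)
        T = 25
        spikes = (rng.random((T, 1, 1, 1, 5)) < 0.6).astype(np.int8)
        out = net.forward(spikes)
        label = np.zeros((1, 3))
        label[0, 1] = 1.0
        e = out - label
        net.backward(e)
        impl_grads = net.gradients()

        # --- independent oracle: explicit matrices, explicit spike times ---
        hidden_layers = [net.layers[1], net.layers[2]]  # FlattenLayer first
        out_layer = net.layers[3]

        def pseudo_from_train(train, tau, v_th):
            T_, n = train.shape[0], train.shape[-1]
            vals = np.zeros(n)
            for j in range(n):
                times = [t + 1 for t in range(T_) if train[t, 0, j]]
                if not times:
                    continue
                fp = -sum(math.exp(-(T_ - tk) / tau) for tk in times) / tau
                vals[j] = min(max((1 + fp / len(times)) / v_th, 0.0), 1.0 / v_th)
            return vals

        delta = e[0] / T                                   # final-layer gradient
        dw_out = np.outer(delta, out_layer.x_sum[0])
        g = out_layer.w.T @ delta
        expected = [dw_out]
        for layer in reversed(hidden_layers):
            pd = pseudo_from_train(layer.pop.out, layer.params.tau_m, layer.params.v_th)
            delta = g * pd
            expected.append(np.outer(delta, layer.x_sum[0]))
            g = layer.w.T @ delta
        expected = expected[::-1]

        assert len(impl_grads) == len(expected)
        for got, want in zip(impl_grads, expected):
            np.testing.assert_allclose(got, want, rtol=1e-10, atol=1e-14)
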