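"""Tests for the spiking conv/pool/fc layers, dropout, and residual blocks."""

import math

import numpy as np
import pytest

from spikebp.layers import (
    AvgPoolLayer,
    ConvLayer,
    DropoutConfig,
    FCLayer,
    ResidualBlock,
    apply_dropout,
    avgpool_forward,
    conv2d,
    conv2d_input_grad,
    conv2d_weight_grad,
)
from spikebp.lif import NeuronParams


def scalar_conv_lif_oracle(spikes, w, v_th, tau_m):
    """Hand-loop reference for a single-channel 2D spiking conv, stride 1,
    no padding: per step correlate, integrate, threshold, reset/decay."""
    T, H, W = spikes.shape
    kh, kw = w.shape
    Ho, Wo = H - kh + 1, W - kw + 1
    decay = math.exp(-1.0 / tau_m)
    v = np.zeros((Ho, Wo))
    out = np.zeros((T, Ho, Wo), dtype=np.int8)
    for t in range(T):
        for i in range(Ho):
            for j in range(Wo):
                cur = sum(
                    spikes[t, i + a, j + b] * w[a, b]
                    for a in range(kh) for b in range(kw)
                )
                v[i, j] += cur
                if v[i, j] > v_th:
                    out[t, i, j] = 1
                    v[i, j] = 0.0
                else:
                    v[i, j] *= decay
    return out


class TestConvPrimitives:
    def test_adjoint_identity_input_grad(self, rng):
        # <conv(x), y> == <x, conv_input_grad(y)> for random tensors
        x = rng.normal(size=(2, 3, 8, 8))
        w = rng.normal(size=(4, 3, 3, 3))
        for stride, padding in [(1, 1), (2, 1), (1, 0)]:
            y = conv2d(x, w, stride, padding)
            g = rng.normal(size=y.shape)
            lhs = np.vdot(y, g)
            rhs = np.vdot(x, conv2d_input_grad(g, w, (8, 8), stride, padding))
            assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_adjoint_identity_weight_grad(self, rng):
        x = rng.normal(size=(2, 3, 6, 6))
        w = rng.normal(size=(5, 3, 3, 3))
        y = conv2d(x, w, 1, 1)
        g = rng.normal(size=y.shape)
        lhs = np.vdot(y, g)
        rhs = np.vdot(w, conv2d_weight_grad(x, g, (3, 3), 1, 1))
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestConvLayer:
    def test_zero_weights_zero_output(self, rng):
        layer = ConvLayer(np.zeros((2, 1, 3, 3)), padding=1)
        spikes = (rng.random((5, 2, 1, 6, 6)) < 0.5).astype(np.int8)
        assert not layer.forward(spikes).any()

    def test_unit_kernel_passthrough(self):
        # 1x1 kernel with w = 1.5 > v_th = 1: every input spike fires out
        layer = ConvLayer(np.full((1, 1, 1, 1), 1.5), params=NeuronParams(v_th=1.0))
        spikes = np.zeros((4, 1, 1, 3, 3), dtype=np.int8)
        spikes[1, 0, 0, 1, 2] = 1
        spikes[3, 0, 0, 0, 0] = 1
        out = layer.forward(spikes)
        assert np.array_equal(out, spikes)

    def test_matches_scalar_step_oracle(self, rng):
        w = rng.normal(0, 0.8, size=(2, 2))
        spikes = (rng.random((3, 4, 4)) < 0.6).astype(np.int8)
        expected = scalar_conv_lif_oracle(spikes, w, v_th=1.0, tau_m=100.0)
        layer = ConvLayer(w[None, None], stride=1, padding=0,
                          params=NeuronParams(v_th=1.0, tau_m=100.0))
        out = layer.forward(spikes[:, None, None])
        assert np.array_equal(out[:, 0, 0], expected)

    def test_shape_mismatch_rejected(self, rng):
        layer = ConvLayer(np.zeros((2, 3, 3, 3)))
        spikes = np.zeros((2, 1, 1, 6, 6), dtype=np.int8)
        with pytest.raises(ValueError, match="channels"):
            layer.forward(spikes)


class TestAvgPool:
    def test_four_simultaneous_spikes_fire(self):
        spikes = np.zeros((1, 1, 1, 2, 2), dtype=np.int8)
        spikes[0] = 1  # 4 spikes in one window: 4 * 0.25 = 1.0 > 0.75
        out, residue = avgpool_forward(spikes)
        assert out[0, 0, 0, 0, 0] == 1
        assert residue[0, 0, 0, 0] == 0.0

    def test_three_spikes_hold_then_fire_with_residue(self):
        spikes = np.zeros((2, 1, 1, 2, 2), dtype=np.int8)
        spikes[0, 0, 0, [0, 0, 1], [0, 1, 0]] = 1  # 3 spikes: 0.75, not > 0.75
        spikes[1, 0, 0, 1, 1] = 1                  # +0.25 -> 1.0 fires
        out, _ = avgpool_forward(spikes)
        assert out[0].sum() == 0
        assert out[1, 0, 0, 0, 0] == 1

    def test_all_zero_input(self):
        out, residue = avgpool_forward(np.zeros((3, 1, 2, 4, 4), dtype=np.int8))
        assert not out.any()
        assert not residue.any()

    def test_residue_conserved_without_firing(self):
        # one spike per step accumulates 0.25 with no decay
        spikes = np.zeros((3, 1, 1, 2, 2), dtype=np.int8)
        spikes[:, 0, 0, 0, 0] = 1
        out, residue = avgpool_forward(spikes)
        assert not out.any()
        assert residue[0, 0, 0, 0] == pytest.approx(0.75)

    def test_odd_dims_rejected(self):
        with pytest.raises(ValueError, match="even"):
            avgpool_forward(np.zeros((1, 1, 1, 3, 3), dtype=np.int8))


class TestDropout:
    def test_p_zero_identity(self, rng):
        values = rng.random((4, 5))
        cfg = DropoutConfig(p=0.0)
        assert np.array_equal(apply_dropout(values, cfg, training=True), values)

    def test_inference_identity(self, rng):
        cfg = DropoutConfig(p=0.3)
        cfg.draw_mask((5,), rng)
        values = rng.random((5,))
        assert np.array_equal(apply_dropout(values, cfg, training=False), values)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            DropoutConfig(p=1.0)
        with pytest.raises(ValueError):
            DropoutConfig(p=-0.1)

    def test_masked_fraction_near_p(self, rng):
        cfg = DropoutConfig(p=0.25)
        cfg.draw_mask((20000,), rng)
        assert np.mean(cfg.mask == 0) == pytest.approx(0.25, abs=0.02)

    def test_mask_constant_across_window_within_iteration(self, rng):
        # all-ones input for T steps: the per-unit time-summed masked input
        # must be exactly 0 or T/(1-p), which holds only if the mask is
        # bit-identical at every step of the iteration
        T, n = 20, 50
        layer = FCLayer(np.zeros((3, n)), dropout_p=0.5)
        layer.begin_iteration(rng, training=True)
        spikes = np.ones((T, 1, n), dtype=np.int8)
        layer.forward(spikes, training=True)
        sums = layer.x_sum[0]
        assert set(np.round(sums, 9)) <= {0.0, round(T / 0.5, 9)}

    def test_masks_differ_across_iterations(self, rng):
        layer = FCLayer(np.zeros((3, 100)), dropout_p=0.5)
        spikes = np.ones((2, 1, 100), dtype=np.int8)
        layer.begin_iteration(rng, training=True)
        layer.forward(spikes, training=True)
        first = layer.dropout.mask.copy()
        layer.begin_iteration(rng, training=True)
        layer.forward(spikes, training=True)
        assert not np.array_equal(first, layer.dropout.mask)


class TestResidualBlock:
    def _spikes(self, rng, T=4, C=2, H=6, W=6):
        return (rng.random((T, 1, C, H, W)) < 0.5).astype(np.int8)

    def test_zero_skip_equals_plain_stack(self, rng):
        w1 = rng.normal(0, 0.7, (3, 2, 3, 3))
        w2 = rng.normal(0, 0.7, (3, 3, 3, 3))
        w_skip = np.zeros((3, 2, 1, 1))
        spikes = self._spikes(rng)
        block = ResidualBlock(w1, w2, w_skip, stride=1)
        out_block = block.forward(spikes)
        c1 = ConvLayer(w1, stride=1, padding=1)
        c2 = ConvLayer(w2, stride=1, padding=1)
        out_plain = c2.forward(c1.forward(spikes))
        assert np.array_equal(out_block, out_plain)

    def test_identity_skip_dominates_when_main_is_zero(self, rng):
        w1 = np.zeros((2, 2, 3, 3))
        w2 = np.zeros((2, 2, 3, 3))
        spikes = np.ones((3, 1, 2, 4, 4), dtype=np.int8)  # strong input
        block = ResidualBlock(w1, w2, None, stride=1, params=NeuronParams(v_th=0.5))
        out = block.forward(spikes)
        # each step's skip current is 1 > v_th: output follows the input
        assert np.array_equal(out, spikes)

    def test_stride_two_halves_spatial_dims(self, rng):
        w1 = rng.normal(0, 0.5, (4, 2, 3, 3))
        w2 = rng.normal(0, 0.5, (4, 4, 3, 3))
        w_skip = rng.normal(0, 0.5, (4, 2, 1, 1))
        block = ResidualBlock(w1, w2, w_skip, stride=2)
        out = block.forward(self._spikes(rng, H=8, W=8))
        assert out.shape == (4, 1, 4, 4, 4)

    def test_identity_skip_requires_matching_channels(self):
        with pytest.raises(ValueError, match="identity"):
            ResidualBlock(np.zeros((3, 2, 3, 3)), np.zeros((3, 3, 3, 3)),
                          None, stride=1)


@pytest.mark.parametrize("layer_factory", [
    lambda: ConvLayer(np.ones((2, 1, 3, 3)), padding=1),
    lambda: FCLayer(np.ones((4, 9))),
    lambda: AvgPoolLayer(),
])
def test_all_zero_input_gives_all_zero_output(layer_factory):
    layer = layer_factory()
    if isinstance(layer, FCLayer):
        spikes = np.zeros((5, 2, 9), dtype=np.int8)
    else:
        spikes = np.zeros((5, 2, 1, 6, 6), dtype=np.int8)
    assert not layer.forward(spikes).any()
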