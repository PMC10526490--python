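"""Network building blocks: deformable convolution against brute-force
oracles, the adaptive channel-attention kernel rule, and BiGRU symmetry."""

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st
from scipy import signal

from eegdcn.nn import (
    BiGRU,
    DeformableConv2d,
    ECABlock,
    ECAConfig,
    GRU,
    Tensor,
    bigru_forward,
    eca_kernel_size,
)
from eegdcn.nn import functional as F


def standard_conv_oracle(x, w, pad=1):
    """Brute-force standard convolution via scipy, independent of the package path."""
    B, C, H, W = x.shape
    O = w.shape[0]
    out = np.zeros((B, O, H + 2 * pad - w.shape[2] + 1, W + 2 * pad - w.shape[3] + 1))
    for b in range(B):
        for o in range(O):
            for c in range(C):
                out[b, o] += signal.correlate(np.pad(x[b, c], pad), w[o, c], mode="valid")
    return out


class TestEcaKernelSize:
    def test_paper_constants_c512(self):
        # (log2(512) + 1) / 2 = 5
        assert eca_kernel_size(512) == 5

    def test_smallest_case(self):
        assert eca_kernel_size(2) == 1

    def test_halfway_rounds_down(self):
        # C=64 -> raw 3.5, nearest odd below chosen
        assert eca_kernel_size(64) == 3

    def test_invalid_channel_count(self):
        with pytest.raises(ValueError):
            eca_kernel_size(0)

    def test_odd_and_nondecreasing_up_to_4096(self):
        ks = [eca_kernel_size(c) for c in range(1, 4097)]
        assert all(k % 2 == 1 and k >= 1 for k in ks)
        assert all(b >= a for a, b in zip(ks, ks[1:]))

    @given(c=st.integers(1, 10000))
    @hsettings(max_examples=50, deadline=None)
    def test_within_one_of_raw_value(self, c):
        import math

        raw = (math.log2(c) + 1.0) / 2.0
        assert abs(eca_kernel_size(c) - raw) <= 1.0 or eca_kernel_size(c) == 1


class TestECABlock:
    def test_shape_preserved(self, rng):
        block = ECABlock(8, rng)
        x = Tensor(rng.normal(size=(3, 8, 5, 5)))
        assert block(x).data.shape == (3, 8, 5, 5)

    def test_gate_strictly_in_unit_interval(self, rng):
        block = ECABlock(16, rng)
        gate = block.gate_values(Tensor(rng.normal(size=(4, 16, 3, 3)) * 5))
        assert np.all(gate > 0) and np.all(gate < 1)

    def test_saturated_gate_limit_doubles_input(self, rng):
        # huge positive conv weights + positive input -> gate -> 1, residual output -> 2x
        block = ECABlock(4, rng, ECAConfig(residual=True))
        block.weight.data = np.full_like(block.weight.data, 1e4)
        x = np.abs(rng.normal(size=(2, 4, 3, 3))) + 0.5
        out = block(Tensor(x)).data
        np.testing.assert_allclose(out, 2 * x, rtol=1e-9)

    def test_residual_flag(self, rng):
        x = np.abs(rng.normal(size=(1, 4, 2, 2))) + 0.5
        with_res = ECABlock(4, rng, ECAConfig(residual=True))
        without = ECABlock(4, rng, ECAConfig(residual=False))
        without.weight.data = with_res.weight.data.copy()
        np.testing.assert_allclose(
            with_res(Tensor(x)).data - without(Tensor(x)).data, x, atol=1e-12
        )

    def test_channel_mismatch_rejected(self, rng):
        block = ECABlock(8, rng)
        with pytest.raises(ValueError, match="channels"):
            block(Tensor(np.zeros((1, 4, 2, 2))))


class TestBilinearSample:
    def test_integer_position_exact(self):
        x = np.arange(12.0).reshape(3, 4)
        assert F.bilinear_sample(x, (1, 2)) == 6.0

    def test_patch_center_is_mean(self):
        x = np.array([[1.0, 3.0], [5.0, 7.0]])
        assert F.bilinear_sample(x, (0.5, 0.5)) == pytest.approx(4.0)

    def test_far_outside_is_zero(self):
        x = np.ones((3, 3))
        assert F.bilinear_sample(x, (100.0, -50.0)) == 0.0

    def test_halfway_off_edge(self):
        x = np.ones((2, 2))
        # halfway outside the top edge: one valid corner pair at weight 0.5
        assert F.bilinear_sample(x, (-0.5, 0.5)) == pytest.approx(0.5)


class TestDeformableConv:
    def test_zero_offsets_equal_standard_conv_50_cases(self, rng):
        for _ in range(50):
            B, C, O = rng.integers(1, 3), rng.integers(1, 4), rng.integers(1, 4)
            H, W = rng.integers(4, 9), rng.integers(4, 9)
            x = rng.normal(size=(B, C, H, W))
            w = rng.normal(size=(O, C, 3, 3))
            off = np.zeros((B, 18, H, W))
            out = F.deform_conv2d(Tensor(x), Tensor(off), Tensor(w), stride=1, pad=1).data
            np.testing.assert_allclose(out, standard_conv_oracle(x, w), atol=1e-5)

    def test_integer_offset_equals_shifted_convolution(self, rng):
        # all taps displaced by (0, 1): equivalent to convolving the input
        # shifted one column left, away from the right border
        x = rng.normal(size=(1, 2, 6, 7))
        w = rng.normal(size=(2, 2, 3, 3))
        off = np.zeros((1, 18, 6, 7))
        off[:, 1::2] = 1.0  # dx = +1 for every tap
        out = F.deform_conv2d(Tensor(x), Tensor(off), Tensor(w), stride=1, pad=1).data
        shifted = np.zeros_like(x)
        shifted[:, :, :, :-1] = x[:, :, :, 1:]
        expected = standard_conv_oracle(shifted, w)
        # away from the left border, where the zero-filled shift and the
        # zero-padded out-of-bounds convention differ
        np.testing.assert_allclose(out[:, :, :, 1:], expected[:, :, :, 1:], atol=1e-5)

    def test_half_pixel_offset_one_hot_kernel(self):
        # kernel selecting only the center tap, displaced by (0, 0.5):
        # output is the mean of the two horizontally adjacent pixels
        x = np.arange(25.0).reshape(1, 1, 5, 5)
        w = np.zeros((1, 1, 3, 3))
        w[0, 0, 1, 1] = 1.0
        off = np.zeros((1, 18, 5, 5))
        off[:, 2 * 4 + 1] = 0.5  # center tap is element 4 in row-major order
        out = F.deform_conv2d(Tensor(x), Tensor(off), Tensor(w), stride=1, pad=1).data
        interior = out[0, 0, 1:-1, 1:-1]
        expected = 0.5 * (x[0, 0, 1:-1, 1:-1] + x[0, 0, 1:-1, 2:])
        np.testing.assert_allclose(interior, expected, atol=1e-10)

    def test_wrong_offset_channel_count_rejected(self, rng):
        with pytest.raises(ValueError, match="18"):
            F.deform_conv2d(
                Tensor(np.zeros((1, 1, 4, 4))),
                Tensor(np.zeros((1, 8, 4, 4))),
                Tensor(np.zeros((1, 1, 3, 3))),
            )

    def test_gradients_vs_finite_difference(self, rng):
        from test_autodiff import check_grads

        x = rng.normal(size=(1, 2, 5, 5))
        off = rng.normal(size=(1, 18, 5, 5)) * 0.3
        w = rng.normal(size=(2, 2, 3, 3))
        check_grads(
            lambda xx, oo, ww: F.deform_conv2d(xx, oo, ww, stride=1, pad=1), x, off, w, atol=1e-4
        )

    def test_strided_gradients(self, rng):
        from test_autodiff import check_grads

        x = rng.normal(size=(1, 1, 5, 5))
        off = rng.normal(size=(1, 18, 3, 3)) * 0.3
        w = rng.normal(size=(1, 1, 3, 3))
        check_grads(
            lambda xx, oo, ww: F.deform_conv2d(xx, oo, ww, stride=2, pad=1), x, off, w, atol=1e-4
        )

    def test_layer_zero_init_matches_plain_conv(self, rng):
        layer = DeformableConv2d(3, 4, rng, stride=2, pad=1)
        x = Tensor(rng.normal(size=(2, 3, 9, 9)))
        deformed = layer(x).data
        layer.use_offsets = False
        np.testing.assert_allclose(deformed, layer(x).data, atol=1e-12)


class TestFpnShapeLaw:
    @given(
        n=st.integers(3, 16),
        p=st.integers(0, 2),
        f=st.sampled_from([1, 3, 5]),
        s=st.integers(1, 3),
    )
    @hsettings(max_examples=40, deadline=None)
    def test_realized_conv_shapes_match_formula(self, n, p, f, s, ):
        if f > n + 2 * p:
            return
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, 1, n, n))
        w = rng.normal(size=(1, 1, f, f))
        out = F.conv2d(Tensor(x), Tensor(w), stride=s, pad=p).data
        m = (n + 2 * p - f) // s + 1
        assert out.shape[2:] == (m, m)

    def test_shape_preserving_case(self):
        # s=1, p=(f-1)/2 -> m = n
        assert F.conv_output_size(9, 1, 3, 1) == 9
        assert F.conv_output_size(5, 2, 5, 1) == 5

    def test_downsample_9_to_5(self):
        assert F.conv_output_size(9, 1, 3, 2) == 5


class TestGru:
    def test_output_width_and_length(self, rng):
        gru = BiGRU(3, 5, rng)
        seq = rng.normal(size=(4, 2, 3))
        out = bigru_forward(seq, gru)
        assert out.shape == (4, 2, 10)

    def test_empty_sequence_rejected(self, rng):
        with pytest.raises(ValueError):
            GRU(2, 2, rng)([])

    def test_direction_symmetry(self, rng):
        # reversing the input and swapping directional weights reproduces the
        # original output reversed (with the two halves swapped)
        layer = BiGRU(3, 4, rng)
        seq = rng.normal(size=(5, 2, 3))
        original = bigru_forward(seq, layer)
        layer.swap_directions()
        swapped = bigru_forward(seq[::-1], layer)
        np.testing.assert_allclose(swapped[::-1, :, 4:], original[:, :, :4], atol=1e-5)
        np.testing.assert_allclose(swapped[::-1, :, :4], original[:, :, 4:], atol=1e-5)

    def test_single_step_sequence(self, rng):
        layer = BiGRU(3, 4, rng)
        out = bigru_forward(rng.normal(size=(1, 2, 3)), layer)
        assert out.shape == (1, 2, 8)

    def test_gradients_flow_through_gru(self, rng):
        gru = GRU(2, 3, rng)
        steps = [Tensor(rng.normal(size=(2, 2))) for _ in range(3)]
        out = gru(steps)
        out[-1].sum().backward()
        assert all(p.grad is not None for p in gru.parameters())
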