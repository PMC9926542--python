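"""Transformer block composition and the gated convolution block."""

import numpy as np
import pytest
from scipy.ndimage import convolve
from scipy.special import erf

from swinunet3d import MLP, ConvBlock3D, SwinBlock3D, WindowSpec
from swinunet3d.blocks import DepthwiseConv3D
from swinunet3d.nn import Tensor


def np_layernorm(x, eps=1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps)


class TestMLP:
    def test_zero_weights_give_zero_output(self, rng):
        m = MLP(6, rng, ratio=2.0)
        for p in m.parameters():
            p.data[...] = 0.0
        out = m(Tensor(rng.normal(size=(3, 6)).astype(np.float32)))
        assert not out.data.any()

    def test_shape_preserved(self, rng):
        m = MLP(6, rng)
        x = rng.normal(size=(2, 5, 6)).astype(np.float32)
        assert m(Tensor(x)).shape == x.shape

    def test_matches_hand_computed_composition(self, rng):
        m = MLP(2, rng, ratio=2.0)
        x = rng.normal(size=(1, 2)).astype(np.float32)
        out = m(Tensor(x)).data
        h = x @ m.fc1.weight.data + m.fc1.bias.data
        h = h * 0.5 * (1.0 + erf(h / np.sqrt(2.0)))  # exact GELU
        expected = h @ m.fc2.weight.data + m.fc2.bias.data
        assert np.allclose(out, expected, atol=1e-6)


class TestSwinBlock:
    def test_shape_preserved(self, rng):
        blk = SwinBlock3D(8, 2, rng, rel_pos_bias=False)
        x = rng.normal(size=(1, 4, 4, 4, 8)).astype(np.float32)
        out = blk(Tensor(x), WindowSpec.half_shift((2, 2, 2)))
        assert out.shape == x.shape

    def test_zeroed_submodules_leave_pure_norm_chain(self, rng):
        """With attention and MLP weights zeroed the block is LN4∘LN3∘LN2∘LN1."""
        blk = SwinBlock3D(8, 2, rng, rel_pos_bias=True)
        for name, p in blk.named_parameters():
            if name.startswith(("attn", "mlp")):
                p.data[...] = 0.0
        x = rng.normal(size=(1, 2, 2, 2, 8)).astype(np.float32)
        out = blk(Tensor(x), WindowSpec((2, 2, 2))).data
        expected = np_layernorm(np_layernorm(np_layernorm(np_layernorm(x))))
        assert np.allclose(out, expected, atol=1e-4)

    def test_identity_residual_mode_keeps_plain_skip(self, rng):
        blk = SwinBlock3D(8, 2, rng, rel_pos_bias=False, residual="identity")
        for name, p in blk.named_parameters():
            if name.startswith(("attn", "mlp")):
                p.data[...] = 0.0
        x = rng.normal(size=(1, 2, 2, 2, 8)).astype(np.float32)
        out = blk(Tensor(x), WindowSpec((2, 2, 2))).data
        assert np.allclose(out, x, atol=1e-5)  # zero branches, skip carries x

    def test_gradient_reaches_every_parameter(self, rng):
        blk = SwinBlock3D(8, 2, rng, rel_pos_bias=True, max_window=(2, 2, 2))
        x = Tensor(rng.normal(size=(1, 4, 4, 4, 8)).astype(np.float32))
        out = blk(x, WindowSpec.half_shift((2, 2, 2)))
        (out * out).sum().backward()
        dead = [n for n, p in blk.named_parameters() if p.grad is None]
        assert dead == []

    def test_invalid_residual_mode_rejected(self, rng):
        with pytest.raises(ValueError):
            SwinBlock3D(8, 2, rng, residual="post")


class TestConvBlock:
    def _force_branch_constant(self, blk, value):
        # zero the second round's affine path so LN sees zeros, then steer
        # its beta to the desired constant (PReLU keeps positives)
        blk.pw2.weight.data[...] = 0.0
        blk.pw2.bias.data[...] = 0.0
        blk.dw2.weight.data[...] = 0.0
        blk.dw2.bias.data[...] = 0.0
        blk.ln2.beta.data[...] = value

    def test_all_ones_branch_is_multiplicative_identity(self, rng):
        blk = ConvBlock3D(5, rng)
        self._force_branch_constant(blk, 1.0)
        x = rng.normal(size=(1, 4, 4, 4, 5)).astype(np.float32)
        assert np.allclose(blk(Tensor(x)).data, x, atol=1e-6)

    def test_all_zero_branch_annihilates(self, rng):
        blk = ConvBlock3D(5, rng)
        self._force_branch_constant(blk, 0.0)
        x = rng.normal(size=(1, 4, 4, 4, 5)).astype(np.float32)
        assert not blk(Tensor(x)).data.any()

    def test_output_is_hadamard_of_branch_and_input(self, rng):
        blk = ConvBlock3D(6, rng)
        x = rng.normal(size=(1, 2, 2, 2, 6)).astype(np.float32)
        branch = blk.gating_branch(Tensor(x)).data
        assert np.allclose(blk(Tensor(x)).data, branch * x, atol=1e-6)

    def test_shape_preserved_larger_volume(self, rng):
        blk = ConvBlock3D(16, rng, kernel=3)
        x = rng.normal(size=(1, 8, 8, 8, 16)).astype(np.float32)
        assert blk(Tensor(x)).shape == x.shape


class TestDepthwiseConv:
    def test_k1_is_per_channel_affine(self, rng):
        dw = DepthwiseConv3D(4, 1, rng)
        x = rng.normal(size=(1, 3, 3, 3, 4)).astype(np.float32)
        out = dw(Tensor(x)).data
        assert np.allclose(out, x * dw.weight.data[0] + dw.bias.data, atol=1e-6)

    def test_k3_matches_scipy_convolve(self, rng):
        dw = DepthwiseConv3D(2, 3, rng)
        x = rng.normal(size=(1, 5, 6, 5, 2)).astype(np.float32)
        out = dw(Tensor(x)).data
        for c in range(2):
            kernel = dw.weight.data[:, c].reshape(3, 3, 3)
            expected = convolve(x[0, ..., c], kernel, mode="constant") + dw.bias.data[c]
            assert np.allclose(out[0, ..., c], expected, atol=1e-4)

    def test_even_kernel_rejected(self, rng):
        with pytest.raises(ValueError):
            DepthwiseConv3D(4, 2, rng)
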