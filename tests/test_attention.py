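"""Window attention against explicit-loop oracles and its invariants."""

import numpy as np
import pytest

from oracles import naive_global_attention, restricted_attention_volume
from swinunet3d import (
    MASK_PENALTY,
    ShapeError,
    WindowAttention,
    WindowSpec,
    scaled_window_attention,
    sw_msa_3d,
    w_msa_3d,
)


def make_attention(rng, dim=8, heads=2, **kw):
    kw.setdefault("rel_pos_bias", False)
    return WindowAttention(dim, heads, rng, **kw)


class TestScaledWindowAttention:
    def test_single_token_window_reduces_to_value_path(self, rng):
        """With T=1 the softmax weight is 1, so Q/K cannot matter."""
        att = make_attention(rng)
        x = rng.normal(size=(3, 1, 8)).astype(np.float32)
        out = att(x, window=(1, 1, 1))
        v = x @ att.v_proj.weight.data + att.v_proj.bias.data
        expected = v @ att.out_proj.weight.data + att.out_proj.bias.data
        assert np.allclose(np.asarray(out.data), expected, atol=1e-5)

    def test_matches_naive_global_attention(self, rng):
        att = make_attention(rng, dim=12, heads=3)
        tokens = rng.normal(size=(1, 27, 12)).astype(np.float32)
        out = scaled_window_attention(tokens, att, window=(3, 3, 3))
        expected = naive_global_attention(att, tokens[0].astype(np.float64))
        assert np.abs(np.asarray(out.data)[0] - expected).max() < 1e-5

    def test_masked_pair_weight_underflows(self, rng):
        att = make_attention(rng)
        x = rng.normal(size=(1, 1, 8, 8)).astype(np.float32)
        mask = np.zeros((1, 8, 8), dtype=np.float32)
        a, b = 2, 5
        mask[0, a, b] = mask[0, b, a] = -MASK_PENALTY
        _, weights = att(x, window=(2, 2, 2), mask=mask, return_weights=True)
        row = weights[0, 0, :, a, :]
        assert (row[:, b] < 1e-3 * row.max(axis=1)).all()

    def test_rows_sum_to_one_masked_and_unmasked(self, rng):
        att = make_attention(rng, rel_pos_bias=True)
        x = rng.normal(size=(2, 4, 8, 8)).astype(np.float32)
        mask = np.zeros((4, 8, 8), dtype=np.float32)
        mask[:, 0, 1:4] = -MASK_PENALTY
        for m in (None, mask):
            _, weights = att(x, window=(2, 2, 2), mask=m, return_weights=True)
            assert np.allclose(weights.sum(axis=-1), 1.0, atol=1e-5)

    def test_mask_shape_mismatch_rejected(self, rng):
        att = make_attention(rng)
        x = rng.normal(size=(1, 2, 8, 8)).astype(np.float32)
        with pytest.raises(ShapeError):
            att(x, window=(2, 2, 2), mask=np.zeros((2, 4, 4), dtype=np.float32))

    def test_permutation_equivariance_within_window(self, rng):
        att = make_attention(rng)
        x = rng.normal(size=(1, 2, 8, 8)).astype(np.float32)
        perm = rng.permutation(8)
        out = np.asarray(att(x, window=(2, 2, 2)).data)
        out_perm = np.asarray(att(x[:, :, perm, :], window=(2, 2, 2)).data)
        assert np.allclose(out[:, :, perm, :], out_perm, atol=1e-5)


class TestWMSA:
    def test_whole_volume_window_equals_global_attention(self, rng):
        att = make_attention(rng, dim=8, heads=2)
        x = rng.normal(size=(1, 2, 2, 2, 8)).astype(np.float32)
        out = w_msa_3d(x, WindowSpec((2, 2, 2)), att)
        expected = naive_global_attention(
            att, x.reshape(8, 8).astype(np.float64)).reshape(1, 2, 2, 2, 8)
        assert np.abs(out - expected).max() < 1e-5

    def test_locality_across_windows(self, rng):
        """Permuting window 2's contents leaves window 1's output unchanged."""
        att = make_attention(rng)
        x = rng.normal(size=(1, 4, 2, 2, 8)).astype(np.float32)
        y = w_msa_3d(x, WindowSpec((2, 2, 2)), att)
        x2 = x.copy()
        x2[0, 2:4] = x2[0, 2:4, ::-1]  # scramble only the second window
        y2 = w_msa_3d(x2, WindowSpec((2, 2, 2)), att)
        assert np.allclose(y[0, :2], y2[0, :2], atol=1e-6)
        assert not np.allclose(y[0, 2:], y2[0, 2:], atol=1e-6)

    def test_shape_preserved(self, rng):
        att = make_attention(rng, rel_pos_bias=True)
        x = rng.normal(size=(2, 4, 4, 4, 8)).astype(np.float32)
        assert w_msa_3d(x, WindowSpec((2, 2, 2)), att).shape == x.shape


class TestSWMSA:
    def test_zero_shift_equals_unshifted(self, rng):
        att = make_attention(rng, rel_pos_bias=True)
        x = rng.normal(size=(1, 4, 4, 4, 8)).astype(np.float32)
        spec = WindowSpec((2, 2, 2), (0, 0, 0))
        assert np.array_equal(sw_msa_3d(x, spec, att), w_msa_3d(x, spec, att))

    def test_matches_restricted_bruteforce(self, rng):
        att = make_attention(rng, dim=8, heads=2)
        x = rng.normal(size=(1, 4, 4, 4, 8)).astype(np.float32)
        spec = WindowSpec((2, 2, 2), (1, 1, 1))
        out = sw_msa_3d(x, spec, att)
        expected = restricted_attention_volume(
            att, x[0].astype(np.float64), spec.window, spec.shift)
        assert np.abs(out[0] - expected).max() < 1e-5

    def test_finite_on_zero_input(self, rng):
        att = make_attention(rng, rel_pos_bias=True)
        x = np.zeros((1, 4, 4, 4, 8), dtype=np.float32)
        out = sw_msa_3d(x, WindowSpec.half_shift((2, 2, 2)), att)
        assert np.isfinite(out).all()


def test_bias_table_rejects_window_larger_than_table(rng):
    att = make_attention(rng, rel_pos_bias=True, max_window=(2, 2, 2))
    x = rng.normal(size=(1, 4, 4, 4, 8)).astype(np.float32)
    with pytest.raises(ShapeError, match="max window"):
        w_msa_3d(x, WindowSpec((4, 4, 4)), att)


def test_decoupled_head_dim_changes_inner_width(rng):
    att = WindowAttention(8, 3, rng, head_dim=4, rel_pos_bias=False)
    assert att.inner == 12
    x = rng.normal(size=(1, 2, 2, 2, 8)).astype(np.float32)
    assert w_msa_3d(x, WindowSpec((2, 2, 2)), att).shape == x.shape
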