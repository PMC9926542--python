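"""Window partitioning, cyclic shifts and the shifted-window mask."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import allowed_pairs_bruteforce
from swinunet3d import (
    MASK_PENALTY,
    ShapeError,
    WindowSpec,
    build_shift_mask,
    cyclic_shift,
    partition_windows,
    reverse_windows,
)


def _volume(rng, dims, c=3):
    return rng.normal(size=(1,) + tuple(dims) + (c,)).astype(np.float32)


class TestWindowSpec:
    def test_shift_must_be_smaller_than_window(self):
        with pytest.raises(ValueError, match="shift"):
            WindowSpec((2, 2, 2), (2, 0, 0))
        with pytest.raises(ValueError):
            WindowSpec((0, 2, 2))

    def test_half_shift(self):
        assert WindowSpec.half_shift((4, 2, 1)).shift == (2, 1, 0)


class TestPartition:
    def test_counts_8_cube_window_4(self, rng):
        wt = partition_windows(_volume(rng, (8, 8, 8)), WindowSpec((4, 4, 4)))
        assert wt.data.shape[1:3] == (8, 64)
        assert wt.n_windows == 8 and wt.tokens_per_window == 64

    def test_identity_window_single_window(self, rng):
        x = _volume(rng, (4, 2, 6))
        wt = partition_windows(x, WindowSpec((4, 2, 6)))
        assert wt.data.shape[1] == 1
        assert wt.data.shape[2] == 4 * 2 * 6

    def test_divisibility_error_names_axis(self, rng):
        with pytest.raises(ShapeError, match="axis 1"):
            partition_windows(_volume(rng, (4, 6, 4)), WindowSpec((2, 4, 2)))

    def test_round_trip_exact(self, rng):
        x = _volume(rng, (4, 8, 4))
        spec = WindowSpec((2, 2, 2))
        assert np.array_equal(reverse_windows(partition_windows(x, spec), spec), x)

    def test_value_multiset_conserved(self, rng):
        x = _volume(rng, (4, 4, 8))
        wt = partition_windows(x, WindowSpec((2, 4, 2)))
        assert np.array_equal(np.sort(wt.data.ravel()), np.sort(x.ravel()))

    def test_reverse_rejects_inconsistent_metadata(self, rng):
        spec = WindowSpec((2, 2, 2))
        wt = partition_windows(_volume(rng, (4, 4, 4)), spec)
        wt.origin_dims = (8, 4, 4)
        with pytest.raises(ShapeError):
            reverse_windows(wt, spec)

    def test_reverse_rejects_window_mismatch(self, rng):
        wt = partition_windows(_volume(rng, (4, 4, 4)), WindowSpec((2, 2, 2)))
        with pytest.raises(ShapeError, match="window"):
            reverse_windows(wt, WindowSpec((4, 4, 4)))


class TestCyclicShift:
    def test_zero_shift_is_identity(self, rng):
        x = _volume(rng, (4, 4, 4))
        assert cyclic_shift(x, (0, 0, 0), "forward") is x

    def test_forward_then_inverse_restores(self, rng):
        x = _volume(rng, (4, 8, 8))
        y = cyclic_shift(cyclic_shift(x, (1, 2, 3), "forward"), (1, 2, 3), "inverse")
        assert np.array_equal(y, x)

    def test_forward_rolls_toward_origin(self):
        # 1D-like volume holding [a, b, c, d]: forward shift 1 -> [b, c, d, a]
        x = np.arange(4, dtype=np.float32).reshape(1, 4, 1, 1, 1)
        y = cyclic_shift(x, (1, 0, 0), "forward")
        assert y[0, :, 0, 0, 0].tolist() == [1, 2, 3, 0]

    def test_out_of_range_shift_rejected(self, rng):
        with pytest.raises(ShapeError):
            cyclic_shift(_volume(rng, (4, 4, 4)), (4, 0, 0), "forward")

    def test_unknown_direction_rejected(self, rng):
        with pytest.raises(ValueError):
            cyclic_shift(_volume(rng, (4, 4, 4)), (1, 0, 0), "sideways")


class TestShiftMask:
    def test_zero_shift_gives_all_zero_mask(self):
        mask = build_shift_mask((4, 4, 4), WindowSpec((2, 2, 2)))
        assert mask.shape == (8, 8, 8)
        assert not mask.any()

    def test_1d_example_masks_cross_region_pairs(self):
        # dims (4,1,1), window (2,1,1), shift (1,0,0): shifted windows hold
        # original voxels {1,2} and {3,0}, both straddling a region border,
        # so only the diagonal survives in each window.
        mask = build_shift_mask((4, 1, 1), WindowSpec((2, 1, 1), (1, 0, 0)))
        expected = np.array([[0.0, -MASK_PENALTY], [-MASK_PENALTY, 0.0]], dtype=np.float32)
        assert mask.shape == (2, 2, 2)
        for w in range(2):
            assert np.array_equal(mask[w], expected)

    @given(
        nh=st.integers(1, 2), nw=st.integers(1, 2), nd=st.integers(1, 2),
        wh=st.sampled_from([1, 2, 3]), ww=st.sampled_from([1, 2]),
        wd=st.sampled_from([1, 2]),
    )
    def test_mask_symmetric_zero_diagonal(self, nh, nw, nd, wh, ww, wd):
        dims = (nh * wh, nw * ww, nd * wd)
        window = (wh, ww, wd)
        spec = WindowSpec(window, tuple(w // 2 for w in window))
        mask = build_shift_mask(dims, spec)
        assert np.array_equal(mask, np.swapaxes(mask, 1, 2))
        t = mask.shape[1]
        assert not mask[:, np.arange(t), np.arange(t)].any()

    def test_half_shift_on_two_windows_masks_something(self):
        spec = WindowSpec.half_shift((2, 2, 2))
        mask = build_shift_mask((4, 4, 4), spec)
        assert (mask == -MASK_PENALTY).any()

    @given(
        nh=st.integers(1, 2), nw=st.integers(1, 2), nd=st.integers(1, 2),
        wh=st.sampled_from([1, 2, 3]), ww=st.sampled_from([1, 2]),
        wd=st.sampled_from([2, 3]),
        sh=st.integers(0, 2), sw=st.integers(0, 1), sd=st.integers(0, 2),
    )
    def test_mask_matches_bruteforce_region_tracking(self, nh, nw, nd, wh, ww, wd,
                                                     sh, sw, sd):
        window = (wh, ww, wd)
        shift = (sh % wh, sw % ww, sd % wd)
        dims = (nh * wh, nw * ww, nd * wd)
        mask = build_shift_mask(dims, WindowSpec(window, shift))
        got = {(w, a, b) for w, a, b in zip(*np.nonzero(mask == 0.0))}
        assert got == allowed_pairs_bruteforce(dims, window, shift)


def test_partition_reverse_round_trip_randomised(rng):
    for _ in range(20):
        window = tuple(int(rng.integers(1, 4)) for _ in range(3))
        reps = tuple(int(rng.integers(1, 4)) for _ in range(3))
        dims = tuple(w * r for w, r in zip(window, reps))
        x = _volume(rng, dims, c=int(rng.integers(1, 5)))
        spec = WindowSpec(window)
        assert np.array_equal(reverse_windows(partition_windows(x, spec), spec), x)
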