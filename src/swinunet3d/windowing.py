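"""Window bookkeeping for 3D shifted-window attention.

Feature volumes are rank-5 arrays ``[batch, H, W, D, C]``.  Windows and the
tokens inside them are always enumerated in row-major order over
``(H/wh, W/ww, D/wd)`` and ``(wh, ww, wd)`` respectively — partitioning, the
shift mask and the inverse stitch all share this order.

Operations accept either plain ``numpy`` arrays or autodiff ``Tensor``s; the
model forward path uses the latter, tests and inference mostly the former.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

#: Additive penalty for forbidden attention pairs.  Finite (not -inf) so the
#: softmax underflows to ~0 without risking NaN propagation.
MASK_PENALTY = 1.0e4


class ShapeError(ValueError):
    """Raised when a volume is not compatible with the requested windowing."""


@dataclass(frozen=True)
class WindowSpec:
    """Per-axis window sizes and cyclic-shift sizes (voxels)."""

    window: tuple[int, int, int]
    shift: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self):
        if len(self.window) != 3 or len(self.shift) != 3:
            raise ValueError("window and shift must be 3-tuples")
        for w, s in zip(self.window, self.shift):
            if w < 1:
                raise ValueError(f"window size must be >= 1, got {w}")
            if not 0 <= s < w:
                raise ValueError(f"shift must lie in [0, window), got shift={s} window={w}")

    @classmethod
    def half_shift(cls, window: tuple[int, int, int]) -> "WindowSpec":
        """The default shifted spec: shift = floor(window / 2) per axis."""
        return cls(tuple(window), tuple(w // 2 for w in window))

    @property
    def has_shift(self) -> bool:
        return any(s > 0 for s in self.shift)


@dataclass
class WindowedTokens:
    """Tokens regrouped by window: ``data`` is ``[batch, nWindows, T, C]``."""

    data: np.ndarray | Tensor
    origin_dims: tuple[int, int, int]
    window: tuple[int, int, int]

    @property
    def n_windows(self) -> int:
        return int(np.prod([d // w for d, w in zip(self.origin_dims, self.window)]))

    @property
    def tokens_per_window(self) -> int:
        return int(np.prod(self.window))


def _spatial_dims(x) -> tuple[int, int, int]:
    if x.ndim != 5:
        raise ShapeError(f"expected rank-5 [batch, H, W, D, C] volume, got shape {x.shape}")
    return x.shape[1:4]


def _check_divisible(dims: tuple[int, int, int], window: tuple[int, int, int]) -> None:
    for axis, (d, w) in enumerate(zip(dims, window)):
        if d % w != 0:
            raise ShapeError(
                f"spatial axis {axis} of size {d} is not divisible by window size {w}"
            )


def _reshape(x, shape):
    return x.reshape(shape) if isinstance(x, Tensor) else np.reshape(x, shape)


def _transpose(x, axes):
    return x.transpose(axes) if isinstance(x, Tensor) else np.transpose(x, axes)


def partition_windows(x, spec: WindowSpec) -> WindowedTokens:
    """Regroup a ``[B, H, W, D, C]`` volume into non-overlapping windows.

    Pure re-indexing: no value is altered, token multiset is conserved.
    """
    dims = _spatial_dims(x)
    _check_divisible(dims, spec.window)
    b, c = x.shape[0], x.shape[4]
    (h, w, d), (wh, ww, wd) = dims, spec.window
    nh, nw, nd = h // wh, w // ww, d // wd
    y = _reshape(x, (b, nh, wh, nw, ww, nd, wd, c))
    y = _transpose(y, (0, 1, 3, 5, 2, 4, 6, 7))
    y = _reshape(y, (b, nh * nw * nd, wh * ww * wd, c))
    return WindowedTokens(data=y, origin_dims=tuple(dims), window=tuple(spec.window))


def reverse_windows(wt: WindowedTokens, spec: WindowSpec):
    """Exact inverse of :func:`partition_windows`."""
    if tuple(wt.window) != tuple(spec.window):
        raise ShapeError(f"window mismatch: tokens carry {wt.window}, spec has {spec.window}")
    (h, w, d), (wh, ww, wd) = wt.origin_dims, wt.window
    _check_divisible(wt.origin_dims, wt.window)
    x = wt.data
    b, c = x.shape[0], x.shape[-1]
    if x.shape[1] != wt.n_windows or x.shape[2] != wt.tokens_per_window:
        raise ShapeError(
            f"windowed data {x.shape} inconsistent with origin_dims {wt.origin_dims} "
            f"and window {wt.window}"
        )
    nh, nw, nd = h // wh, w // ww, d // wd
    y = _reshape(x, (b, nh, nw, nd, wh, ww, wd, c))
    y = _transpose(y, (0, 1, 4, 2, 5, 3, 6, 7))
    return _reshape(y, (b, h, w, d, c))


def cyclic_shift(x, shift: tuple[int, int, int], direction: str = "forward"):
    """Cyclically roll the spatial axes.

    ``forward`` moves voxel (i, j, k) to ((i-sh) mod H, (j-sw) mod W,
    (k-sd) mod D) — i.e. rolls content toward the origin, the Swin
    convention; ``inverse`` undoes it exactly.
    """
    dims = _spatial_dims(x)
    for axis, (s, d) in enumerate(zip(shift, dims)):
        if not 0 <= s < d:
            raise ShapeError(f"shift {s} out of range [0, {d}) on axis {axis}")
    if direction == "forward":
        amounts = tuple(-s for s in shift)
    elif direction == "inverse":
        amounts = tuple(shift)
    else:
        raise ValueError(f"direction must be 'forward' or 'inverse', got {direction!r}")
    if all(a == 0 for a in amounts):
        return x
    if isinstance(x, Tensor):
        return nn.roll(x, amounts, (1, 2, 3))
    return np.roll(x, amounts, axis=(1, 2, 3))


def region_ids(dims: tuple[int, int, int], spec: WindowSpec) -> np.ndarray:
    """Label every voxel with its pre-shift window id, then forward-shift.

    The returned ``[H, W, D]`` integer volume says, for each position of the
    *shifted* volume, which original window the voxel there came from.
    """
    _check_divisible(dims, spec.window)
    ids_axis = []
    for d, w in zip(dims, spec.window):
        ids_axis.append(np.arange(d) // w)
    grid = (
        ids_axis[0][:, None, None] * ((dims[1] // spec.window[1]) * (dims[2] // spec.window[2]))
        + ids_axis[1][None, :, None] * (dims[2] // spec.window[2])
        + ids_axis[2][None, None, :]
    )
    return np.roll(grid, tuple(-s for s in spec.shift), axis=(0, 1, 2))


def build_shift_mask(dims: tuple[int, int, int], spec: WindowSpec) -> np.ndarray:
    """Additive attention mask ``[nWindows, T, T]`` for the shifted pass.

    Entry (w, a, b) is 0 iff tokens a, b of shifted window w originate from
    the same pre-shift window, else ``-MASK_PENALTY``.  With zero shift the
    mask is identically zero.
    """
    ids = region_ids(dims, spec)[None, ..., None]  # fake batch/channel axes
    wt = partition_windows(ids.astype(np.float32), WindowSpec(spec.window))
    labels = wt.data[0, :, :, 0]  # [nWindows, T]
    same = labels[:, :, None] == labels[:, None, :]
    mask = np.where(same, 0.0, -MASK_PENALTY).astype(np.float32)
    return mask
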