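"""Patch embedding, merging (downsample) and expanding (upsample).

All three are non-overlapping block transforms (kernel == stride), so each
is realised exactly as a reshape to blocks plus one linear map:

* embed:  4x4x4 voxel blocks flattened and mapped to the embedding width N,
  then LayerNorm;
* merge:  2x2x2 blocks mapped C -> 2C (strided convolution), then LayerNorm;
* expand: transposed convolution with kernel = stride = factor, i.e. a
  linear map C -> factor^3 * C_out followed by block re-interleaving, then
  LayerNorm.  Factor 2 halves channels; the final factor-4 stage keeps them.
"""

from __future__ import annotations

import numpy as np

from .nn import LayerNorm, Linear, Module, Tensor
from .windowing import ShapeError, _reshape, _transpose


def _check_block_divisible(dims, k: int) -> None:
    for axis, d in enumerate(dims):
        if d % k != 0:
            raise ShapeError(f"spatial axis {axis} of size {d} not divisible by patch size {k}")


def _to_blocks(x, k: int):
    """[B, H, W, D, C] -> [B, H/k, W/k, D/k, k^3*C] by non-overlapping blocks."""
    b, h, w, d, c = x.shape
    _check_block_divisible((h, w, d), k)
    y = _reshape(x, (b, h // k, k, w // k, k, d // k, k, c))
    y = _transpose(y, (0, 1, 3, 5, 2, 4, 6, 7))
    return _reshape(y, (b, h // k, w // k, d // k, k * k * k * c))


def _from_blocks(x, k: int, out_channels: int):
    """[B, h, w, d, k^3*C] -> [B, h*k, w*k, d*k, C], inverse interleaving."""
    b, h, w, d, _ = x.shape
    y = _reshape(x, (b, h, w, d, k, k, k, out_channels))
    y = _transpose(y, (0, 1, 4, 2, 5, 3, 6, 7))
    return _reshape(y, (b, h * k, w * k, d * k, out_channels))


class PatchEmbed3D(Module):
    """Flatten non-overlapping ``patch^3`` blocks and encode each as an
    ``embed_dim``-vector (equivalently a kernel-4 stride-4 convolution)."""

    def __init__(self, in_channels: int, embed_dim: int, rng: np.random.Generator,
                 patch: int = 4):
        super().__init__()
        self.patch = patch
        self.proj = Linear(patch**3 * in_channels, embed_dim, rng)
        self.norm = LayerNorm(embed_dim)

    def forward(self, x):
        return self.norm(self.proj(_to_blocks(x, self.patch)))


class PatchMerging3D(Module):
    """Halve each spatial axis, double channels: kernel-2 stride-2 conv + LN."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        if out_channels <= in_channels:
            raise ValueError("merging must widen channels")
        self.proj = Linear(8 * in_channels, out_channels, rng)
        self.norm = LayerNorm(out_channels)

    def forward(self, x):
        return self.norm(self.proj(_to_blocks(x, 2)))


class PatchExpanding3D(Module):
    """Transposed convolution with kernel = stride = factor, then LN."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator,
                 factor: int = 2):
        super().__init__()
        if factor not in (2, 4):
            raise ValueError(f"expanding factor must be 2 or 4, got {factor}")
        self.factor = factor
        self.out_channels = out_channels
        self.proj = Linear(in_channels, factor**3 * out_channels, rng)
        self.norm = LayerNorm(out_channels)

    def forward(self, x):
        y = self.proj(x)
        y = _from_blocks(y, self.factor, self.out_channels)
        return self.norm(y)


def patch_embed(x, params: PatchEmbed3D):
    out = params(x if isinstance(x, Tensor) else Tensor(x))
    return out if isinstance(x, Tensor) else out.data


def patch_merging3d(x, params: PatchMerging3D):
    out = params(x if isinstance(x, Tensor) else Tensor(x))
    return out if isinstance(x, Tensor) else out.data


def patch_expanding3d(x, params: PatchExpanding3D):
    out = params(x if isinstance(x, Tensor) else Tensor(x))
    return out if isinstance(x, Tensor) else out.data
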