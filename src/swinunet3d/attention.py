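"""Windowed multi-head self-attention in 3D (W-MSA-3D / SW-MSA-3D).

Within every window the usual scaled dot-product attention is computed,

    attn = Softmax(Q K^T / sqrt(d_k) + B + M) V,

where B is an optional learnable relative-position bias (one table per head,
indexed by the 3D offset between the two tokens, as in the video variant of
the Swin transformer) and M is the additive shift mask (0 or a large negative
penalty).  The shifted variant rolls the volume by the spec's shift, attends
under the mask built from pre-shift window membership, and unrolls.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Linear, Module, Parameter, Tensor, trunc_normal
from .windowing import (
    ShapeError,
    WindowSpec,
    build_shift_mask,
    cyclic_shift,
    partition_windows,
    reverse_windows,
)


def relative_position_index(window: tuple[int, int, int],
                            max_window: tuple[int, int, int]) -> np.ndarray:
    """Integer index [T, T] into a flattened (2*mw-1)^3 offset table."""
    for w, m in zip(window, max_window):
        if w > m:
            raise ShapeError(f"window {window} exceeds the bias table's max window {max_window}")
    coords = np.stack(np.meshgrid(*[np.arange(w) for w in window], indexing="ij"), axis=0)
    coords = coords.reshape(3, -1)  # [3, T]
    rel = coords[:, :, None] - coords[:, None, :]  # [3, T, T] in [-(w-1), w-1]
    sizes = [2 * m - 1 for m in max_window]
    idx = (
        (rel[0] + max_window[0] - 1) * (sizes[1] * sizes[2])
        + (rel[1] + max_window[1] - 1) * sizes[2]
        + (rel[2] + max_window[2] - 1)
    )
    return idx.astype(np.int64)


class WindowAttention(Module):
    """Learnable parameters + forward pass of per-window multi-head attention.

    ``head_dim`` defaults to ``dim // heads`` (square Q/K/V projections); a
    different value decouples the inner attention width from the channel
    count.
    """

    def __init__(self, dim: int, heads: int, rng: np.random.Generator,
                 head_dim: int | None = None, qkv_bias: bool = True,
                 rel_pos_bias: bool = True, max_window: tuple[int, int, int] = (4, 4, 4),
                 attn_dropout: float = 0.0):
        super().__init__()
        if head_dim is None:
            if dim % heads != 0:
                raise ValueError(
                    f"dim {dim} not divisible by heads {heads}; pass head_dim explicitly"
                )
            head_dim = dim // heads
        self.dim = dim
        self.heads = heads
        self.head_dim = head_dim
        self.inner = heads * head_dim
        self.scale = 1.0 / float(np.sqrt(head_dim))
        self.q_proj = Linear(dim, self.inner, rng, bias=qkv_bias)
        self.k_proj = Linear(dim, self.inner, rng, bias=qkv_bias)
        self.v_proj = Linear(dim, self.inner, rng, bias=qkv_bias)
        self.out_proj = Linear(self.inner, dim, rng, bias=True)
        self.max_window = tuple(max_window)
        self.attn_dropout = attn_dropout
        self._dropout_rng = np.random.default_rng(rng.integers(0, 2**31))
        if rel_pos_bias:
            table_len = int(np.prod([2 * m - 1 for m in self.max_window]))
            self.bias_table = Parameter(trunc_normal(rng, (heads, table_len)), no_decay=True)
        else:
            self.bias_table = None
        self._index_cache: dict[tuple[int, int, int], np.ndarray] = {}

    def _bias_for(self, window: tuple[int, int, int]) -> Tensor | None:
        if self.bias_table is None:
            return None
        window = tuple(window)
        if window not in self._index_cache:
            self._index_cache[window] = relative_position_index(window, self.max_window)
        return nn.index_rows(self.bias_table, self._index_cache[window])  # [heads, T, T]

    def forward(self, tokens, window: tuple[int, int, int],
                mask: np.ndarray | None = None, return_weights: bool = False):
        """Attend within windows.

        ``tokens`` is ``[B, nW, T, C]`` (or ``[nW, T, C]``, treated as B=1);
        ``mask`` is an additive ``[nW, T, T]`` array or None.
        """
        squeeze = False
        if tokens.ndim == 3:
            tokens = tokens.reshape((1,) + tuple(tokens.shape))
            squeeze = True
        if not isinstance(tokens, Tensor):
            tokens = Tensor(tokens)
        b, nw, t, c = tokens.shape
        if c != self.dim:
            raise ShapeError(f"token channels {c} != attention dim {self.dim}")
        if mask is not None and mask.shape != (nw, t, t):
            raise ShapeError(f"mask shape {mask.shape} incompatible with tokens {(nw, t, t)}")
        if int(np.prod(window)) != t:
            raise ShapeError(f"window {window} does not produce {t} tokens per window")

        h, dh = self.heads, self.head_dim

        def split_heads(x):  # [B,nW,T,I] -> [B,nW,h,T,dh]
            return x.reshape((b, nw, t, h, dh)).transpose((0, 1, 3, 2, 4))

        q = split_heads(self.q_proj(tokens))
        k = split_heads(self.k_proj(tokens))
        v = split_heads(self.v_proj(tokens))
        scores = (q * self.scale) @ k.transpose((0, 1, 2, 4, 3))  # [B,nW,h,T,T]
        bias = self._bias_for(window)
        if bias is not None:
            scores = scores + bias.reshape((1, 1, h, t, t))
        if mask is not None:
            scores = scores + np.asarray(mask, dtype=np.float32)[None, :, None, :, :]
        weights = nn.softmax(scores, axis=-1)
        if self.attn_dropout > 0.0 and self.training:
            keep = (self._dropout_rng.random(weights.shape) >= self.attn_dropout)
            weights = weights * (keep.astype(np.float32) / (1.0 - self.attn_dropout))
        out = weights @ v  # [B,nW,h,T,dh]
        out = out.transpose((0, 1, 3, 2, 4)).reshape((b, nw, t, h * dh))
        out = self.out_proj(out)
        if squeeze:
            out = out.reshape((nw, t, self.dim))
        if return_weights:
            return out, weights.data if isinstance(weights, Tensor) else weights
        return out


#: Alias used where the parameter bundle is referred to by role.
AttentionParams = WindowAttention


def scaled_window_attention(tokens, params: WindowAttention,
                            mask: np.ndarray | None = None,
                            window: tuple[int, int, int] | None = None):
    """Functional per-window attention on ``[nWindows, T, C]`` tokens."""
    if window is None:
        t = tokens.shape[-2]
        # attention itself only needs T; reuse the bias index of a cubic
        # window when one exists, otherwise disable the bias lookup
        cube = round(t ** (1.0 / 3.0))
        window = (cube, cube, cube) if cube**3 == t else None
    if window is None:
        raise ShapeError("pass window=(wh, ww, wd) for non-cubic windows")
    return params(tokens, window=window, mask=mask)


def _match_input_kind(x, result):
    if not isinstance(x, Tensor) and isinstance(result, Tensor):
        return result.data
    return result


def w_msa_3d(x, spec: WindowSpec, params: WindowAttention):
    """Unshifted window attention: partition -> attend -> stitch back."""
    plain = WindowSpec(spec.window)  # shift ignored
    wt = partition_windows(x, plain)
    out = params(wt.data, window=plain.window, mask=None)
    merged = reverse_windows(
        type(wt)(data=out, origin_dims=wt.origin_dims, window=wt.window), plain
    )
    return _match_input_kind(x, merged)


def sw_msa_3d(x, spec: WindowSpec, params: WindowAttention):
    """Shifted, masked window attention; degenerates to W-MSA at zero shift."""
    if not spec.has_shift:
        return w_msa_3d(x, spec, params)
    dims = tuple(x.shape[1:4])
    mask = build_shift_mask(dims, spec)
    shifted = cyclic_shift(x, spec.shift, "forward")
    wt = partition_windows(shifted, WindowSpec(spec.window))
    out = params(wt.data, window=spec.window, mask=mask)
    merged = reverse_windows(
        type(wt)(data=out, origin_dims=wt.origin_dims, window=wt.window),
        WindowSpec(spec.window),
    )
    return _match_input_kind(x, cyclic_shift(merged, spec.shift, "inverse"))
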