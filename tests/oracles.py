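"""Independent brute-force references for the attention tests.

Everything here is written with explicit per-token loops against the raw
projection weights, deliberately sharing no code with the package's
vectorised window/attention path.
"""

from __future__ import annotations

import numpy as np


def _project(att, x: np.ndarray, which: str) -> np.ndarray:
    proj = getattr(att, f"{which}_proj")
    y = x @ proj.weight.data
    if proj.bias is not None:
        y = y + proj.bias.data
    return y


def naive_global_attention(att, tokens: np.ndarray) -> np.ndarray:
    """O(T^2) double-loop self-attention over one token set [T, C]."""
    t, _ = tokens.shape
    q = _project(att, tokens, "q")
    k = _project(att, tokens, "k")
    v = _project(att, tokens, "v")
    h, dh = att.heads, att.head_dim
    out_heads = np.zeros((t, h * dh), dtype=np.float64)
    for head in range(h):
        sl = slice(head * dh, (head + 1) * dh)
        for a in range(t):
            scores = np.empty(t, dtype=np.float64)
            for b in range(t):
                scores[b] = float(q[a, sl] @ k[b, sl]) / np.sqrt(dh)
            w = np.exp(scores - scores.max())
            w /= w.sum()
            out_heads[a, sl] = sum(w[b] * v[b, sl] for b in range(t))
    return out_heads @ att.out_proj.weight.data + att.out_proj.bias.data


def restricted_attention_volume(att, x: np.ndarray, window, shift) -> np.ndarray:
    """Shifted-window attention by explicit voxel bookkeeping.

    For each query voxel the allowed partners are the voxels that (a) fall
    into the same window after the cyclic shift and (b) originate from the
    same pre-shift window.  ``x`` is [H, W, D, C]; returns the same shape.
    """
    dims = x.shape[:3]
    coords = [(i, j, k) for i in range(dims[0])
              for j in range(dims[1]) for k in range(dims[2])]

    def shifted_window_id(voxel):
        pos = tuple((v - s) % d for v, s, d in zip(voxel, shift, dims))
        return tuple(p // w for p, w in zip(pos, window))

    def preshift_window_id(voxel):
        return tuple(v // w for v, w in zip(voxel, window))

    flat = x.reshape(-1, x.shape[-1])
    q = _project(att, flat, "q")
    k = _project(att, flat, "k")
    v = _project(att, flat, "v")
    index = {c: i for i, c in enumerate(coords)}
    h, dh = att.heads, att.head_dim
    out = np.zeros((len(coords), h * dh), dtype=np.float64)
    for c in coords:
        a = index[c]
        allowed = [index[u] for u in coords
                   if shifted_window_id(u) == shifted_window_id(c)
                   and preshift_window_id(u) == preshift_window_id(c)]
        for head in range(h):
            sl = slice(head * dh, (head + 1) * dh)
            scores = np.array([float(q[a, sl] @ k[b, sl]) for b in allowed]) / np.sqrt(dh)
            w = np.exp(scores - scores.max())
            w /= w.sum()
            out[a, sl] = sum(wi * v[b, sl] for wi, b in zip(w, allowed))
    out = out @ att.out_proj.weight.data + att.out_proj.bias.data
    return out.reshape(x.shape[:3] + (att.dim,))


def allowed_pairs_bruteforce(dims, window, shift) -> set[tuple[int, ...]]:
    """All (window, a, b) index triples the mask must leave unmasked,
    tracking every voxel's pre-shift window id explicitly."""
    n_ax = [d // w for d, w in zip(dims, window)]

    def window_and_slot(pos):
        wid = tuple(p // w for p, w in zip(pos, window))
        slot = tuple(p % w for p, w in zip(pos, window))
        w_flat = (wid[0] * n_ax[1] + wid[1]) * n_ax[2] + wid[2]
        s_flat = (slot[0] * window[1] + slot[1]) * window[2] + slot[2]
        return w_flat, s_flat

    entries = []  # (shifted window, slot, pre-shift window id)
    for i in range(dims[0]):
        for j in range(dims[1]):
            for k in range(dims[2]):
                voxel = (i, j, k)
                pos = tuple((v - s) % d for v, s, d in zip(voxel, shift, dims))
                w_flat, s_flat = window_and_slot(pos)
                region = tuple(v // w for v, w in zip(voxel, window))
                entries.append((w_flat, s_flat, region))
    allowed = set()
    for wa, sa, ra in entries:
        for wb, sb, rb in entries:
            if wa == wb and ra == rb:
                allowed.add((wa, sa, sb))
    return allowed
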