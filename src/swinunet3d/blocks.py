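"""Feature-extraction units: the transformer block pair and the gated conv block.

The transformer block consists of two units — one around unshifted window
attention, one around the shifted, masked variant — each followed by a
token-wise MLP:

    X1  = LN1(X)  + W-MSA-3D(LN1(X))
    X2  = LN2(X1) + MLP(LN2(X1))
    X3  = LN3(X2) + SW-MSA-3D(LN3(X2))
    out = LN4(X3) + MLP(LN4(X3))

Note the residual branch carries LN(X), not X: that is how the block is
defined here; ``residual="identity"`` switches to the conventional pre-norm
residual (X + f(LN(X))) for comparison.

The conv block runs two rounds of depthwise-separable 3D convolution ->
LayerNorm -> PReLU, then gates the input multiplicatively: Y = branch ⊙ X.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import LayerNorm, Linear, Module, Parameter, PReLU, Tensor
from .attention import WindowAttention, sw_msa_3d, w_msa_3d
from .windowing import WindowSpec


class MLP(Module):
    """Token-wise two-layer network: C -> ratio*C -> C with GELU."""

    def __init__(self, dim: int, rng: np.random.Generator, ratio: float = 4.0):
        super().__init__()
        hidden = int(round(dim * ratio))
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def forward(self, x):
        return self.fc2(nn.gelu(self.fc1(x)))


def mlp(tokens, params: "MLP"):
    """Functional form of the token-wise MLP."""
    out = params(tokens if isinstance(tokens, Tensor) else Tensor(tokens))
    return out if isinstance(tokens, Tensor) else out.data


class SwinBlock3D(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator,
                 head_dim: int | None = None, mlp_ratio: float = 4.0,
                 qkv_bias: bool = True, rel_pos_bias: bool = True,
                 max_window: tuple[int, int, int] = (4, 4, 4),
                 attn_dropout: float = 0.0, residual: str = "ln"):
        super().__init__()
        if residual not in ("ln", "identity"):
            raise ValueError(f"residual must be 'ln' or 'identity', got {residual!r}")
        self.residual = residual
        self.ln1 = LayerNorm(dim)
        self.ln2 = LayerNorm(dim)
        self.ln3 = LayerNorm(dim)
        self.ln4 = LayerNorm(dim)
        kw = dict(head_dim=head_dim, qkv_bias=qkv_bias, rel_pos_bias=rel_pos_bias,
                  max_window=max_window, attn_dropout=attn_dropout)
        self.attn_w = WindowAttention(dim, heads, rng, **kw)
        self.attn_sw = WindowAttention(dim, heads, rng, **kw)
        self.mlp1 = MLP(dim, rng, ratio=mlp_ratio)
        self.mlp2 = MLP(dim, rng, ratio=mlp_ratio)

    def _unit(self, x, norm, fn):
        nx = norm(x)
        base = nx if self.residual == "ln" else x
        return base + fn(nx)

    def forward(self, x, spec: WindowSpec):
        x = self._unit(x, self.ln1, lambda t: w_msa_3d(t, spec, self.attn_w))
        x = self._unit(x, self.ln2, self.mlp1)
        x = self._unit(x, self.ln3, lambda t: sw_msa_3d(t, spec, self.attn_sw))
        x = self._unit(x, self.ln4, self.mlp2)
        return x


def swin_block3d(x, spec: WindowSpec, params: SwinBlock3D):
    """Functional form; accepts numpy or Tensor volumes [B, H, W, D, C]."""
    out = params(x if isinstance(x, Tensor) else Tensor(x), spec)
    return out if isinstance(x, Tensor) else out.data


class DepthwiseConv3D(Module):
    """Per-channel k*k*k stride-1 convolution with zero padding (channels-last).

    k = 1 degenerates to a per-channel scale + bias; larger k is realised as
    a weighted sum over the k^3 spatially shifted copies of the input.
    """

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel < 1 or kernel % 2 == 0:
            raise ValueError(f"depthwise kernel must be odd and >= 1, got {kernel}")
        self.kernel = kernel
        fan = kernel ** 3
        self.weight = Parameter(
            rng.uniform(-1, 1, size=(fan, channels)).astype(np.float32) / np.sqrt(fan)
        )
        self.bias = Parameter(np.zeros(channels, dtype=np.float32), no_decay=True)

    def forward(self, x):
        k = self.kernel
        if k == 1:
            return x * self.weight.reshape((self.weight.shape[1],)) + self.bias
        r = k // 2
        acc = None
        i = 0
        for dz in range(-r, r + 1):
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    shifted = nn.shift_zero(x, (dz, dy, dx), (1, 2, 3))
                    term = shifted * nn.take_index(self.weight, i, axis=0)
                    acc = term if acc is None else acc + term
                    i += 1
        return acc + self.bias


class ConvBlock3D(Module):
    """Gated local-feature branch: two (depthwise sep. conv, LN, PReLU) rounds,
    output multiplied element-wise with the block input."""

    def __init__(self, channels: int, rng: np.random.Generator, kernel: int = 1):
        super().__init__()
        self.dw1 = DepthwiseConv3D(channels, kernel, rng)
        self.pw1 = Linear(channels, channels, rng)
        self.ln1 = LayerNorm(channels)
        self.act1 = PReLU(channels)
        self.dw2 = DepthwiseConv3D(channels, kernel, rng)
        self.pw2 = Linear(channels, channels, rng)
        self.ln2 = LayerNorm(channels)
        self.act2 = PReLU(channels)

    def gating_branch(self, x):
        if not isinstance(x, Tensor):
            x = Tensor(x)
        t = self.act1(self.ln1(self.pw1(self.dw1(x))))
        t = self.act2(self.ln2(self.pw2(self.dw2(t))))
        return t

    def forward(self, x):
        if not isinstance(x, Tensor):
            x = Tensor(x)
        return self.gating_branch(x) * x


def conv_block3d(x, params: ConvBlock3D):
    out = params(x if isinstance(x, Tensor) else Tensor(x))
    return out if isinstance(x, Tensor) else out.data
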