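"""Assembly of the volumetric shifted-window U-Net.

Encoder stages operate at 1/4, 1/8, 1/16 and 1/32 of the input resolution
(downsampling factors 4, 2, 2, 2).  Every stage runs a stack of transformer
blocks in parallel with a gated convolutional block on the same input and
sums the two branch outputs; the "pure" ablation variant drops the
convolutional branch.  Decoder stages upsample by 2, add the same-level
encoder output (element-wise skip), and apply the same parallel extraction.
A final factor-4 expansion restores full resolution before a linear head
produces one logit channel per class (multi-label, sigmoid at prediction
time).

The window size for attention is the input resolution divided by 32 per
axis, so inputs must be multiples of 32; the shift is half the window.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .nn import Linear, Module, ModuleList, Tensor
from .blocks import ConvBlock3D, SwinBlock3D
from .resampling import PatchEmbed3D, PatchExpanding3D, PatchMerging3D
from .windowing import ShapeError, WindowSpec


class ConfigError(ValueError):
    """Raised for an invalid model configuration; names the offending field."""


@dataclass(frozen=True)
class StageSpec:
    depth: int
    heads: int
    channels: int


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the architecture.

    Defaults give the full-size model: embedding width 96, encoder head
    schedule (3, 6, 9, 12) with per-stage channels 32x the head count
    (96, 192, 288, 384) so every Q/K/V projection is square, encoder depths
    (2, 2, 4, 2) and decoder depths (4, 4, 2) counting whole two-unit
    transformer blocks.
    """

    in_channels: int = 4
    num_classes: int = 3
    embed_dim: int = 96
    patch_size: int = 4
    depths: tuple[int, ...] = (2, 2, 4, 2)
    decoder_depths: tuple[int, ...] = (4, 4, 2)
    heads: tuple[int, ...] = (3, 6, 9, 12)
    channel_multipliers: tuple[int, ...] = (1, 2, 3, 4)
    head_dim: int | None = None
    max_window: tuple[int, int, int] = (4, 4, 4)
    mlp_ratio: float = 4.0
    use_conv_branch: bool = True
    residual: str = "ln"
    conv_kernel: int = 1
    rel_pos_bias: bool = True
    qkv_bias: bool = True
    attn_dropout: float = 0.0
    seed: int = 42

    def __post_init__(self):
        n = len(self.depths)
        if len(self.heads) != n:
            raise ConfigError(f"heads must have {n} entries (one per encoder stage)")
        if len(self.channel_multipliers) != n:
            raise ConfigError(f"channel_multipliers must have {n} entries")
        if len(self.decoder_depths) != n - 1:
            raise ConfigError(f"decoder_depths must have {n - 1} entries")
        if self.head_dim is None:
            for h, m in zip(self.heads, self.channel_multipliers):
                c = self.embed_dim * m
                if c % h != 0:
                    raise ConfigError(
                        f"heads={h} does not divide channels={c}; "
                        "set head_dim to decouple the attention width"
                    )
        if self.residual not in ("ln", "identity"):
            raise ConfigError("residual must be 'ln' or 'identity'")
        if self.patch_size != 4:
            raise ConfigError("patch_size is fixed at 4 (downsampling schedule 4,2,2,2)")

    @property
    def channels(self) -> tuple[int, ...]:
        return tuple(self.embed_dim * m for m in self.channel_multipliers)

    def encoder_stages(self) -> list[StageSpec]:
        return [StageSpec(d, h, c) for d, h, c in zip(self.depths, self.heads, self.channels)]

    def decoder_stages(self) -> list[StageSpec]:
        heads = self.heads[:-1][::-1]
        chans = self.channels[:-1][::-1]
        return [StageSpec(d, h, c) for d, h, c in zip(self.decoder_depths, heads, chans)]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("depths", "decoder_depths", "heads", "channel_multipliers", "max_window"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


class _Stage(Module):
    """One encoder or decoder stage: resample, then parallel branch extraction."""

    def __init__(self, resample: Module | None, blocks: ModuleList,
                 conv: ConvBlock3D | None, skip_add: bool):
        super().__init__()
        self.resample = resample
        self.blocks = blocks
        self.conv = conv
        self.skip_add = skip_add

    def forward(self, x, spec: WindowSpec, skip=None):
        if self.resample is not None:
            x = self.resample(x)
        if self.skip_add:
            if skip is None:
                raise ShapeError("decoder stage requires the same-level encoder output")
            x = x + skip
        y = x
        for block in self.blocks:
            y = block(y, spec)
        if self.conv is not None:
            y = y + self.conv(x)
        return y


class SwinUNet3D(Module):
    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        chans = cfg.channels

        def make_blocks(st: StageSpec) -> ModuleList:
            return ModuleList([
                SwinBlock3D(
                    st.channels, st.heads, rng, head_dim=cfg.head_dim,
                    mlp_ratio=cfg.mlp_ratio, qkv_bias=cfg.qkv_bias,
                    rel_pos_bias=cfg.rel_pos_bias, max_window=cfg.max_window,
                    attn_dropout=cfg.attn_dropout, residual=cfg.residual,
                )
                for _ in range(st.depth)
            ])

        def make_conv(channels: int) -> ConvBlock3D | None:
            if not cfg.use_conv_branch:
                return None
            return ConvBlock3D(channels, rng, kernel=cfg.conv_kernel)

        self.patch_embed = PatchEmbed3D(cfg.in_channels, chans[0], rng, cfg.patch_size)
        enc = []
        for i, st in enumerate(cfg.encoder_stages()):
            resample = None if i == 0 else PatchMerging3D(chans[i - 1], chans[i], rng)
            enc.append(_Stage(resample, make_blocks(st), make_conv(st.channels), skip_add=False))
        self.encoders = ModuleList(enc)
        dec = []
        prev_c = chans[-1]
        for st in cfg.decoder_stages():
            expand = PatchExpanding3D(prev_c, st.channels, rng, factor=2)
            dec.append(_Stage(expand, make_blocks(st), make_conv(st.channels), skip_add=True))
            prev_c = st.channels
        self.decoders = ModuleList(dec)
        self.final_expand = PatchExpanding3D(chans[0], chans[0], rng, factor=4)
        self.head = Linear(chans[0], cfg.num_classes, rng)

    # ------------------------------------------------------------------
    def _window_for(self, dims: tuple[int, int, int]) -> tuple[int, int, int]:
        for axis, d in enumerate(dims):
            if d % 32 != 0 or d < 32:
                raise ShapeError(
                    f"input spatial axis {axis} has size {d}; every axis must be a "
                    "positive multiple of 32"
                )
        window = tuple(d // 32 for d in dims)
        for axis, (w, m) in enumerate(zip(window, self.cfg.max_window)):
            if w > m:
                raise ShapeError(
                    f"axis {axis}: window {w} exceeds max_window {m}; rebuild the "
                    "model with a larger max_window for inputs this big"
                )
        return window

    def forward(self, x):
        was_numpy = not isinstance(x, Tensor)
        if was_numpy:
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim != 5 or x.shape[4] != self.cfg.in_channels:
            raise ShapeError(
                f"expected [batch, H, W, D, {self.cfg.in_channels}] input, got {x.shape}"
            )
        dims = tuple(x.shape[1:4])
        window = self._window_for(dims)

        def spec_at(token_dims):
            # disable the shift along axes with a single window (nothing to mix)
            shift = tuple(
                (w // 2 if t > w else 0) for t, w in zip(token_dims, window)
            )
            return WindowSpec(window, shift)

        p = self.cfg.patch_size
        token_dims = tuple(d // p for d in dims)
        x = self.patch_embed(x)
        skips = []
        for i, stage in enumerate(self.encoders):
            if i > 0:
                token_dims = tuple(t // 2 for t in token_dims)
            x = stage(x, spec_at(token_dims))
            skips.append(x)
        for j, stage in enumerate(self.decoders):
            token_dims = tuple(t * 2 for t in token_dims)
            x = stage(x, spec_at(token_dims), skip=skips[-2 - j])
        x = self.final_expand(x)
        logits = self.head(x)
        return logits.data if was_numpy else logits

    # ------------------------------------------------------------------
    def conv_branch_parameters(self) -> int:
        """Independent ledger of the gated conv branch's learnable scalars."""
        total = 0
        for stage in list(self.encoders) + list(self.decoders):
            if stage.conv is not None:
                total += stage.conv.num_parameters()
        return total


def build_model(cfg: ModelConfig | None = None) -> SwinUNet3D:
    return SwinUNet3D(cfg or ModelConfig())


def build_pure_variant(cfg: ModelConfig | None = None) -> SwinUNet3D:
    """The ablation without the convolutional branch (transformer only)."""
    cfg = cfg or ModelConfig()
    return SwinUNet3D(dataclasses.replace(cfg, use_conv_branch=False))


def count_parameters(model: SwinUNet3D) -> int:
    return model.num_parameters()
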