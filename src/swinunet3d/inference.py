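"""Sliding-window whole-volume prediction and channel/label conversion.

Large volumes are tiled with fixed-size overlapping regions of interest
(ROI); sigmoid probabilities are averaged where tiles overlap (uniform
weights by default, Gaussian optional), so every voxel is covered at least
once.  A volume equal to one ROI reduces exactly to a direct forward pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import no_grad
from .metrics import CHANNEL_NAMES  # noqa: F401  (re-exported for CSV writers)
from .windowing import ShapeError


class InferenceError(ValueError):
    pass


@dataclass(frozen=True)
class InferenceConfig:
    roi: tuple[int, int, int] = (128, 128, 128)
    overlap: float = 0.125
    blend: str = "uniform"  # or "gaussian"
    threshold: float = 0.5

    def __post_init__(self):
        for r in self.roi:
            if r % 32 != 0:
                raise InferenceError(f"roi dims must be multiples of 32, got {self.roi}")
        if not 0.0 <= self.overlap < 1.0:
            raise InferenceError(f"overlap must lie in [0, 1), got {self.overlap}")
        if self.blend not in ("uniform", "gaussian"):
            raise InferenceError(f"blend must be 'uniform' or 'gaussian', got {self.blend!r}")


def tile_starts(dim: int, roi: int, overlap: float) -> list[int]:
    """Start offsets along one axis: stride floor(roi*(1-overlap)), the last
    tile snapped flush to the border."""
    if dim <= roi:
        return [0]
    stride = max(1, int(roi * (1.0 - overlap)))
    starts = list(range(0, dim - roi + 1, stride))
    if starts[-1] != dim - roi:
        starts.append(dim - roi)
    return starts


def _gaussian_weight(roi: tuple[int, int, int]) -> np.ndarray:
    ws = []
    for r in roi:
        x = np.arange(r) - (r - 1) / 2.0
        ws.append(np.exp(-0.5 * (x / (0.125 * r)) ** 2))
    return (ws[0][:, None, None] * ws[1][None, :, None] * ws[2][None, None, :]).astype(np.float32)


def sliding_window_predict(model, volume: np.ndarray,
                           cfg: InferenceConfig | None = None) -> np.ndarray:
    """Tile ``volume`` [H, W, D, C], average per-voxel sigmoid probabilities.

    Volumes smaller than the ROI along an axis are zero-padded to it and the
    padding cropped from the output.
    """
    cfg = cfg or InferenceConfig()
    volume = np.asarray(volume, dtype=np.float32)
    if volume.ndim != 4:
        raise InferenceError(f"expected [H, W, D, C] volume, got shape {volume.shape}")
    if volume.shape[-1] != model.cfg.in_channels:
        raise InferenceError(
            f"volume has {volume.shape[-1]} channels, model expects {model.cfg.in_channels}"
        )
    orig_dims = volume.shape[:3]
    pad = [max(0, r - d) for d, r in zip(orig_dims, cfg.roi)]
    if any(pad):
        volume = np.pad(volume, [(0, p) for p in pad] + [(0, 0)])
    dims = volume.shape[:3]

    num_classes = model.cfg.num_classes
    accum = np.zeros(dims + (num_classes,), dtype=np.float32)
    coverage = np.zeros(dims, dtype=np.float32)
    weight = (_gaussian_weight(cfg.roi) if cfg.blend == "gaussian"
              else np.ones(cfg.roi, dtype=np.float32))

    starts = [tile_starts(d, r, cfg.overlap) for d, r in zip(dims, cfg.roi)]
    model.eval()
    with no_grad():
        for i0 in starts[0]:
            for j0 in starts[1]:
                for k0 in starts[2]:
                    tile = volume[i0:i0 + cfg.roi[0], j0:j0 + cfg.roi[1],
                                  k0:k0 + cfg.roi[2], :]
                    logits = model(tile[None])
                    probs = 1.0 / (1.0 + np.exp(-np.asarray(logits)[0]))
                    sl = (slice(i0, i0 + cfg.roi[0]), slice(j0, j0 + cfg.roi[1]),
                          slice(k0, k0 + cfg.roi[2]))
                    accum[sl] += probs * weight[..., None]
                    coverage[sl] += weight
    if (coverage <= 0).any():
        raise InferenceError("internal error: uncovered voxels in the tiling")
    probs = accum / coverage[..., None]
    return probs[: orig_dims[0], : orig_dims[1], : orig_dims[2], :]


def predict_labels(model, volume: np.ndarray,
                   cfg: InferenceConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Convenience: probabilities plus the integer label map at threshold."""
    cfg = cfg or InferenceConfig()
    probs = sliding_window_predict(model, volume, cfg)
    channels = (probs >= cfg.threshold).astype(np.uint8)
    return probs, channels_to_labels(channels)


def channels_to_labels(channels: np.ndarray) -> np.ndarray:
    """Binary (ET, TC, WT) channels -> integer labels by specificity.

    Precedence resolves nesting (and any non-nested prediction the same
    way): ET -> 4, then TC-not-ET -> 1, then WT-only -> 2, else background.
    """
    channels = np.asarray(channels).astype(bool)
    if channels.ndim != 4 or channels.shape[-1] != 3:
        raise ShapeError(f"expected [H, W, D, 3] channels, got {channels.shape}")
    et, tc, wt = channels[..., 0], channels[..., 1], channels[..., 2]
    labels = np.zeros(channels.shape[:3], dtype=np.uint8)
    labels[wt] = 2
    labels[tc] = 1
    labels[et] = 4
    return labels
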