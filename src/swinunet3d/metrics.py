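"""Dice metric, soft dice loss, and BraTS label / channel conversions.

BraTS reference segmentations use integer labels {0 background, 1 necrotic
core, 2 peritumoral edema, 4 enhancing tumor}.  Evaluation happens on three
nested binary channels built by unioning label sets:

    ET (enhancing tumor) = {4};  TC (tumor core) = {1, 4};  WT (whole tumor) = {1, 2, 4}

(the ``"paper"`` mapping — ET = {2}, TC = {2, 4}, WT = {1, 2, 4} — is
selectable but breaks ET ⊆ TC ⊆ WT nesting semantics against Fig.-style
label definitions and is not the default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .nn import Tensor

ADMISSIBLE_LABELS = (0, 1, 2, 4)

CHANNEL_NAMES = ("ET", "TC", "WT")

LABEL_MAPPINGS: dict[str, tuple[tuple[int, ...], ...]] = {
    "brats": ((4,), (1, 4), (1, 2, 4)),
    "paper": ((2,), (2, 4), (1, 2, 4)),
}


class DataError(ValueError):
    pass


def labels_to_channels(labels: np.ndarray, mapping: str = "brats") -> np.ndarray:
    """Integer label volume [H, W, D] -> binary channel volume [H, W, D, 3]."""
    labels = np.asarray(labels)
    bad = ~np.isin(labels, ADMISSIBLE_LABELS)
    if bad.any():
        raise DataError(
            f"{int(bad.sum())} voxel(s) carry labels outside {ADMISSIBLE_LABELS}"
        )
    try:
        sets = LABEL_MAPPINGS[mapping]
    except KeyError:
        raise DataError(f"unknown mapping {mapping!r}; choose from {sorted(LABEL_MAPPINGS)}")
    channels = np.zeros(labels.shape + (3,), dtype=np.uint8)
    for ci, label_set in enumerate(sets):
        acc = np.zeros(labels.shape, dtype=bool)
        for lab in label_set:
            acc |= labels == lab  # logical OR over the union's members
        channels[..., ci] = acc
    return channels


@dataclass(frozen=True)
class DiceResult:
    value: float
    tp: int
    fp: int
    fn: int


def dice_coefficient(pred: np.ndarray, truth: np.ndarray) -> DiceResult:
    """Dice = 2TP / (2TP + FP + FN); both-empty volumes score 1.0."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise DataError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    denom = 2 * tp + fp + fn
    value = 1.0 if denom == 0 else 2.0 * tp / denom
    return DiceResult(value=value, tp=tp, fp=fp, fn=fn)


def dice_loss(logits, targets, eps: float = 1e-5):
    """1 - mean soft dice over channels; probabilities from sigmoid.

    ``logits`` may be a Tensor (training) or array; ``targets`` is a binary
    array of the same shape.  Smoothing ``eps`` enters numerator and
    denominator so an all-empty channel predicted empty costs ~0.
    """
    is_tensor = isinstance(logits, Tensor)
    t = logits if is_tensor else Tensor(np.asarray(logits, dtype=np.float32))
    targets = np.asarray(targets, dtype=np.float32)
    if tuple(t.shape) != targets.shape:
        raise DataError(f"shape mismatch: logits {tuple(t.shape)} vs targets {targets.shape}")
    probs = nn.sigmoid(t)
    nch = t.shape[-1]
    axes = tuple(range(t.ndim - 1))  # sum over everything except the channel axis
    inter = (probs * targets).sum(axis=axes)
    denom = probs.sum(axis=axes) + Tensor(targets.sum(axis=axes))
    soft = (inter * 2.0 + eps) / (denom + eps)
    loss = 1.0 - soft.sum() * (1.0 / nch)
    return loss if is_tensor else loss.item()


def dice_per_channel(pred_channels: np.ndarray, true_channels: np.ndarray) -> dict[str, DiceResult]:
    """Per-channel dice between binary [..., 3] prediction and reference."""
    return {
        name: dice_coefficient(pred_channels[..., i], true_channels[..., i])
        for i, name in enumerate(CHANNEL_NAMES)
    }


def evaluate_cases(cases: list[tuple[str, np.ndarray, np.ndarray]]) -> pd.DataFrame:
    """Per-case dice table (case_id, dice_ET, dice_TC, dice_WT).

    ``cases`` holds (case_id, predicted channels, reference channels) binary
    volumes.  The table feeds external significance testing.
    """
    rows = []
    for case_id, pred, truth in cases:
        scores = dice_per_channel(pred, truth)
        rows.append({"case_id": case_id,
                     **{f"dice_{k}": v.value for k, v in scores.items()}})
    return pd.DataFrame(rows, columns=["case_id", "dice_ET", "dice_TC", "dice_WT"])
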