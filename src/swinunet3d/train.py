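"""Training loop: AdamW on the soft dice loss with gradient accumulation.

The protocol mirrors common BraTS practice: batch size 1 with gradient
accumulation to an effective batch of 16, random crops whose sides are
multiples of 32, learning rate 3e-4, early stopping on the mean validation
dice.  Everything is driven by explicit seeds so two runs with the same
configuration are bit-identical on one device.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .nn import AdamW, Tensor, no_grad
from .inference import InferenceConfig, sliding_window_predict
from .metrics import CHANNEL_NAMES, dice_coefficient, dice_loss, labels_to_channels
from .model import ConfigError, ModelConfig, SwinUNet3D


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 3e-4
    weight_decay: float = 0.01
    accumulate: int = 16          # effective batch size at physical batch 1
    crop: tuple[int, int, int] = (128, 128, 128)
    max_epochs: int = 50
    patience: int = 10            # epochs without val-dice improvement
    seed: int = 0
    mapping: str = "brats"
    log_csv: str | None = None
    checkpoint: str | None = None

    def __post_init__(self):
        for c in self.crop:
            if c % 32 != 0 or c < 32:
                raise ConfigError(f"crop sides must be positive multiples of 32, got {self.crop}")


@dataclass
class TrainResult:
    history: pd.DataFrame
    best_epoch: int
    best_dice: float
    best_state: dict = field(repr=False)


def random_crop(volume: np.ndarray, channels: np.ndarray,
                crop: tuple[int, int, int], rng: np.random.Generator):
    dims = volume.shape[:3]
    starts = []
    for d, c in zip(dims, crop):
        if d < c:
            raise ConfigError(f"volume dims {dims} smaller than crop {crop}")
        starts.append(0 if d == c else int(rng.integers(0, d - c + 1)))
    sl = tuple(slice(s, s + c) for s, c in zip(starts, crop))
    return volume[sl], channels[sl]


def _prepare(cases, mapping: str):
    out = []
    for volume, labels in cases:
        out.append((np.asarray(volume, dtype=np.float32),
                    labels_to_channels(labels, mapping=mapping)))
    return out


def validate(model: SwinUNet3D, cases, mapping: str = "brats",
             roi: tuple[int, int, int] | None = None,
             threshold: float = 0.5) -> dict[str, float]:
    """Mean per-channel dice over held-out cases (sliding-window prediction)."""
    prepared = _prepare(cases, mapping)
    sums = {name: 0.0 for name in CHANNEL_NAMES}
    for volume, channels in prepared:
        icfg = InferenceConfig(roi=roi or tuple(min(d - d % 32, 128) or 32 for d in volume.shape[:3]),
                               threshold=threshold)
        probs = sliding_window_predict(model, volume, icfg)
        pred = probs >= threshold
        for i, name in enumerate(CHANNEL_NAMES):
            sums[name] += dice_coefficient(pred[..., i], channels[..., i]).value
    n = max(1, len(prepared))
    scores = {name: s / n for name, s in sums.items()}
    scores["mean"] = float(np.mean([scores[n_] for n_ in CHANNEL_NAMES]))
    return scores


def train_model(model: SwinUNet3D, train_cases, val_cases,
                cfg: TrainConfig | None = None) -> TrainResult:
    """Optimise ``model`` in place; returns history and the best weights.

    ``train_cases``/``val_cases`` are sequences of (volume [H, W, D, C],
    integer label volume [H, W, D]) arrays.
    """
    cfg = cfg or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    train_data = _prepare(train_cases, cfg.mapping)
    opt = AdamW(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)

    history_rows = []
    best = {"epoch": -1, "dice": -1.0, "state": model.state_dict()}
    stale = 0
    for epoch in range(cfg.max_epochs):
        model.train()
        order = rng.permutation(len(train_data))
        epoch_loss = 0.0
        pending = 0
        for idx in order:
            volume, channels = train_data[idx]
            vcrop, ccrop = random_crop(volume, channels, cfg.crop, rng)
            logits = model(_as_batch(vcrop))
            loss = dice_loss(logits, ccrop[None].astype(np.float32))
            epoch_loss += loss.item()
            # scale so accumulated gradients average over the effective batch
            loss.backward(np.full((), 1.0 / cfg.accumulate, dtype=np.float32))
            pending += 1
            if pending == cfg.accumulate:
                opt.step()
                opt.zero_grad()
                pending = 0
        if pending:
            opt.step()
            opt.zero_grad()
        epoch_loss /= max(1, len(train_data))

        scores = validate(model, val_cases, mapping=cfg.mapping,
                          roi=cfg.crop) if val_cases else {
            name: float("nan") for name in (*CHANNEL_NAMES, "mean")}
        history_rows.append({
            "epoch": epoch, "loss": epoch_loss,
            **{f"dice_{name}": scores[name] for name in CHANNEL_NAMES},
            "dice_mean": scores["mean"],
        })
        if cfg.log_csv:
            pd.DataFrame(history_rows).to_csv(cfg.log_csv, index=False)

        current = scores["mean"]
        if val_cases and current > best["dice"]:
            best = {"epoch": epoch, "dice": current, "state": model.state_dict()}
            stale = 0
            if cfg.checkpoint:
                save_checkpoint(cfg.checkpoint, model, optimizer=opt,
                                extra={"epoch": epoch, "val_dice": current,
                                       "train_seed": cfg.seed})
        else:
            stale += 1
            if val_cases and stale > cfg.patience:
                break

    if val_cases:
        model.load_state_dict(best["state"])
    else:
        best = {"epoch": len(history_rows) - 1, "dice": float("nan"),
                "state": model.state_dict()}
    return TrainResult(history=pd.DataFrame(history_rows),
                       best_epoch=best["epoch"], best_dice=best["dice"],
                       best_state=best["state"])


def _as_batch(volume: np.ndarray) -> Tensor:
    return Tensor(np.asarray(volume, dtype=np.float32)[None])


def overfit_one_batch(model: SwinUNet3D, volume: np.ndarray, labels: np.ndarray,
                      steps: int = 50, lr: float = 3e-4,
                      mapping: str = "brats") -> list[float]:
    """Optimise on one fixed crop; returns the per-step loss trace."""
    channels = labels_to_channels(labels, mapping=mapping)[None].astype(np.float32)
    batch = _as_batch(volume)
    opt = AdamW(model.parameters(), lr=lr)
    trace = []
    model.train()
    for _ in range(steps):
        logits = model(batch)
        loss = dice_loss(logits, channels)
        trace.append(loss.item())
        opt.zero_grad()
        loss.backward()
        opt.step()
    return trace


def desk_scale_protocol(seed: int = 0) -> tuple[ModelConfig, TrainConfig]:
    """The CPU-scale study conditions: width-reduced model, 32-cube crops.

    Embedding width 24 keeps the architecture (stage schedule, head counts,
    parallel branches) while shrinking every width fourfold; gradient
    accumulation is dropped (effective batch 1) so a 40-case epoch provides
    40 optimizer steps, which is what makes dice-loss training converge in
    tens of epochs on one CPU.  Learning rate and loss follow the reference
    protocol (AdamW, 3e-4, soft dice).
    """
    model_cfg = ModelConfig(embed_dim=24, seed=seed)
    train_cfg = TrainConfig(crop=(32, 32, 32), accumulate=1, max_epochs=30,
                            patience=10, seed=seed + 1)
    return model_cfg, train_cfg


# ---- checkpointing ---------------------------------------------------

def save_checkpoint(path: str | Path, model: SwinUNet3D,
                    optimizer: AdamW | None = None, extra: dict | None = None) -> None:
    """Weights + full model config (+ optimizer state) in one .npz file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {f"param/{k}": v for k, v in model.state_dict().items()}
    meta = {"config": model.cfg.to_dict(), "extra": extra or {}}
    if optimizer is not None:
        state = optimizer.state_dict()
        payload["opt/t"] = np.array(state["t"])
        for i, (m, v) in enumerate(zip(state["m"], state["v"])):
            payload[f"opt/m{i}"] = m
            payload[f"opt/v{i}"] = v
    payload["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **payload)


def load_checkpoint(path: str | Path) -> tuple[SwinUNet3D, dict]:
    """Rebuild the model recorded in a checkpoint; returns (model, meta)."""
    path = Path(path)
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        cfg = ModelConfig.from_dict(meta["config"])
        model = SwinUNet3D(cfg)
        state = {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
        model.load_state_dict(state)
        if any(k.startswith("opt/") for k in data.files):
            n = sum(1 for k in data.files if k.startswith("opt/m"))
            meta["optimizer"] = {
                "t": int(data["opt/t"]),
                "m": [data[f"opt/m{i}"] for i in range(n)],
                "v": [data[f"opt/v{i}"] for i in range(n)],
            }
    return model, meta
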