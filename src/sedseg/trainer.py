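"""Training harness: Adam + soft Dice loss, per-stage learning-rate
schedules, epoch-wise validation, and best-model selection.

The two stages train independently on different pairings:

* stage 1 (liver): input = windowed CT slice, target = liver mask;
* stage 2 (tumor): input = CT slice multiplied by the *ground-truth*
  liver mask (teacher forcing), target = tumor mask; slices without
  liver are excluded since the stage-2 input is defined on liver regions.

Learning-rate schedules, both anchored at 1e-4 and stepping every second
epoch:

* ``step_decay_10pct``:  lr(e) = lr0 * 0.9 ** floor(e / 2)
* ``exp_decay_0p9``:     lr(e) = lr0 * exp(-0.9 * floor(e / 2))

After every epoch the mean validation Dice loss is recorded; the
checkpoint returned is the one with the lowest validation loss over the
whole run (ties broken by the earlier epoch).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .nn import Adam, GraphModel, dice_loss_and_grad, soft_dice_batch

__all__ = ["TrainConfig", "HistoryRow", "TrainResult", "lr_at_epoch",
           "make_pairs", "train_stage"]

SCHEDULES = ("step_decay_10pct", "exp_decay_0p9")


@dataclass
class TrainConfig:
    """Optimization protocol for one stage.

    Defaults follow the published protocol: stage 1 trains 50 epochs at
    batch 16 with the 10%-per-two-epochs step decay; stage 2 trains 100
    epochs at batch 4 with the exp(-0.9)-per-two-epochs decay.
    """

    stage: str = "sed1"
    epochs: int = None  # type: ignore[assignment]
    batch_size: int = None  # type: ignore[assignment]
    lr0: float = 1e-4
    schedule: str = None  # type: ignore[assignment]
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stage not in ("sed1", "sed2"):
            raise ValueError("stage must be 'sed1' or 'sed2'")
        if self.epochs is None:
            self.epochs = 50 if self.stage == "sed1" else 100
        if self.batch_size is None:
            self.batch_size = 16 if self.stage == "sed1" else 4
        if self.schedule is None:
            self.schedule = "step_decay_10pct" if self.stage == "sed1" else "exp_decay_0p9"
        if self.schedule not in SCHEDULES:
            raise ValueError(f"unknown schedule {self.schedule!r}")
        if self.epochs < 1 or self.batch_size < 1 or self.lr0 <= 0:
            raise ValueError("epochs, batch_size must be >= 1 and lr0 > 0")


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Learning rate for a 0-based epoch index under the config's schedule."""
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    steps = epoch // 2
    if config.schedule == "step_decay_10pct":
        return config.lr0 * 0.9 ** steps
    return config.lr0 * math.exp(-0.9 * steps)


@dataclass(frozen=True)
class HistoryRow:
    epoch: int
    lr: float
    train_loss: float
    val_loss: float


@dataclass
class TrainResult:
    best_state: dict
    best_epoch: int
    best_val_loss: float
    history: list = field(default_factory=list)


def make_pairs(samples: Sequence, stage: str):
    """Build (input, target) arrays for one stage from slice samples.

    Stage 1 keeps every slice (empty livers are negative examples);
    stage 2 keeps only slices with liver and multiplies the image by the
    ground-truth liver mask.
    """
    xs, ys = [], []
    for s in samples:
        if stage == "sed1":
            if s.liver_mask is None:
                raise ValueError("stage-1 training needs liver masks")
            xs.append(s.image)
            ys.append(s.liver_mask)
        elif stage == "sed2":
            if s.liver_mask is None or s.tumor_mask is None:
                raise ValueError("stage-2 training needs liver and tumor masks")
            if not s.liver_mask.any():
                continue
            xs.append(s.image * s.liver_mask)
            ys.append(s.tumor_mask)
        else:
            raise ValueError(f"unknown stage {stage!r}")
    if not xs:
        raise ValueError(f"no usable samples for stage {stage!r}")
    x = np.stack(xs)[..., None].astype(np.float32)
    y = np.stack(ys)[..., None].astype(np.float32)
    return x, y


def _epoch_loss(model: GraphModel, x: np.ndarray, y: np.ndarray,
                batch_size: int) -> float:
    """Mean per-sample Dice loss in inference mode."""
    losses = []
    for i in range(0, len(x), batch_size):
        out = model.forward(x[i : i + batch_size], train=False)
        losses.extend(1.0 - soft_dice_batch(out, y[i : i + batch_size]))
    return float(np.mean(losses))


def train_stage(model: GraphModel, config: TrainConfig,
                train_samples: Sequence, val_samples: Sequence,
                verbose: bool = False) -> TrainResult:
    """Train one stage and return the lowest-validation-loss checkpoint.

    The returned model state is also loaded back into ``model``.
    Deterministic for a fixed config seed on a single thread.
    """
    if not len(train_samples) or not len(val_samples):
        raise ValueError("train and validation sets must be non-empty")
    x_tr, y_tr = make_pairs(train_samples, config.stage)
    x_va, y_va = make_pairs(val_samples, config.stage)

    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params(), lr=config.lr0)
    best = TrainResult(best_state=model.state_dict(), best_epoch=-1,
                       best_val_loss=float("inf"))

    for epoch in range(config.epochs):
        lr = lr_at_epoch(config, epoch)
        opt.lr = lr
        perm = rng.permutation(len(x_tr))
        batch_losses, batch_sizes = [], []
        for i in range(0, len(perm), config.batch_size):
            idx = perm[i : i + config.batch_size]
            out = model.forward(x_tr[idx], train=True)
            loss, grad = dice_loss_and_grad(out, y_tr[idx])
            model.zero_grad()
            model.backward(grad)
            opt.step()
            batch_losses.append(loss)
            batch_sizes.append(len(idx))
        train_loss = float(np.average(batch_losses, weights=batch_sizes))
        # validation is inference-only; batch-norm uses running stats, so a
        # larger batch changes nothing numerically per sample
        val_loss = _epoch_loss(model, x_va, y_va, max(config.batch_size, 16))
        best.history.append(HistoryRow(epoch, lr, train_loss, val_loss))
        if val_loss < best.best_val_loss:
            best.best_val_loss = val_loss
            best.best_epoch = epoch
            best.best_state = model.state_dict()
        if verbose:
            print(f"epoch {epoch:3d}  lr {lr:.3e}  train {train_loss:.4f}  "
                  f"val {val_loss:.4f}")

    model.load_state_dict(best.best_state)
    return best
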