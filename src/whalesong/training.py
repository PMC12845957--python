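"""Training loop: AdamW, warm-up + cosine schedule, early stopping, checkpointing.

Defaults mirror the two architectures' training procedures: the CNN trains
for 10 epochs at a constant 1e-3 learning rate; the ViT trains for up to 30
epochs under a linear warm-up (2 epochs, starting from 0) into cosine decay,
with early stopping (patience 5 on validation loss) and check-pointing of
the best-validation-loss weights.  Both use batch size 128, weight decay
0.004 and sparse categorical cross-entropy.  A single seed covers shuffling
and dropout; model initialization is seeded at build time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn


@dataclass(frozen=True)
class TrainConfig:
    base_lr: float = 1e-3
    weight_decay: float = 0.004
    batch_size: int = 128
    max_epochs: int = 10
    schedule: str = "constant"  # "constant" or "warmup_cosine"
    warmup_epochs: int = 2
    early_stopping_patience: int | None = None  # epochs of no val-loss improvement
    checkpoint_best: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_lr <= 0 or self.weight_decay < 0 or self.batch_size <= 0:
            raise ValueError("rates and batch size must be positive")
        if self.schedule not in ("constant", "warmup_cosine"):
            raise ValueError(f"unknown schedule {self.schedule!r}")
        if self.schedule == "warmup_cosine" and not self.warmup_epochs < self.max_epochs:
            raise ValueError("warmup_epochs must be smaller than max_epochs")


#: Per-architecture defaults.
CNN_TRAIN = TrainConfig(max_epochs=10, schedule="constant")
VIT_TRAIN = TrainConfig(
    max_epochs=30, schedule="warmup_cosine", warmup_epochs=2, early_stopping_patience=5
)


@dataclass
class History:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)

    @property
    def best_epoch(self) -> int:
        return int(np.argmin(self.val_loss))


def lr_at(step: int, total_steps: int, cfg: TrainConfig) -> float:
    """Learning rate at a global step.

    Constant schedule: always ``base_lr``.  Warm-up + cosine: a linear ramp
    from 0 to ``base_lr`` over the warm-up steps, then
    ``base_lr * 0.5 * (1 + cos(pi * progress))`` over the remaining steps,
    reaching 0 at ``total_steps``.  Continuous at the boundary and
    non-increasing afterward.
    """
    if not 0 <= step <= total_steps:
        raise ValueError(f"step {step} outside [0, {total_steps}]")
    if cfg.schedule == "constant":
        return cfg.base_lr
    warmup_steps = max(1, round(total_steps * cfg.warmup_epochs / cfg.max_epochs))
    if step <= warmup_steps:
        return cfg.base_lr * step / warmup_steps
    progress = (step - warmup_steps) / max(1, total_steps - warmup_steps)
    return cfg.base_lr * 0.5 * (1.0 + math.cos(math.pi * progress))


def _evaluate(model: nn.Model, x: np.ndarray, y: np.ndarray, batch_size: int) -> tuple[float, float]:
    losses, correct, n = [], 0, len(x)
    for i in range(0, n, batch_size):
        xb, yb = x[i : i + batch_size], y[i : i + batch_size]
        logits = model.forward_logits(xb, training=False)
        loss, _ = nn.sparse_categorical_crossentropy(logits, yb)
        losses.append(loss * len(xb))
        correct += int((logits.argmax(axis=1) == yb).sum())
    return float(np.sum(losses) / n), correct / n


def train(
    model: nn.Model,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig = CNN_TRAIN,
    verbose: bool = False,
) -> tuple[nn.Model, History]:
    """Train in place; returns the model with its best-checkpoint weights.

    Weights returned are those of the epoch with the lowest validation loss
    when ``checkpoint_best`` is on, otherwise the final-epoch weights.  The
    run is reproducible from (model seed, cfg.seed).
    """
    x_train, y_train = train_data
    x_val, y_val = val_data
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("train and validation datasets must be non-empty")
    x_train = np.asarray(x_train, dtype=np.float32)
    x_val = np.asarray(x_val, dtype=np.float32)
    y_train = np.asarray(y_train, dtype=np.int64)
    y_val = np.asarray(y_val, dtype=np.int64)
    n_out = model.predict_proba(x_train[:1]).shape[1]
    if y_train.max() >= n_out or y_val.max() >= n_out:
        raise ValueError("label arity exceeds model output dimension")

    rng = np.random.default_rng(cfg.seed)
    optimizer = nn.AdamW(model.parameters(), weight_decay=cfg.weight_decay)
    steps_per_epoch = math.ceil(len(x_train) / cfg.batch_size)
    total_steps = steps_per_epoch * cfg.max_epochs
    history = History()
    best_val = math.inf
    best_weights = None
    since_best = 0
    step = 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(x_train))
        epoch_loss, epoch_correct = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            step += 1
            lr = lr_at(step, total_steps, cfg)
            model.zero_grad()
            logits = model.forward_logits(xb, training=True, rng=rng)
            loss, dlogits = nn.sparse_categorical_crossentropy(logits, yb)
            if not math.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, step {step}"
                )
            model.backward_from_logits(dlogits)
            optimizer.step(lr)
            epoch_loss += loss * len(xb)
            epoch_correct += int((logits.argmax(axis=1) == yb).sum())
        # recalibrate BN inference statistics for this epoch's weights before
        # measuring validation loss (short runs leave momentum stats stale)
        model.refresh_batchnorm_stats(x_train, batch_size=cfg.batch_size)
        val_loss, val_acc = _evaluate(model, x_val, y_val, cfg.batch_size)
        history.train_loss.append(epoch_loss / len(x_train))
        history.train_acc.append(epoch_correct / len(x_train))
        history.val_loss.append(val_loss)
        history.val_acc.append(val_acc)
        if verbose:
            print(
                f"epoch {epoch + 1:3d}: loss {history.train_loss[-1]:.4f} "
                f"acc {history.train_acc[-1]:.4f}  val_loss {val_loss:.4f} val_acc {val_acc:.4f}"
            )
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            since_best = 0
            if cfg.checkpoint_best:
                best_weights = model.get_weights()
        else:
            since_best += 1
            if cfg.early_stopping_patience is not None and since_best > cfg.early_stopping_patience:
                break
    if cfg.checkpoint_best and best_weights is not None:
        model.set_weights(best_weights)
    return model, history


def predict(model: nn.Model, images: np.ndarray, batch_size: int = 128) -> np.ndarray:
    """Class probability pairs for a batch of standardized feature images.

    Inputs are expected to be per-image standardized (mean ~0, sd ~1 or an
    all-zero silence image); grossly unstandardized input is rejected.
    """
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 3:
        images = images[None]
    sds = images.reshape(len(images), -1).std(axis=1)
    means = images.reshape(len(images), -1).mean(axis=1)
    bad = (np.abs(means) > 0.05) | ((np.abs(sds - 1.0) > 0.05) & (sds > 1e-9))
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} image(s) are not per-image standardized; "
            "apply features.standardize_image first"
        )
    out = [model.predict_proba(images[i : i + batch_size]) for i in range(0, len(images), batch_size)]
    return np.concatenate(out, axis=0)
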