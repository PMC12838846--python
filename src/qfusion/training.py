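"""Training loop for the fusion head: AdamW-style decoupled weight decay,
per-step cosine annealing, macro-F1 early stopping.

The recipe mirrors the study conditions: 10 epochs, batch size 32, learning
rate 1e-4, cosine annealing to zero over all steps, mean cross-entropy loss,
and the best checkpoint chosen by validation macro F1.  The loop is
deterministic given the config seed (single-threaded NumPy; shuffling and
dropout draw from seeded generators).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ValidationError
from .evaluation import macro_f1_score
from .fusion import FusionModel


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 10
    batch_size: int = 32
    lr: float = 1e-4
    weight_decay: float = 1e-2
    schedule: str = "cosine"
    early_stop_metric: str = "macro_f1"
    patience: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValidationError("lr must be positive")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValidationError("batch_size and epochs must be >= 1")


@dataclass
class TrainLog:
    """Per-epoch train loss, validation macro F1 and learning rate."""

    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_macro_f1: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": self.epochs, "loss": self.train_loss,
                             "val_macro_f1": self.val_macro_f1, "lr": self.lr})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def cross_entropy_loss(probs: np.ndarray, labels: np.ndarray,
                       clamp: float = 1e-12) -> float:
    """Mean negative log-probability of the true class over the batch.

    Probabilities at the true label are clamped below at ``clamp`` so a
    confidently wrong prediction yields a large finite loss.
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    labels = np.asarray(labels)
    if probs.shape[0] != labels.shape[0]:
        raise ValidationError("probs and labels must have equal batch size")
    if labels.size and (labels.min() < 0 or labels.max() >= probs.shape[1]):
        raise ValidationError("labels out of range")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValidationError("each probability row must sum to 1")
    p_true = np.clip(probs[np.arange(len(labels)), labels], clamp, None)
    return float(-np.log(p_true).mean())


def cosine_lr(step: int, total_steps: int, lr0: float) -> float:
    """Cosine annealing: ``lr0 * (1 + cos(pi * step / total_steps)) / 2``.

    Starts at ``lr0``, reaches 0 at ``total_steps``; no warm restarts.
    """
    if total_steps <= 0:
        raise ValidationError("total_steps must be positive")
    if not 0 <= step <= total_steps:
        raise ValidationError("step must lie in [0, total_steps]")
    return lr0 * 0.5 * (1.0 + np.cos(np.pi * step / total_steps))


class AdamW:
    """Adam with decoupled weight decay over a named-parameter dict.

    Weight decay multiplies parameters by ``(1 - lr * weight_decay)``
    separately from the gradient update; bias vectors are not decayed.
    """

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-2):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray], lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            if self.weight_decay and p.ndim > 1:  # decay matrices, not biases
                p *= 1.0 - lr * self.weight_decay
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


def train_fusion(model: FusionModel,
                 zA_train: np.ndarray, zB_train: np.ndarray, y_train: np.ndarray,
                 zA_val: np.ndarray, zB_val: np.ndarray, y_val: np.ndarray,
                 config: TrainConfig = TrainConfig()) -> TrainLog:
    """Train the fusion parameters on frozen features; returns the log.

    The model is left holding the parameters of the epoch with the highest
    validation macro F1 (ties -> earliest epoch).  Training stops early after
    ``config.patience`` epochs without improvement.
    """
    for name, arr in (("train", y_train), ("val", y_val)):
        if len(arr) == 0:
            raise ValidationError(f"empty {name} split")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    drop_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 19]))
    params = model.parameters()
    opt = AdamW(params, lr=config.lr, weight_decay=config.weight_decay)

    n = len(y_train)
    steps_per_epoch = int(np.ceil(n / config.batch_size))
    total_steps = config.epochs * steps_per_epoch
    log = TrainLog()
    best_f1, best_params, since_best = -1.0, None, 0
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        epoch_lr = cosine_lr(step, total_steps, config.lr)
        for b in range(steps_per_epoch):
            idx = order[b * config.batch_size:(b + 1) * config.batch_size]
            lr = cosine_lr(step, total_steps, config.lr) if config.schedule == "cosine" else config.lr
            loss, grads = model.loss_and_grads(zA_train[idx], zB_train[idx],
                                               y_train[idx], rng=drop_rng)
            opt.step(grads, lr=lr)
            losses.append(loss)
            step += 1
        preds = model.predict(zA_val, zB_val)
        f1 = macro_f1_score(y_val, preds, model.config.n_classes)
        log.epochs.append(epoch)
        log.train_loss.append(float(np.mean(losses)))
        log.val_macro_f1.append(f1)
        log.lr.append(float(epoch_lr))
        if f1 > best_f1:
            best_f1, since_best = f1, 0
            best_params = {k: v.copy() for k, v in params.items()}
            log.best_epoch = epoch
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    if best_params is not None:
        model.set_parameters(best_params)
    return log
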