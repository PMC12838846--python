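"""Pluggable backbone feature extractors and candidate selection.

A *backbone* is a frozen network whose classifier has been removed, used
purely as a feature extractor.  This package ships small deterministic
NumPy extractors ("tiny" backbones): blockwise intensity statistics passed
through a fixed random projection with a tanh nonlinearity.  Each registered
name carries its own projection seed, so different backbones emit genuinely
different feature spaces — enough to exercise selection, fusion and
evaluation end-to-end on a single CPU.  Large pretrained architectures can
be plugged in through the same registry contract: a callable mapping a
normalized image batch to an (n, feature_dim) matrix.

Candidate ranking follows the study protocol: each candidate gets a linear
probe trained with the standard recipe (10 epochs, batch 32, lr 1e-4,
decoupled weight decay, cosine annealing, macro-F1 early stopping) and
candidates are compared by weighted F1 on the evaluation split.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .evaluation import confusion_matrix, macro_f1_score, metrics_from_cm
from .training import AdamW, TrainConfig, cosine_lr


@dataclass(frozen=True)
class BackboneHandle:
    """A named frozen feature extractor emitting ``feature_dim``-d vectors."""

    name: str
    feature_dim: int = 768
    frozen: bool = True
    weights_source: str = "tiny-test"

    def __post_init__(self) -> None:
        if self.feature_dim < 1:
            raise ValidationError("feature_dim must be >= 1")


@dataclass(frozen=True)
class CandidateScore:
    """Evaluation-split metrics of one fine-tuned candidate, in percent."""

    name: str
    f1: float  # weighted F1, the selection criterion
    accuracy: float = 0.0
    precision: float = 0.0
    recall: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.f1, self.accuracy, self.precision, self.recall):
            if not 0.0 <= v <= 100.0:
                raise ValidationError("metrics must lie in [0, 100]")


_REGISTRY: dict[str, dict] = {}


def register_backbone(name: str, feature_dim: int = 768, kind: str = "tiny-conv",
                      weights_source: str = "tiny-test") -> None:
    _REGISTRY[name] = {"feature_dim": feature_dim, "kind": kind,
                       "weights_source": weights_source}


# default tiny candidates (names indicate the statistic family, not any
# published architecture)
for _n, _k in [("tiny-conv-a", "tiny-conv"), ("tiny-conv-b", "tiny-conv"),
               ("tiny-grad-a", "tiny-grad"), ("tiny-grad-b", "tiny-grad"),
               ("tiny-mix-a", "tiny-mix"), ("tiny-mix-b", "tiny-mix")]:
    register_backbone(_n, 768, _k)


def list_backbones() -> list[str]:
    return sorted(_REGISTRY)


def get_backbone(name: str, feature_dim: int | None = None) -> BackboneHandle:
    if name not in _REGISTRY:
        raise ValidationError(f"unknown backbone {name!r}; known: {list_backbones()}")
    entry = _REGISTRY[name]
    return BackboneHandle(name, feature_dim or entry["feature_dim"],
                          frozen=True, weights_source=entry["weights_source"])


def _name_seed(name: str) -> int:
    return int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big")


def _block_stats(images: np.ndarray, grid: int = 8) -> np.ndarray:
    """Blockwise channel means and stds: the raw descriptor, (n, 2*grid^2*3)."""
    n, H, W, C = images.shape
    hb, wb = H // grid, W // grid
    if hb < 1 or wb < 1:
        raise ValidationError("images too small for the block grid")
    x = images[:, : grid * hb, : grid * wb, :]
    x = x.reshape(n, grid, hb, grid, wb, C)
    means = x.mean(axis=(2, 4)).reshape(n, -1)
    stds = x.std(axis=(2, 4)).reshape(n, -1)
    return np.concatenate([means, stds], axis=1)


def _grad_stats(images: np.ndarray, grid: int = 8) -> np.ndarray:
    gy = np.abs(np.diff(images, axis=1, prepend=images[:, :1]))
    gx = np.abs(np.diff(images, axis=2, prepend=images[:, :, :1]))
    return _block_stats(gy + gx, grid)


def extract_features(handle: BackboneHandle, images: np.ndarray) -> np.ndarray:
    """Map a normalized image batch to an (n, feature_dim) matrix.

    Deterministic: the projection matrix is derived from the backbone name
    alone, so repeated calls (and separate processes) agree bitwise.
    """
    images = np.asarray(images, dtype=np.float64)
    if images.ndim != 4 or images.shape[-1] != 3:
        raise ValidationError("expected a normalized (n, H, W, 3) batch")
    kind = _REGISTRY.get(handle.name, {}).get("kind", "tiny-conv")
    if kind == "tiny-conv":
        raw = _block_stats(images)
    elif kind == "tiny-grad":
        raw = _grad_stats(images)
    elif kind == "tiny-mix":
        raw = np.concatenate([_block_stats(images, 4), _grad_stats(images, 4)], axis=1)
    else:
        raise ValidationError(f"unknown backbone kind {kind!r}")
    rng = np.random.default_rng(_name_seed(handle.name))
    proj = rng.normal(size=(raw.shape[1], handle.feature_dim)) / np.sqrt(raw.shape[1])
    return np.tanh(raw @ proj)


def fit_linear_probe(features: np.ndarray, labels: np.ndarray,
                     val_features: np.ndarray, val_labels: np.ndarray,
                     n_classes: int, config: TrainConfig = TrainConfig()):
    """Softmax regression on frozen features with the standard recipe.

    Returns ``(W, b)`` of the epoch with the best validation macro F1.
    """
    n, d = features.shape
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    W = np.zeros((d, n_classes))
    b = np.zeros(n_classes)
    opt = AdamW({"W": W, "b": b}, lr=config.lr, weight_decay=config.weight_decay)
    steps_per_epoch = int(np.ceil(n / config.batch_size))
    total_steps = config.epochs * steps_per_epoch
    best = (-1.0, W.copy(), b.copy())
    since_best, step = 0, 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for k in range(steps_per_epoch):
            idx = order[k * config.batch_size:(k + 1) * config.batch_size]
            X, y = features[idx], labels[idx]
            logits = X @ W + b
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            g = p.copy()
            g[np.arange(len(y)), y] -= 1.0
            g /= len(y)
            lr = cosine_lr(step, total_steps, config.lr)
            opt.step({"W": X.T @ g, "b": g.sum(axis=0)}, lr=lr)
            step += 1
        preds = np.argmax(val_features @ W + b, axis=1)
        f1 = macro_f1_score(val_labels, preds, n_classes)
        if f1 > best[0]:
            best = (f1, W.copy(), b.copy())
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    W[...], b[...] = best[1], best[2]
    return W, b


def score_candidate(handle: BackboneHandle, images_train, y_train,
                    images_eval, y_eval, n_classes: int,
                    config: TrainConfig = TrainConfig()) -> CandidateScore:
    """Fine-tune a linear probe on one candidate and score it (percent)."""
    feats_train = extract_features(handle, images_train)
    feats_eval = extract_features(handle, images_eval)
    W, b = fit_linear_probe(feats_train, y_train, feats_eval, y_eval,
                            n_classes, config)
    preds = np.argmax(feats_eval @ W + b, axis=1)
    report = metrics_from_cm(confusion_matrix(y_eval, preds, n_classes))
    return CandidateScore(handle.name, f1=report.weighted_f1,
                          accuracy=report.accuracy,
                          precision=report.weighted_precision,
                          recall=report.weighted_recall)


def select_top_two(scores: list[CandidateScore]) -> tuple[CandidateScore, CandidateScore]:
    """The two best candidates by F1, best first (it becomes Backbone A).

    Ties are broken by higher accuracy, then lexicographic name.  The result
    is permutation-invariant in the input order.
    """
    if len(scores) < 2:
        raise ValidationError("need at least 2 candidates to select from")
    ranked = sorted(scores, key=lambda s: (-s.f1, -s.accuracy, s.name))
    return ranked[0], ranked[1]
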