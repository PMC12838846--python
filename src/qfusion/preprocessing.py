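"""Image resizing, channel statistics, normalization and data splits.

Normalization is the standard per-channel standardization: with N images of
size H x W, channel mean and population standard deviation are

    mu_c    = 1/(NHW) sum_{n,h,w} x[n,c,h,w]
    sigma_c = sqrt( 1/(NHW) sum_{n,h,w} (x[n,c,h,w] - mu_c)^2 )

and each pixel becomes (x - mu_c) / sigma_c.  Statistics are computed over
the full image set by default (matching the training recipe this package
reproduces); computing them on the training split only is available via
``subset`` and avoids information leakage into evaluation splits -- see the
methods note.

The partition is 80/20 train/test with 10% of the training data held out for
validation, stratified per class with a ceiling rule on the test share.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from math import ceil
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import ValidationError


@dataclass
class ChannelStats:
    """Per-channel mean/std of an image set (population std, divisor NHW)."""

    mu: tuple[float, float, float]
    sigma: tuple[float, float, float]
    n_images: int
    height: int
    width: int

    def to_json(self, path: Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: Path) -> "ChannelStats":
        d = json.loads(Path(path).read_text())
        d["mu"], d["sigma"] = tuple(d["mu"]), tuple(d["sigma"])
        return cls(**d)


@dataclass
class SplitSpec:
    """Disjoint train/val/test index partition of a dataset."""

    train_idx: list[int]
    val_idx: list[int]
    test_idx: list[int]
    test_fraction: float = 0.20
    val_fraction_of_train: float = 0.10
    stratified: bool = True
    seed: int = 0

    def to_json(self, path: Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: Path) -> "SplitSpec":
        return cls(**json.loads(Path(path).read_text()))


def resize_images(images: np.ndarray, size: int = 224) -> np.ndarray:
    """Bilinear-resize a batch of HxWx3 uint8 images to size x size."""
    if images.ndim != 4 or images.shape[-1] != 3:
        raise ValidationError("expected a (n, H, W, 3) image batch")
    if images.shape[1] == size and images.shape[2] == size:
        return images
    out = np.empty((len(images), size, size, 3), dtype=np.uint8)
    for i, img in enumerate(images):
        out[i] = np.asarray(Image.fromarray(img).resize((size, size), Image.BILINEAR))
    return out


def compute_channel_stats(images: np.ndarray) -> ChannelStats:
    """Channel means and population standard deviations of an image set."""
    images = np.asarray(images)
    if images.size == 0:
        raise ValidationError("cannot compute statistics of an empty image set")
    if images.ndim != 4 or images.shape[-1] != 3:
        raise ValidationError("expected a uniform (n, H, W, 3) image batch")
    x = images.astype(np.float64)
    mu = x.mean(axis=(0, 1, 2))
    sigma = x.std(axis=(0, 1, 2))  # population std: divisor NHW
    n, h, w, _ = images.shape
    return ChannelStats(tuple(mu), tuple(sigma), n, h, w)


def normalize(images: np.ndarray, stats: ChannelStats, eps_norm: float = 1e-8) -> np.ndarray:
    """Standardize pixels per channel; a zero sigma is guarded by ``eps_norm``."""
    images = np.asarray(images)
    if images.ndim != 4 or images.shape[-1] != 3:
        raise ValidationError("expected a (n, H, W, 3) image batch")
    if images.shape[1] != stats.height or images.shape[2] != stats.width:
        raise ValidationError("image size differs from the size the stats were computed on")
    mu = np.asarray(stats.mu)
    sigma = np.asarray(stats.sigma)
    sigma = np.where(sigma == 0.0, sigma + eps_norm, sigma)
    return (images.astype(np.float64) - mu) / sigma


def make_splits(labels: np.ndarray, test_fraction: float = 0.20,
                val_fraction_of_train: float = 0.10, stratified: bool = True,
                seed: int = 0) -> SplitSpec:
    """Seeded stratified 80/20 split with 10% of training held out for validation.

    The test share is rounded per class with a ceiling rule, so every class is
    represented in the test set; validation is carved from the shuffled
    training indices the same way.
    """
    labels = np.asarray(labels)
    if not 0.0 < test_fraction < 1.0 or not 0.0 < val_fraction_of_train < 1.0:
        raise ValidationError("fractions must lie strictly between 0 and 1")
    if labels.size == 0:
        raise ValidationError("empty label vector")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))

    groups: list[np.ndarray]
    if stratified:
        classes = np.unique(labels)
        if any((labels == k).sum() < 1 for k in classes):
            raise ValidationError("each class needs at least one sample when stratified")
        groups = [np.flatnonzero(labels == k) for k in classes]
    else:
        groups = [np.arange(labels.size)]

    # test share: per-class ceiling, so every class appears in the test set
    test: list[int] = []
    rest_pool: list[int] = []
    for idx in groups:
        idx = idx.copy()
        rng.shuffle(idx)
        n_test = min(ceil(test_fraction * len(idx)), len(idx))
        test.extend(idx[:n_test].tolist())
        rest_pool.extend(idx[n_test:].tolist())

    # validation share: round-half-up over the pooled training remainder
    rest = np.asarray(rest_pool)
    rng.shuffle(rest)
    n_val = int(np.floor(val_fraction_of_train * len(rest) + 0.5))
    val = rest[:n_val].tolist()
    train = rest[n_val:].tolist()
    return SplitSpec(sorted(train), sorted(val), sorted(test),
                     test_fraction, val_fraction_of_train, stratified, seed)


def load_image_tree(root: Path, size: int = 224,
                    class_names: list[str] | None = None):
    """Read a directory-per-class PNG/JPEG tree into a resized uint8 batch.

    Classes are the sorted sub-directory names unless ``class_names`` fixes an
    explicit order (persisted label map).  Returns (images, labels, names).
    """
    root = Path(root)
    if not root.is_dir():
        raise ValidationError(f"data root {root} does not exist")
    names = class_names or sorted(p.name for p in root.iterdir() if p.is_dir())
    if not names:
        raise ValidationError(f"no class directories under {root}")
    imgs, labels = [], []
    for k, name in enumerate(names):
        for f in sorted((root / name).glob("*")):
            if f.suffix.lower() not in {".png", ".jpg", ".jpeg"}:
                continue
            with Image.open(f) as im:
                imgs.append(np.asarray(im.convert("RGB")))
            labels.append(k)
    if not imgs:
        raise ValidationError(f"no images found under {root}")
    batch = resize_images(np.stack(imgs), size)
    return batch, np.asarray(labels), names
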