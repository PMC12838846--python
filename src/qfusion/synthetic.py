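"""Synthetic labelled datasets for exercising the classification pipeline.

Real abdominal CT collections are hospital data and cannot ship with the
package, so every stage is testable against generated stand-ins:

* :func:`generate_images` draws 5-class RGB images whose classes differ by
  blob count and texture frequency, with an overall ``signal_strength`` dial
  (0 = class-conditional distributions identical, 1 = strong signal).
* :func:`generate_feature_fixture` draws labelled Gaussian feature clusters
  for unit-testing the fusion head without any image I/O.
* :func:`generate_interaction_fixture` draws paired feature views in which
  each view alone is chance-level and only the elementwise product of the
  views reveals the class -- the regime the Hadamard interaction token is
  designed for.

All generators are bit-deterministic under a fixed seed; one integer seed
hierarchically spawns per-stage streams via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import ValidationError

DEFAULT_CLASS_NAMES = (
    "localized_complicated",
    "normal",
    "rare",
    "advanced_complicated",
    "simple",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic image dataset.

    Attributes
    ----------
    n_per_class : images per class.
    image_size : side length of the square RGB images, pixels.
    n_classes : number of classes.
    signal_strength : in [0, 1]; scales every class-dependent signal.
        At 0 the class-conditional image distributions are identical.
    interaction_only : if True, each sample is a *pair* of image views;
        either view alone is uninformative about the class and only the
        joint (product) statistics of the two views carry the label.
    noise_sd : standard deviation of additive pixel noise (8-bit units).
    seed : master seed; spawns independent per-image streams.
    """

    n_per_class: int = 40
    image_size: int = 224
    n_classes: int = 5
    signal_strength: float = 1.0
    interaction_only: bool = False
    noise_sd: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValidationError("n_per_class must be >= 1")
        if self.image_size < 8:
            raise ValidationError("image_size must be >= 8")
        if self.n_classes < 2:
            raise ValidationError("n_classes must be >= 2")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValidationError("signal_strength must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass
class FeatureFixture:
    """Labelled two-view feature matrices for head-only tests."""

    features_a: np.ndarray  # n x dA
    features_b: np.ndarray  # n x dB
    labels: np.ndarray  # n ints in [0, n_classes)

    def __post_init__(self) -> None:
        if not (len(self.features_a) == len(self.features_b) == len(self.labels)):
            raise ValidationError("features_a, features_b and labels must have equal row counts")
        if self.features_a.ndim != 2 or self.features_b.ndim != 2:
            raise ValidationError("feature matrices must be 2-D")
        if self.features_a.shape[1] < 1 or self.features_b.shape[1] < 1:
            raise ValidationError("feature dimensions must be >= 1")


def _blob_image(rng: np.random.Generator, size: int, n_blobs: int,
                freq: float, layout: np.ndarray, amplitude: float,
                noise_sd: float) -> np.ndarray:
    """One RGB image: blobs + sinusoidal texture + class layout + noise.

    The class signal has three components, all scaled by ``amplitude``:
    blob count, texture frequency, and a fixed per-class +-1 coarse
    brightness layout (a shape cue that survives blockwise pooling).
    """
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64) / size
    img = np.full((size, size), 128.0)
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0.15, 0.85, size=2)
        s = rng.uniform(0.06, 0.12)
        img += amplitude * 55.0 * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s * s)))
    phase = rng.uniform(0, 2 * np.pi)
    img += amplitude * 18.0 * np.sin(2 * np.pi * freq * xx + phase)
    g = layout.shape[0]
    block = size // g
    grid = np.kron(layout, np.ones((block, block)))
    img[: g * block, : g * block] += amplitude * 14.0 * grid
    img = img[..., None] + rng.normal(0.0, noise_sd, size=(size, size, 3))
    return np.clip(img, 0, 255).astype(np.uint8)


def _interaction_pair(rng: np.random.Generator, size: int, code: np.ndarray,
                      amplitude: float, noise_sd: float) -> tuple[np.ndarray, np.ndarray]:
    """Two image views whose per-block brightness signs multiply to ``code``.

    View A carries an i.i.d. random sign per block, view B carries that sign
    times the class code, so each view's marginal distribution is
    class-independent while the blockwise product reproduces the code.
    """
    g = int(np.sqrt(code.size))
    eps = rng.choice([-1.0, 1.0], size=(g, g))
    cls = code.reshape(g, g)
    block = size // g
    amp = amplitude * 40.0

    def render(signs: np.ndarray) -> np.ndarray:
        img = np.full((size, size), 128.0)
        grid = np.kron(signs, np.ones((block, block)))
        img[: g * block, : g * block] += amp * grid
        img = img[..., None] + rng.normal(0.0, noise_sd, size=(size, size, 3))
        return np.clip(img, 0, 255).astype(np.uint8)

    return render(eps), render(eps * cls)


def _class_codes(n_classes: int, n_blocks: int, seed: int) -> np.ndarray:
    """Distinct +-1 codes per class (fixed given seed), pairwise far apart."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0DE]))
    codes = rng.choice([-1.0, 1.0], size=(n_classes, n_blocks))
    # regenerate rows until all pairwise Hamming distances are positive
    for i in range(1, n_classes):
        while any(np.array_equal(codes[i], codes[j]) for j in range(i)):
            codes[i] = rng.choice([-1.0, 1.0], size=n_blocks)
    return codes


def generate_images(spec: SyntheticSpec):
    """Generate a labelled image set according to ``spec``.

    Returns
    -------
    images : uint8 array, ``(n, H, W, 3)`` -- or a pair of such arrays
        (view A, view B) when ``spec.interaction_only`` is set.
    labels : int array of length ``n`` with exactly ``n_per_class`` of each
        class, in class-major order.
    """
    n_total = spec.n_per_class * spec.n_classes
    labels = np.repeat(np.arange(spec.n_classes), spec.n_per_class)
    streams = np.random.SeedSequence(spec.seed).spawn(n_total)

    if spec.interaction_only:
        grid = 4
        codes = _class_codes(spec.n_classes, grid * grid, spec.seed)
        views_a = np.empty((n_total, spec.image_size, spec.image_size, 3), np.uint8)
        views_b = np.empty_like(views_a)
        for i, (lab, ss) in enumerate(zip(labels, streams)):
            rng = np.random.default_rng(ss)
            a, b = _interaction_pair(rng, spec.image_size, codes[lab],
                                     spec.signal_strength, spec.noise_sd)
            views_a[i], views_b[i] = a, b
        return (views_a, views_b), labels

    layouts = _class_codes(spec.n_classes, 16, spec.seed).reshape(-1, 4, 4)
    images = np.empty((n_total, spec.image_size, spec.image_size, 3), np.uint8)
    for i, (lab, ss) in enumerate(zip(labels, streams)):
        rng = np.random.default_rng(ss)
        # class signal: blob count 1..K, texture frequency 3..3+2(K-1),
        # and a per-class coarse layout; all vanish at signal_strength 0
        images[i] = _blob_image(rng, spec.image_size, n_blobs=1 + int(lab),
                                freq=3.0 + 2.0 * int(lab),
                                layout=layouts[lab],
                                amplitude=spec.signal_strength,
                                noise_sd=spec.noise_sd)
    return images, labels


def generate_feature_fixture(n: int, dA: int, dB: int, n_classes: int = 5,
                             separation: float = 1.0, seed: int = 0) -> FeatureFixture:
    """Class-conditional Gaussian feature clusters in two views.

    Class centroids are unit directions scaled by ``separation``; within-class
    spread is unit Gaussian, so expected centroid distance grows linearly in
    ``separation`` and ``separation=0`` removes all class signal.
    """
    if dA < 1 or dB < 1:
        raise ValidationError("feature dimensions must be >= 1")
    if n < n_classes:
        raise ValidationError("n must be >= n_classes")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    labels = np.arange(n) % n_classes
    rng.shuffle(labels)

    def draw(d: int) -> np.ndarray:
        cent = rng.normal(size=(n_classes, d))
        cent /= np.linalg.norm(cent, axis=1, keepdims=True)
        return separation * cent[labels] + rng.normal(size=(n, d))

    return FeatureFixture(draw(dA), draw(dB), labels)


def generate_interaction_fixture(n: int, d: int = 16, n_classes: int = 5,
                                 noise_sd: float = 0.3, seed: int = 0) -> FeatureFixture:
    """Two feature views informative only through their elementwise product.

    Each class has a +-1 code ``c_k``; a sample draws i.i.d. signs ``eps`` and
    returns view A = eps + noise, view B = eps * c_k + noise.  Marginally both
    views are sign-symmetric regardless of class (chance-level alone), while
    A * B ~= c_k recovers the code.
    """
    if n < n_classes:
        raise ValidationError("n must be >= n_classes")
    if d < 1:
        raise ValidationError("feature dimension must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    codes = _class_codes(n_classes, d, seed)
    labels = np.arange(n) % n_classes
    rng.shuffle(labels)
    eps = rng.choice([-1.0, 1.0], size=(n, d))
    a = eps + rng.normal(0.0, noise_sd, size=(n, d))
    b = eps * codes[labels] + rng.normal(0.0, noise_sd, size=(n, d))
    return FeatureFixture(a, b, labels)


def write_image_tree(images: np.ndarray, labels: np.ndarray, root: Path,
                     class_names: tuple[str, ...] | None = None) -> dict:
    """Write a directory-per-class PNG tree and return its manifest."""
    root = Path(root)
    n_classes = int(labels.max()) + 1
    names = class_names or DEFAULT_CLASS_NAMES[:n_classes]
    if len(names) < n_classes:
        names = tuple(f"class_{k}" for k in range(n_classes))
    counters = dict.fromkeys(range(n_classes), 0)
    entries = []
    for img, lab in zip(images, labels):
        cdir = root / names[lab]
        cdir.mkdir(parents=True, exist_ok=True)
        idx = counters[int(lab)]
        counters[int(lab)] += 1
        path = cdir / f"{idx:05d}.png"
        Image.fromarray(img).save(path)
        entries.append({"path": str(path.relative_to(root)), "label": int(lab)})
    manifest = {"class_names": list(names), "n_images": len(entries), "entries": entries}
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def write_feature_fixture(fx: FeatureFixture, path_a: Path, path_b: Path) -> None:
    """Write each view as CSV with header ``label,f0,f1,...``."""
    for mat, path in ((fx.features_a, path_a), (fx.features_b, path_b)):
        d = mat.shape[1]
        header = "label," + ",".join(f"f{i}" for i in range(d))
        data = np.column_stack([fx.labels.astype(float), mat])
        np.savetxt(path, data, delimiter=",", header=header, comments="",
                   fmt=["%d"] + ["%.10g"] * d)


def read_feature_fixture(path_a: Path, path_b: Path) -> FeatureFixture:
    a = np.loadtxt(path_a, delimiter=",", skiprows=1, ndmin=2)
    b = np.loadtxt(path_b, delimiter=",", skiprows=1, ndmin=2)
    labels_a, labels_b = a[:, 0].astype(int), b[:, 0].astype(int)
    if not np.array_equal(labels_a, labels_b):
        raise ValidationError("the two fixture files carry different labels")
    return FeatureFixture(a[:, 1:], b[:, 1:], labels_a)
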