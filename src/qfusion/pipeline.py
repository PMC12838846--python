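"""End-to-end pipeline: data -> stats -> splits -> candidates -> fusion -> report.

Each run directory is self-describing: resolved config, label map, channel
stats, split spec, per-candidate scores, train logs, checkpoint manifest and
metrics CSVs are all persisted, so a run can be replayed exactly from its
directory and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .backbones import (CandidateScore, extract_features, fit_linear_probe,
                        get_backbone, list_backbones, score_candidate,
                        select_top_two)
from .errors import ValidationError
from .evaluation import confusion_matrix, metrics_from_cm
from .fusion import FusionConfig, FusionModel
from .preprocessing import (compute_channel_stats, load_image_tree, make_splits,
                            normalize, resize_images)
from .synthetic import SyntheticSpec, generate_images, write_image_tree
from .training import TrainConfig, train_fusion


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    data_root: str = ""
    out_dir: str = "runs/default"
    image_size: int = 224
    stats_from: str = "all"  # "all" (study protocol) or "train" (no leakage)
    test_fraction: float = 0.20
    val_fraction_of_train: float = 0.10
    candidates: list[str] = field(default_factory=list_backbones)
    feature_dim: int = 768
    P: int = 256
    r: int = 32
    n_heads: int = 4
    hidden_dim: int = 256
    dropout_rate: float = 0.3
    eps: float = 1e-6
    pooling: str = "mean"
    train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0

    def to_yaml(self, path: Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "train" in d and isinstance(d["train"], dict):
            d["train"] = TrainConfig(**d["train"])
        return cls(**d)


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a summary dict and writes reports.

    The comparison table holds one row per fine-tuned candidate plus a
    concatenation+MLP baseline over the two selected backbones and the
    fusion model itself, all scored on the held-out test split.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    if not config.data_root or not Path(config.data_root).is_dir():
        raise ValidationError(f"data root {config.data_root!r} does not exist")

    images, labels, class_names = load_image_tree(Path(config.data_root),
                                                  config.image_size)
    n_classes = len(class_names)
    (out / "label_map.json").write_text(json.dumps(
        {i: n for i, n in enumerate(class_names)}, indent=1))

    splits = make_splits(labels, config.test_fraction,
                         config.val_fraction_of_train, seed=config.seed)
    splits.to_json(out / "splits.json")
    tr, va, te = (np.asarray(x) for x in (splits.train_idx, splits.val_idx,
                                          splits.test_idx))

    stats_images = images if config.stats_from == "all" else images[tr]
    stats = compute_channel_stats(stats_images)
    stats.to_json(out / "channel_stats.json")
    norm = normalize(images, stats)

    # candidate fine-tuning, scored on the validation split
    tcfg = TrainConfig(**{**asdict(config.train), "seed": config.seed})
    scores: list[CandidateScore] = []
    for name in config.candidates:
        handle = get_backbone(name, config.feature_dim)
        scores.append(score_candidate(handle, norm[tr], labels[tr],
                                      norm[va], labels[va], n_classes, tcfg))
    pd.DataFrame([asdict(s) for s in scores]).to_csv(
        out / "candidate_scores.csv", index=False)
    best, second = select_top_two(scores)
    (out / "selected_backbones.json").write_text(json.dumps(
        {"backbone_a": best.name, "backbone_b": second.name}, indent=1))

    hA = get_backbone(best.name, config.feature_dim)
    hB = get_backbone(second.name, config.feature_dim)
    zA = extract_features(hA, norm)
    zB = extract_features(hB, norm)

    rows = []

    def test_metrics(preds: np.ndarray):
        cm = confusion_matrix(labels[te], preds, n_classes, class_names)
        return cm, metrics_from_cm(cm)

    # per-candidate rows on the test split
    for sc in scores:
        h = get_backbone(sc.name, config.feature_dim)
        z = extract_features(h, norm)
        W, b = fit_linear_probe(z[tr], labels[tr], z[va], labels[va],
                                n_classes, tcfg)
        _, rep = test_metrics(np.argmax(z[te] @ W + b, axis=1))
        rows.append({"model": sc.name, **rep.aggregates()})

    # concat + MLP baseline over the two selected backbones
    zcat = np.concatenate([zA, zB], axis=1)
    Wc, bc = fit_linear_probe(zcat[tr], labels[tr], zcat[va], labels[va],
                              n_classes, tcfg)
    _, rep_cat = test_metrics(np.argmax(zcat[te] @ Wc + bc, axis=1))
    rows.append({"model": f"concat+mlp ({best.name}+{second.name})",
                 **rep_cat.aggregates()})

    # the fusion model
    fcfg = FusionConfig(dA=config.feature_dim, dB=config.feature_dim,
                        P=config.P, r=config.r, n_heads=config.n_heads,
                        hidden_dim=config.hidden_dim,
                        dropout_rate=config.dropout_rate,
                        n_classes=n_classes, eps=config.eps,
                        pooling=config.pooling, seed=config.seed)
    model = FusionModel(fcfg)
    log = train_fusion(model, zA[tr], zB[tr], labels[tr],
                       zA[va], zB[va], labels[va], tcfg)
    log.to_csv(out / "fusion_train_log.csv")
    model.save(out / "fusion_checkpoint.npz", out / "fusion_manifest.json")
    cm, rep_fusion = test_metrics(model.predict(zA[te], zB[te]))
    cm.to_json(out / "fusion_confusion.json")
    rep_fusion.to_csv(out / "fusion_per_class.csv")
    rows.append({"model": "qfm-fusion", **rep_fusion.aggregates()})

    table = pd.DataFrame(rows)
    table.to_csv(out / "comparison.csv", index=False)
    return {"selected": (best.name, second.name),
            "comparison": table,
            "fusion_report": rep_fusion,
            "confusion": cm,
            "train_log": log}


def synthesize_dataset(out_root: Path, n_per_class: int = 40, image_size: int = 224,
                       n_classes: int = 5, signal_strength: float = 1.0,
                       noise_sd: float = 12.0, seed: int = 0) -> dict:
    """Generate and write a synthetic directory-per-class dataset."""
    spec = SyntheticSpec(n_per_class=n_per_class, image_size=image_size,
                         n_classes=n_classes, signal_strength=signal_strength,
                         noise_sd=noise_sd, seed=seed)
    images, labels = generate_images(spec)
    return write_image_tree(images, labels, Path(out_root))
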