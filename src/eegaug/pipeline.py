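"""End-to-end run: synthetic EEG -> DE topomaps -> per-emotion VAE-D2GAN ->
augmented classifier -> metrics.

Everything is a pure function of the run configuration, whose global seed
feeds every random draw site; re-running an identical configuration
reproduces ``metrics.json`` bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .classifier import ClassifierConfig, accuracy, train_classifier
from .evaluation import KernelSpec, evaluate_quality
from .features import (BandSet, LDSConfig, compute_de, lds_smooth,
                       make_topomap, synthetic_layout)
from .generative import save_checkpoint
from .synthetic_data import default_profiles, synth_eeg
from .training import (TrainConfig, assemble_training_set,
                       fit_augmentation_plan, generate_augmented_set)


@dataclass
class RunConfig:
    """Every knob of one pipeline run; round-trips through YAML."""

    seed: int = 0
    # synthetic data
    n_classes: int = 3
    n_channels: int = 62
    segments_per_class: int = 100
    duration_s: float = 1.0
    fs: float = 200.0
    train_fraction: float = 0.6      # leading fraction of each class's session
    # features
    grid_size: int = 32
    lds_q: float = 1e-3
    lds_r: float = 1e-1
    # generative training
    iterations: int = 2000
    batch_size: int = 16
    learning_rate: float = 1e-4
    alpha: float = 0.2
    beta: float = 0.1
    latent_dim: int = 128
    base_channels: int = 64
    # augmentation
    n_per_emotion: int = 8000        # generated pool size per class
    n_generated: int = 2000          # generated samples added to training
    # classifier
    clf_epochs: int = 10
    clf_batch_size: int = 32
    clf_base_channels: int = 64
    pool_domains: bool = False
    # evaluation
    quality_subset: int = 500        # samples per side for the quality report

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(**yaml.safe_load(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _make_maps(config: RunConfig):
    """Synthetic EEG per class, DE + LDS, one shared train-set normalizer."""
    bands = BandSet()
    layout = synthetic_layout(config.n_channels, grid_size=config.grid_size)
    lds = LDSConfig(q=config.lds_q, r=config.lds_r)
    profiles = default_profiles(config.n_classes, config.n_channels)
    per_class_feats = {}
    for profile in profiles:
        segs = synth_eeg(profile, config.segments_per_class, config.duration_s,
                         config.fs, seed=config.seed * 1009 + profile.class_index)
        feats = [compute_de(s, bands) for s in segs]
        for i, f in enumerate(feats):
            f.segment_index = i
        per_class_feats[profile.class_index] = lds_smooth(feats, lds)
    n_train = int(round(config.train_fraction * config.segments_per_class))
    train_values = np.concatenate(
        [np.stack([f.values for f in feats[:n_train]])
         for feats in per_class_feats.values()])
    normalizer = np.stack([train_values.min(axis=(0, 1)),
                           train_values.max(axis=(0, 1))], axis=1)
    names = tuple(f"ch{i:02d}" for i in range(config.n_channels))

    def render(feats):
        return np.stack([make_topomap(f, layout, names, normalizer).image
                         for f in feats])

    xtr, ytr, xte, yte = [], [], [], []
    for cls, feats in per_class_feats.items():
        xtr.append(render(feats[:n_train]))
        ytr.append(np.full(n_train, cls))
        xte.append(render(feats[n_train:]))
        yte.append(np.full(len(feats) - n_train, cls))
    return (np.concatenate(xtr), np.concatenate(ytr),
            np.concatenate(xte), np.concatenate(yte), normalizer)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages and write maps, models, losses and metrics.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.to_yaml())

    x_train, y_train, x_test, y_test, normalizer = _make_maps(config)
    eio.save_maps(out / "train_maps.npz", x_train, y_train, normalizer)
    eio.save_maps(out / "test_maps.npz", x_test, y_test, normalizer)

    clf_cfg = ClassifierConfig(
        n_classes=config.n_classes, base_channels=config.clf_base_channels,
        learning_rate=config.learning_rate, batch_size=config.clf_batch_size,
        epochs=config.clf_epochs, seed=config.seed,
        pool_domains=config.pool_domains)
    baseline_clf = train_classifier(x_train, y_train, clf_cfg)
    baseline_acc = accuracy(baseline_clf.adapt_and_predict(x_test), y_test)

    metrics = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        # every random draw site and the seed it derives from the global one
        "seed_derivations": {
            "eeg_per_class": [config.seed * 1009 + c for c in range(config.n_classes)],
            "model_per_class": [config.seed + c for c in range(config.n_classes)],
            "generation_per_class": [[config.seed, c] for c in range(config.n_classes)],
            "classifier": config.seed,
            "assembly_and_quality_subset": config.seed,
        },
        "n_train_real": int(len(y_train)),
        "n_test": int(len(y_test)),
        "baseline_accuracy": baseline_acc,
        "augmented_accuracy": None,
        "quality": None,
    }

    if config.n_generated > 0:
        train_cfg = TrainConfig(
            learning_rate=config.learning_rate, batch_size=config.batch_size,
            iterations=config.iterations, alpha=config.alpha, beta=config.beta,
            latent_dim=config.latent_dim, base_channels=config.base_channels,
            seed=config.seed)
        plan = fit_augmentation_plan(x_train, y_train, train_cfg,
                                     samples_per_emotion=config.n_per_emotion)
        models_dir = out / "models"
        models_dir.mkdir(exist_ok=True)
        rows = []
        for cls, hist in plan.histories.items():
            save_checkpoint(models_dir / f"emotion_{cls}.npz", plan.models[cls])
            for it, rep in enumerate(hist):
                rows.append({"class": cls, "iteration": it, **rep.as_dict()})
        pd.DataFrame(rows).to_csv(out / "losses.csv", index=False)

        gen_maps, gen_labels = generate_augmented_set(plan)
        x_mix, y_mix, domains = assemble_training_set(
            x_train, y_train, gen_maps, gen_labels,
            n_generated=config.n_generated, seed=config.seed)
        aug_clf = train_classifier(x_mix, y_mix, clf_cfg, domains=domains)
        metrics["augmented_accuracy"] = accuracy(
            aug_clf.adapt_and_predict(x_test), y_test)

        # class-mixed subsets for the quality report (maps are class-ordered)
        qrng = np.random.default_rng(config.seed)
        m = config.quality_subset
        real_idx = qrng.permutation(len(y_train))[:m]
        gen_idx = qrng.permutation(len(gen_labels))[:m]
        report = evaluate_quality(x_train[real_idx], gen_maps[gen_idx],
                                  baseline_clf, KernelSpec())
        metrics["quality"] = report.as_dict()

    text = json.dumps(metrics, sort_keys=True, indent=2)
    (out / "metrics.json").write_text(text)
    return metrics
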