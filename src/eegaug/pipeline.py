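"""Training/evaluation orchestration: the Siamese flow, run configs, logging.

A run takes a :class:`~eegaug.core.DatasetBundle`, splits off a validation
set, then splits the training portion into a plain stream (task loss only)
and an enhanced stream (10% by default).  Every optimizer step combines the
task loss on a plain minibatch with the contrastive alignment loss between
the enhanced segments' embeddings and their augmented counterparts (each
branch optionally passed through cross-attention first), weighted by the
composite-loss coefficients alpha and beta.  Training keeps the
best-validation checkpoint and stops early after ``patience`` stagnant
epochs.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import augment as aug_mod
from .augment import AUGMENTATION_NAMES, AugmentationSpec
from .autodiff import Tensor, softmax
from .core import DatasetBundle, split_for_augmentation
from .losses import (EmbeddingPair, LossWeights, Temperature,
                     average_contrastive_loss, cross_attention_align,
                     cross_entropy_loss, l1_loss, negative_pearson_loss)
from .metrics import accuracy, similarity_report, spectrogram_pearson
from .model import LinearBaseline, NeuroBrain, NeuroBrainConfig
from .nn import AdamW
from .selection import (AugmentationWeights, SelectionResult, init_weights,
                        run_selection, weighted_contrastive_loss)

__all__ = ["RunConfig", "TrainLog", "train", "evaluate", "NetworkTrainer", "select"]


@dataclass
class RunConfig:
    """Everything a run needs; defaults follow the framework's protocol
    (AdamW, lr 5e-4, max 100 epochs, patience 6, 10% augmentation split,
    pruning threshold 0.4, alpha 0.01, beta 0.001)."""

    task: str = "reconstruction"
    model: str = "neurobrain"                 # or "linear"
    model_config: dict = field(default_factory=dict)
    augmentations: dict = field(
        default_factory=lambda: {name: {} for name in AUGMENTATION_NAMES})
    alpha: float = 0.01
    beta: float = 0.001
    lr: float = 5e-4
    max_epochs: int = 100
    patience: int = 6
    batch_size: int = 16
    aug_fraction: float = 0.1
    val_fraction: float = 0.2
    threshold: float = 0.4
    outlier_k: float = 1.5
    seed: int = 0
    max_steps: int | None = None
    use_cross_attention: bool = True
    symmetric_contrastive: bool = False
    contrastive_batch: int = 16
    resample_augmentation_split: bool = False  # resplit the 10% each epoch

    def __post_init__(self):
        for name in self.augmentations:
            if name not in AUGMENTATION_NAMES:
                raise ValueError(f"unknown augmentation '{name}'")
        if self.model not in ("neurobrain", "linear"):
            raise ValueError(f"unknown model preset '{self.model}'")

    # ---- serialization -------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def manifest(self) -> dict:
        digest = hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()).hexdigest()
        return {"config_hash": digest[:16], "seed": self.seed}


@dataclass
class TrainLog:
    rows: list[dict] = field(default_factory=list)
    stop_reason: str = ""
    best_epoch: int = -1
    best_score: float = -np.inf
    manifest: dict = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> None:
        if not self.rows:
            Path(path).write_text("")
            return
        with open(path, "w", newline="") as f:
            writer = csv.DictWriter(f, fieldnames=list(self.rows[0]))
            writer.writeheader()
            writer.writerows(self.rows)


def _build_model(config: RunConfig, bundle: DatasetBundle):
    """Model config is reconciled with the bundle's actual shapes."""
    seg = bundle.segments[0]
    overrides = dict(config.model_config)
    overrides.update(channels=seg.n_channels, time_samples=seg.n_samples,
                     task=config.task)
    if config.task == "reconstruction":
        overrides.setdefault("mel_bins", bundle.targets[0].spec.shape[0])
        overrides.setdefault("n_transposed", 3)
    else:
        overrides.setdefault("n_classes",
                             int(max(t.label for t in bundle.targets)) + 1)
        overrides.setdefault("n_transposed", 1)
    cfg = NeuroBrainConfig(**overrides)
    cls = NeuroBrain if config.model == "neurobrain" else LinearBaseline
    return cls(cfg, seed=config.seed)


def _resample_frames(y: np.ndarray, frames: int) -> np.ndarray:
    """Linearly resample targets [N, mel, T] to the model's frame count."""
    if y.shape[-1] == frames:
        return y
    old = np.arange(y.shape[-1], dtype=float)
    new = np.linspace(0.0, y.shape[-1] - 1.0, frames)
    return np.apply_along_axis(lambda row: np.interp(new, old, row), -1, y)


def _contrastive_term(model, enh_x: np.ndarray, specs: list[AugmentationSpec],
                      enh_segments, temperature: Temperature,
                      weights: AugmentationWeights | None, config: RunConfig,
                      rng: np.random.Generator) -> Tensor:
    if not specs or enh_x.shape[0] < 2:
        return Tensor(0.0)
    idx = np.arange(enh_x.shape[0])
    if idx.size > config.contrastive_batch:
        idx = rng.choice(idx.size, size=config.contrastive_batch, replace=False)
    f_a, _ = model(enh_x[idx])
    pairs = []
    for spec in specs:
        aug_data = np.stack([
            aug_mod.apply(spec, enh_segments[i], rng=rng).data for i in idx])
        f_i, _ = model(aug_data)
        if config.use_cross_attention:
            f_i = cross_attention_align(f_a, f_i)
        pairs.append(EmbeddingPair(f_a, f_i, temperature.tau))
    if weights is not None:
        return weighted_contrastive_loss(pairs, weights)
    return average_contrastive_loss(pairs, symmetric=config.symmetric_contrastive)


def train(config: RunConfig, bundle: DatasetBundle,
          weights: AugmentationWeights | None = None,
          val_bundle: DatasetBundle | None = None):
    """Run the Siamese training flow; returns (model, TrainLog).

    With an empty augmentation set and alpha = beta = 0 this reduces to plain
    supervised training.  When ``weights`` is given the per-branch
    coefficients are trained jointly through the weighted contrastive loss.
    """
    if bundle.task != config.task:
        raise ValueError(f"bundle task '{bundle.task}' does not match config "
                         f"task '{config.task}'")
    rng = np.random.default_rng(config.seed)
    if val_bundle is None:
        n = len(bundle)
        n_val = max(1, int(round(config.val_fraction * n)))
        perm = rng.permutation(n)
        val_bundle = bundle.subset(sorted(perm[:n_val].tolist()))
        bundle = bundle.subset(sorted(perm[n_val:].tolist()))

    specs = [AugmentationSpec(name, dict(params))
             for name, params in sorted(config.augmentations.items())]
    if weights is not None and [s.name for s in specs] != weights.names:
        raise ValueError("augmentation set does not match the coefficient names")

    model = _build_model(config, bundle)
    temperature = Temperature(1.0)
    lw = LossWeights(alpha=config.alpha, beta=config.beta)
    params = model.parameters()
    if specs:
        params += temperature.parameters()
        if weights is not None:
            params += weights.parameters()
    opt = AdamW(params, lr=config.lr)

    plain, enhanced = split_for_augmentation(bundle, config.aug_fraction,
                                             seed=config.seed)
    x_val = val_bundle.eeg_array()
    y_val = val_bundle.target_array()
    frames = model.config.frames
    if config.task == "reconstruction":
        y_val = _resample_frames(y_val, frames)

    log = TrainLog(manifest=config.manifest())
    best_state = model.state_dict()
    stale = 0
    steps = 0
    done = False
    for epoch in range(config.max_epochs):
        if config.resample_augmentation_split:
            plain, enhanced = split_for_augmentation(bundle, config.aug_fraction,
                                                     seed=config.seed + epoch)
        x_train = plain.eeg_array()
        y_train = plain.target_array()
        if config.task == "reconstruction":
            y_train = _resample_frames(y_train, frames)
        enh_x = enhanced.eeg_array() if len(enhanced) else np.empty((0, 1, 1))
        order = rng.permutation(len(plain))
        epoch_losses = []
        model.train()
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            if batch.size < 2:
                continue
            emb, pred = model(x_train[batch])
            l_cont = _contrastive_term(model, enh_x, specs, enhanced.segments,
                                       temperature, weights, config, rng)
            if config.task == "reconstruction":
                yb = y_train[batch]
                l_task = negative_pearson_loss(pred, yb)
                l_aux = l1_loss(pred, yb)
                total = l_task + lw.alpha * l_cont + lw.beta * l_aux
            else:
                yb = y_train[batch]
                l_task = cross_entropy_loss(yb, softmax(pred, axis=1))
                l_aux = Tensor(0.0)
                total = l_task + lw.alpha * l_cont
            opt.zero_grad()
            total.backward()
            opt.step()
            steps += 1
            epoch_losses.append((float(l_task), float(l_cont), float(l_aux),
                                 float(total)))
            if config.max_steps is not None and steps >= config.max_steps:
                done = True
                break
        val_score = _validation_score(model, x_val, y_val, config.task)
        means = np.mean(epoch_losses, axis=0) if epoch_losses else np.zeros(4)
        log.rows.append({"epoch": epoch, "steps": steps,
                         "loss_task": round(float(means[0]), 6),
                         "loss_cont": round(float(means[1]), 6),
                         "loss_aux": round(float(means[2]), 6),
                         "loss_total": round(float(means[3]), 6),
                         "val_score": round(float(val_score), 6)})
        if val_score > log.best_score:
            log.best_score = float(val_score)
            log.best_epoch = epoch
            best_state = model.state_dict()
            stale = 0
        else:
            stale += 1
        if done:
            log.stop_reason = "max_steps"
            break
        if stale > config.patience:
            log.stop_reason = "early_stop"
            break
    if not log.stop_reason:
        log.stop_reason = "max_epochs"
    model.load_state_dict(best_state)
    model.eval()
    return model, log


def _validation_score(model, x_val: np.ndarray, y_val: np.ndarray,
                      task: str) -> float:
    model.eval()
    _, pred = model(x_val)
    if task == "reconstruction":
        return spectrogram_pearson(pred.data, y_val)
    return accuracy(y_val, pred.data.argmax(axis=1))


def evaluate(model, bundle: DatasetBundle, scale100: bool = False):
    """Score a trained model on a bundle.

    Reconstruction returns a :class:`SimilarityReport` (Pearson, SSIM,
    CW-SSIM, optionally x100); classification returns the accuracy fraction.
    """
    x = bundle.eeg_array()
    y = bundle.target_array()
    _, pred = model(x)
    if bundle.task == "classification":
        return accuracy(y, pred.data.argmax(axis=1))
    y = _resample_frames(y, pred.shape[-1])
    return similarity_report(pred.data, y, scale100=scale100)


class NetworkTrainer:
    """Real-model trainer satisfying the selection engine's interface."""

    def __init__(self, config: RunConfig, train_bundle: DatasetBundle,
                 val_bundle: DatasetBundle):
        self.config = config
        self.train_bundle = train_bundle
        self.val_bundle = val_bundle

    def train(self, policy, seed: int = 0):
        from dataclasses import replace
        names = sorted(policy)
        cfg = replace(self.config, seed=seed, augmentations={
            n: self.config.augmentations.get(n, {}) for n in names})
        w = init_weights(names, threshold=cfg.threshold) if names else None
        model, log = train(cfg, self.train_bundle, weights=w,
                           val_bundle=self.val_bundle)
        return {"model": model, "weights": w, "log": log}

    def evaluate(self, handle) -> tuple[float, dict[str, float]]:
        score = handle["log"].best_score
        w = handle["weights"].w if handle["weights"] is not None else {}
        return float(score), w


def select(config: RunConfig, bundle: DatasetBundle) -> SelectionResult:
    """Run the two-stage augmentation-integration search on real training."""
    rng = np.random.default_rng(config.seed)
    n = len(bundle)
    n_val = max(1, int(round(config.val_fraction * n)))
    perm = rng.permutation(n)
    val_bundle = bundle.subset(sorted(perm[:n_val].tolist()))
    train_bundle = bundle.subset(sorted(perm[n_val:].tolist()))
    trainer = NetworkTrainer(config, train_bundle, val_bundle)
    return run_selection(trainer, set(config.augmentations),
                         threshold=config.threshold,
                         outlier_k=config.outlier_k, seed=config.seed)
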