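"""Optimisation loop and patient-grouped cross-validation.

Defaults follow the clinical training recipe: SGD with momentum 0.9,
initial learning rate 0.005 annealed per batch with a cosine schedule over
30 epochs, batch size 16, label smoothing 0.1, weighted random oversampling
(with replacement) against class imbalance. Folds are split by patient
identifier so no patient contributes to both the training and the test set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import SGD, Tensor
from .network import ModelConfig, OCTClassifier
from .volio import AugmentConfig, NormStats, _augment_float, oversampling_weights, resize_patch

__all__ = [
    "TrainConfig",
    "TrainResult",
    "cosine_lr",
    "split_folds",
    "prepare_images",
    "train",
]


@dataclass
class TrainConfig:
    batch_size: int = 16
    epochs: int = 30
    lr0: float = 0.005
    momentum: float = 0.9
    label_smoothing: float = 0.1
    weight_decay: float = 0.0
    seed: int = 0
    input_size: int = 224
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    oversample: bool = True


def cosine_lr(step: int, total_steps: int, lr0: float) -> float:
    """Per-batch cosine annealing: lr0/2 * (1 + cos(pi * step/total)), floor 0."""
    if total_steps <= 0:
        raise ValueError("total_steps must be positive")
    if not 0 <= step <= total_steps:
        raise ValueError("step out of range")
    return lr0 / 2.0 * (1.0 + np.cos(np.pi * step / total_steps))


def split_folds(patient_ids, k: int = 10, seed: int = 0) -> dict[str, int]:
    """Patient-grouped fold assignment: shuffle unique patients, deal round
    robin; fold sizes differ by at most one patient."""
    unique = sorted(set(patient_ids))
    if k > len(unique):
        raise ValueError(f"k={k} exceeds the number of patients ({len(unique)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    return {unique[idx]: i % k for i, idx in enumerate(order)}


def prepare_images(patches: np.ndarray, input_size: int = 224) -> np.ndarray:
    """Resize raw uint8 patches once to (N, size, size) float32 on the 0-255 scale."""
    return np.stack([resize_patch(p, input_size) for p in patches])


@dataclass
class TrainResult:
    model: OCTClassifier
    history: list[dict]  # one record per epoch
    lr_log: list[float]  # learning rate at every optimiser step
    stats: NormStats


def _accuracy(model: OCTClassifier, images: np.ndarray, labels: np.ndarray,
              stats: NormStats) -> float:
    probs = model.predict_probs(((images - stats.mean) / stats.std)[:, None])
    return float((probs.argmax(axis=1) == labels).mean())


def train(patches: np.ndarray, labels: np.ndarray,
          model_config: ModelConfig | None = None,
          config: TrainConfig | None = None,
          heldout: tuple[np.ndarray, np.ndarray] | None = None) -> TrainResult:
    """Train a classifier on raw uint8 patches with integer class labels.

    Returns the trained model, a per-epoch history (loss terms, accuracy)
    and the full per-step learning-rate log. Fully deterministic for a
    fixed seed. ``heldout`` is an optional (patches, labels) pair evaluated
    every epoch.
    """
    cfg = config or TrainConfig()
    labels = np.asarray(labels, dtype=int)
    if len(patches) == 0:
        raise ValueError("empty training set")
    if len(np.unique(labels)) < 2:
        raise ValueError("training needs at least two classes")
    mcfg = model_config or ModelConfig(backbone_profile="test")
    mcfg.label_smoothing = cfg.label_smoothing

    rng = np.random.default_rng(cfg.seed)
    images = prepare_images(patches, cfg.input_size)  # float32, 0-255 scale
    stats = NormStats(mean=float(images.mean()), std=float(images.std()))
    held_images = prepare_images(heldout[0], cfg.input_size) if heldout else None

    model = OCTClassifier(mcfg)
    model.norm_mean = np.float32(stats.mean) * np.ones(1, dtype=np.float32)
    model.norm_std = np.float32(stats.std) * np.ones(1, dtype=np.float32)
    opt = SGD(model.parameters(), lr=cfg.lr0, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)

    n = len(images)
    if cfg.oversample:
        w = oversampling_weights(labels)
        p_sample = w / w.sum()
    else:
        p_sample = None
    n_batches = int(np.ceil(n / cfg.batch_size))
    total_steps = cfg.epochs * n_batches
    lr_log: list[float] = []
    history: list[dict] = []
    step = 0
    for epoch in range(cfg.epochs):
        # epoch length = dataset size, drawn with replacement under the
        # oversampling weights (uniform expected class frequencies)
        order = rng.choice(n, size=n, replace=True, p=p_sample)
        epoch_terms: dict[str, list[float]] = {}
        correct = 0
        for bi in range(n_batches):
            idx = order[bi * cfg.batch_size : (bi + 1) * cfg.batch_size]
            batch = np.empty((len(idx), cfg.input_size, cfg.input_size), dtype=np.float32)
            for j, i in enumerate(idx):
                batch[j] = _augment_float(images[i], cfg.augment, rng, 0.0, 255.0)
            x = Tensor(((batch - stats.mean) / stats.std)[:, None])
            yb = labels[idx]
            out = model(x)
            terms = model.loss(out, yb)
            opt.zero_grad()
            terms["total"].backward()
            opt.lr = cosine_lr(step, total_steps, cfg.lr0)
            lr_log.append(opt.lr)
            opt.step()
            step += 1
            correct += int((out["probs"].data.argmax(axis=1) == yb).sum())
            for k, v in terms.items():
                epoch_terms.setdefault(k, []).append(float(v.data))
        record = {
            "epoch": epoch,
            "loss": float(np.mean(epoch_terms["total"])),
            "train_accuracy": correct / n,
            "lr": lr_log[-1],
        }
        for k, vals in epoch_terms.items():
            if k != "total":
                record[f"loss_{k}"] = float(np.mean(vals))
        if held_images is not None:
            record["heldout_accuracy"] = _accuracy(model, held_images, heldout[1], stats)
        history.append(record)
    model.eval()
    return TrainResult(model=model, history=history, lr_log=lr_log, stats=stats)
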