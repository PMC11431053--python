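"""The desk-scale study fixture: a balanced five-class synthetic cohort and
the CPU training profile used by the end-to-end checks and examples.

Per-class patient counts are chosen so the windowed dataset carries at
least 200 patches per class at roughly one thousand patches total
(negative volumes contribute every window, positive volumes only their
lesion windows). Training uses the shallow test backbone at the native
128-pixel window resolution with the standard recipe (SGD momentum 0.9,
lr 0.005 with per-batch cosine annealing, batch 16, label smoothing 0.1,
weighted oversampling, 30 epochs).
"""

from __future__ import annotations

import numpy as np

from . import synthetic as syn
from .network import ModelConfig
from .training import TrainConfig, split_folds

__all__ = [
    "FIXTURE_PATIENTS_PER_CLASS",
    "fixture_model_config",
    "fixture_train_config",
    "build_fixture_cohort",
    "split_cohort",
    "oracle_prediction_grid",
]

FIXTURE_PATIENTS_PER_CLASS = {"MI": 4, "CY": 4, "EP": 4, "HSIL": 9, "CC": 9}


def fixture_model_config() -> ModelConfig:
    return ModelConfig(backbone_profile="test", n_textons=8, texton_dim=32)


def fixture_train_config(seed: int = 0, epochs: int = 30) -> TrainConfig:
    return TrainConfig(epochs=epochs, seed=seed, input_size=128)


def build_fixture_cohort(seed: int = 0,
                         counts: dict[str, int] | None = None,
                         config: syn.SyntheticConfig | None = None) -> list[syn.Patient]:
    """Cohort with exact per-class patient counts (deterministic per seed)."""
    counts = counts or FIXTURE_PATIENTS_PER_CLASS
    cfg = config or syn.SyntheticConfig()
    cohort: list[syn.Patient] = []
    for ci, (cls, n) in enumerate(sorted(counts.items())):
        sub = syn.generate_cohort(n, {cls: 1.0}, 1, cfg,
                                  seed=(seed * 211 + ci) % (2**31 - 1),
                                  id_prefix=f"{cls}-")
        cohort.extend(sub)
    return cohort


def split_cohort(cohort: list[syn.Patient], test_fraction: float = 0.25,
                 seed: int = 0) -> tuple[list[syn.Patient], list[syn.Patient]]:
    """Patient-grouped train/test split (fold 0 of a k-fold assignment)."""
    k = max(2, int(round(1.0 / test_fraction)))
    folds = split_folds([p.patient_id for p in cohort], k=k, seed=seed)
    test_ids = {pid for pid, f in folds.items() if f == 0}
    train = [p for p in cohort if p.patient_id not in test_ids]
    test = [p for p in cohort if p.patient_id in test_ids]
    return train, test


def oracle_prediction_grid(sv: syn.SyntheticVolume, window_size: int,
                           stride: int) -> np.ndarray:
    """Perfect patch classifier built from the ground-truth lesion mask:
    probability 1 on the lesion class over lesion windows, 1 on MI elsewhere."""
    flags = syn.lesion_window_flags(sv, window_size, stride)
    probs = np.zeros(flags.shape + (len(syn.CLASS_NAMES),))
    cls = syn.CLASS_NAMES.index(sv.class_label) if sv.is_positive else 0
    probs[..., 0] = ~flags
    probs[flags, cls] = 1.0
    return probs
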