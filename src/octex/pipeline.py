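"""End-to-end orchestration: simulate -> patchify -> train -> vote -> evaluate.

A :class:`RunConfig` (usually loaded from YAML) fully determines a run; the
snapshot written next to the artifacts reproduces it bit-for-bit under the
same seed. Stage logs go to a JSON-lines file in the output directory.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic as syn
from .evaluation import confusion_from_labels, metrics
from .network import CLASS_NAMES, ModelConfig, OCTClassifier, save_checkpoint
from .training import TrainConfig, split_folds, train
from .volio import NormStats, OCTVolume, extract_patches, resize_patch
from .voting import PatchPredictionGrid, VotingConfig, patient_verdict, vote_volume

__all__ = ["RunConfig", "StageError", "predict_volume", "run_end_to_end"]


class StageError(RuntimeError):
    """Failure of one pipeline stage, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "run"
    verbosity: int = 1
    # simulate block
    n_patients: int = 30
    class_mix: dict = field(default_factory=lambda: {c: 0.2 for c in CLASS_NAMES})
    volumes_per_patient: int = 1
    synthetic: syn.SyntheticConfig = field(default_factory=syn.SyntheticConfig)
    # patchify block
    patch: syn.PatchSpec = field(default_factory=syn.PatchSpec)
    # train block
    model: ModelConfig = field(default_factory=lambda: ModelConfig(
        backbone_profile="test", n_textons=8, texton_dim=32))
    train: TrainConfig = field(default_factory=TrainConfig)
    test_fraction: float = 0.3  # patient-grouped holdout
    # predict/vote block
    vote: VotingConfig = field(default_factory=VotingConfig)
    explain_examples: int = 0

    _BLOCKS = ("simulate", "train", "vote")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for block in cls._BLOCKS:
            if block not in d:
                raise ValueError(f"run config missing required block: {block!r}")
        sim = d.pop("simulate")
        cfg = cls(
            seed=int(d.get("seed", 0)),
            out_dir=str(d.get("out_dir", "run")),
            verbosity=int(d.get("verbosity", 1)),
            n_patients=int(sim.get("n_patients", 30)),
            class_mix=sim.get("class_mix", {c: 0.2 for c in CLASS_NAMES}),
            volumes_per_patient=int(sim.get("volumes_per_patient", 1)),
            synthetic=syn.SyntheticConfig(**sim.get("synthetic", {})),
            patch=syn.PatchSpec(**d.pop("patch", {})),
            test_fraction=float(d.get("test_fraction", 0.3)),
            explain_examples=int(d.get("explain_examples", 0)),
        )
        tr = dict(d.pop("train"))
        model_kwargs = tr.pop("model", {})
        if model_kwargs:
            cfg.model = ModelConfig.from_dict({**cfg.model.to_dict(), **model_kwargs})
        if "augment" in tr:
            from .volio import AugmentConfig

            tr["augment"] = AugmentConfig(**tr["augment"])
        cfg.train = TrainConfig(**tr)
        cfg.vote = VotingConfig(**d.pop("vote"))
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def snapshot(self) -> dict:
        d = asdict(self)
        d["model"] = self.model.to_dict()
        return d


def predict_volume(model: OCTClassifier, volume: OCTVolume, window_size: int,
                   stride: int, input_size: int = 224) -> PatchPredictionGrid:
    """Patch-level class probabilities for one volume, as a (F, W, C) grid."""
    grid = extract_patches(volume, window_size, stride)
    stats = NormStats(mean=float(model.norm_mean[0]), std=float(model.norm_std[0]))
    flat = grid.patches.reshape(-1, window_size, window_size)
    imgs = np.stack([(resize_patch(p, input_size) - stats.mean) / stats.std for p in flat])
    probs = model.predict_probs(imgs[:, None])
    return PatchPredictionGrid(
        probs=probs.reshape(grid.n_frames, grid.n_windows, -1),
        class_names=tuple(model.config.class_names),
    )


def run_end_to_end(config: RunConfig) -> dict:
    """Execute the full synthetic study; returns the metrics report dict."""
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.jsonl"

    def log(stage: str, **kw):
        rec = {"stage": stage, "time": time.time(), **kw}
        with open(log_path, "a") as fh:
            fh.write(json.dumps(rec) + "\n")
        if cfg.verbosity:
            print(f"[{stage}] " + ", ".join(f"{k}={v}" for k, v in kw.items()))

    with open(out / "config_snapshot.json", "w") as fh:
        json.dump(cfg.snapshot(), fh, indent=2, default=str)

    try:
        cohort = syn.generate_cohort(cfg.n_patients, cfg.class_mix,
                                     cfg.volumes_per_patient, cfg.synthetic, seed=cfg.seed)
        syn.write_cohort(cohort, out / "cohort")
        log("simulate", n_patients=len(cohort),
            n_volumes=sum(len(p.volumes) for p in cohort))
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", e) from e

    try:
        # patient-grouped train/test split via fold assignment
        k = max(2, int(round(1.0 / cfg.test_fraction)))
        folds = split_folds([p.patient_id for p in cohort], k=k, seed=cfg.seed)
        test_ids = {pid for pid, f in folds.items() if f == 0}
        train_cohort = [p for p in cohort if p.patient_id not in test_ids]
        test_cohort = [p for p in cohort if p.patient_id in test_ids]
        train_ds = syn.generate_patch_dataset(train_cohort, cfg.patch)
        test_ds = syn.generate_patch_dataset(test_cohort, cfg.patch)
        log("patchify", train_patches=len(train_ds), test_patches=len(test_ds))
    except Exception as e:  # noqa: BLE001
        raise StageError("patchify", e) from e

    try:
        tc = cfg.train
        log("train_start", batch_size=tc.batch_size, epochs=tc.epochs, lr0=tc.lr0,
            momentum=tc.momentum, label_smoothing=tc.label_smoothing,
            n_textons=cfg.model.n_textons, texton_dim=cfg.model.texton_dim,
            schedule="cosine per batch")
        result = train(train_ds.patches, train_ds.labels, cfg.model, tc,
                       heldout=(test_ds.patches, test_ds.labels) if len(test_ds) else None)
        save_checkpoint(result.model, out / "checkpoint.npz")
        with open(out / "train_history.jsonl", "w") as fh:
            for rec in result.history:
                fh.write(json.dumps(rec) + "\n")
        log("train", final_loss=result.history[-1]["loss"],
            heldout_accuracy=result.history[-1].get("heldout_accuracy"))
    except Exception as e:  # noqa: BLE001
        raise StageError("train", e) from e

    try:
        rows = []
        vol_pred, vol_true, pat_pred, pat_true = [], [], [], []
        for patient in test_cohort:
            verdicts = []
            for vi, sv in enumerate(patient.volumes):
                grid = predict_volume(result.model, sv.volume, cfg.patch.window_size,
                                      cfg.patch.stride, cfg.train.input_size)
                verdict = vote_volume(grid, cfg.vote)
                verdicts.append(verdict)
                vol_pred.append(verdict.positive)
                vol_true.append(bool(sv.is_positive))
                for (fi, wi), rho in np.ndenumerate(grid.risk):
                    rows.append({"patient_id": patient.patient_id, "volume_index": vi,
                                 "frame": fi, "window": wi, "risk": float(rho)})
            pat_pred.append(patient_verdict(verdicts))
            pat_true.append(bool(patient.binary_label))
        pd.DataFrame(rows).to_csv(out / "patch_risk.csv", index=False)
        log("predict", volumes=len(vol_true), patients=len(pat_true))
    except Exception as e:  # noqa: BLE001
        raise StageError("predict", e) from e

    try:
        report = {
            "heldout_patch_accuracy": result.history[-1].get("heldout_accuracy"),
            "volume": metrics(confusion_from_labels(vol_pred, vol_true), with_ci=True).as_percent()
            if len(set(vol_true)) > 0 else None,
            "patient": metrics(confusion_from_labels(pat_pred, pat_true), with_ci=True).as_percent()
            if len(set(pat_true)) > 0 else None,
            "n_test_volumes": len(vol_true),
            "n_test_patients": len(pat_true),
        }
        with open(out / "metrics.json", "w") as fh:
            json.dump(report, fh, indent=2)
        log("evaluate", **{k: v for k, v in report.items() if not isinstance(v, dict)})
    except Exception as e:  # noqa: BLE001
        raise StageError("evaluate", e) from e

    if cfg.explain_examples:
        try:
            from .interpret import grad_cam_stack, overlay
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            done = 0
            hm_dir = out / "heatmaps"
            hm_dir.mkdir(exist_ok=True)
            stats = NormStats(float(result.model.norm_mean[0]), float(result.model.norm_std[0]))
            for patient in test_cohort:
                if done >= cfg.explain_examples:
                    break
                sv = patient.volumes[0]
                img = resize_patch(sv.volume.frames[0][: cfg.patch.window_size,
                                                       : cfg.patch.window_size],
                                   cfg.train.input_size)
                stack = grad_cam_stack(result.model, (img - stats.mean) / stats.std,
                                       CLASS_NAMES.index(sv.class_label))
                rgb = overlay(img, stack.heatmaps[3])
                plt.imsave(hm_dir / f"{patient.patient_id}_scaleIV.png", rgb)
                done += 1
            log("explain", heatmaps=done)
        except Exception as e:  # noqa: BLE001
            raise StageError("explain", e) from e

    return report
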