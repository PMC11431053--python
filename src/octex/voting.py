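"""Cross-shaped threshold voting: patch probabilities -> volume and patient verdicts.

A patch is high risk when its summed positive-class probability
rho = P(HSIL) + P(CC) reaches the threshold tau (0.8 by default). A volume
is positive when some high-risk patch has at least ``arm_length``
consecutive high-risk patches along the in-frame (window) axis and along
the cross-frame axis — the firing pattern looks like a cross, which makes
the verdict easy to audit. A patient is positive when any of her volumes
is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import CLASS_NAMES, POSITIVE_CLASSES

__all__ = [
    "VotingConfig",
    "PatchPredictionGrid",
    "VolumeVerdict",
    "patch_risk",
    "risk_grid",
    "vote_volume",
    "patient_verdict",
]


@dataclass
class VotingConfig:
    tau: float = 0.8  # high-risk probability threshold (inclusive)
    arm_length: int = 1  # minimum consecutive high-risk neighbors per direction

    def __post_init__(self):
        if not 0.0 < self.tau <= 1.0:
            raise ValueError("tau must lie in (0, 1]")
        if self.arm_length < 1:
            raise ValueError("arm_length must be >= 1")


@dataclass
class PatchPredictionGrid:
    """Per-(frame, window) class-probability vectors for one volume."""

    probs: np.ndarray  # (F, W, C)
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 3:
            raise ValueError("probs must be (frames, windows, classes)")
        if np.any(np.abs(p.sum(axis=-1) - 1.0) > 1e-4):
            raise ValueError("probability vectors must sum to 1")
        self.probs = p

    @property
    def risk(self) -> np.ndarray:
        """rho(f, w) = P(HSIL) + P(CC)."""
        idx = [self.class_names.index(c) for c in POSITIVE_CLASSES if c in self.class_names]
        return self.probs[..., idx].sum(axis=-1)


def patch_risk(prob_vector, tau: float = 0.8,
               class_names: tuple[str, ...] = CLASS_NAMES) -> tuple[float, bool]:
    """Risk score rho = P(HSIL) + P(CC) and its threshold flag (>= tau)."""
    p = np.asarray(prob_vector, dtype=float)
    if abs(p.sum() - 1.0) > 1e-4:
        raise ValueError(f"probability vector sums to {p.sum():.6f}")
    idx = [class_names.index(c) for c in POSITIVE_CLASSES if c in class_names]
    score = float(p[idx].sum())
    return score, score >= tau


def risk_grid(probs: np.ndarray, class_names: tuple[str, ...] = CLASS_NAMES) -> np.ndarray:
    return PatchPredictionGrid(probs=probs, class_names=class_names).risk


@dataclass
class VolumeVerdict:
    positive: bool
    cross_centers: list[tuple[int, int]] = field(default_factory=list)


def _run_lengths(high: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Consecutive high-risk run lengths extending from each cell in the four
    grid directions (excluding the cell itself); borders simply end the run."""
    f, w = high.shape
    left = np.zeros((f, w), dtype=int)
    right = np.zeros((f, w), dtype=int)
    up = np.zeros((f, w), dtype=int)
    down = np.zeros((f, w), dtype=int)
    for j in range(1, w):
        left[:, j] = np.where(high[:, j - 1], left[:, j - 1] + 1, 0)
    for j in range(w - 2, -1, -1):
        right[:, j] = np.where(high[:, j + 1], right[:, j + 1] + 1, 0)
    for i in range(1, f):
        up[i] = np.where(high[i - 1], up[i - 1] + 1, 0)
    for i in range(f - 2, -1, -1):
        down[i] = np.where(high[i + 1], down[i + 1] + 1, 0)
    return left, right, up, down


def vote_volume(grid: PatchPredictionGrid | np.ndarray,
                config: VotingConfig | None = None) -> VolumeVerdict:
    """Apply the cross-shaped rule to one volume's patch-prediction grid.

    ``grid`` may be a :class:`PatchPredictionGrid` or a precomputed (F, W)
    risk-score array.
    """
    config = config or VotingConfig()
    rho = grid.risk if isinstance(grid, PatchPredictionGrid) else np.asarray(grid, dtype=float)
    if rho.ndim != 2 or rho.size == 0:
        raise ValueError("risk grid must be a non-empty (frames, windows) array")
    high = rho >= config.tau
    left, right, up, down = _run_lengths(high)
    m = config.arm_length
    centers = high & ((left + right) >= m) & ((up + down) >= m)
    cc = [tuple(map(int, fw)) for fw in np.argwhere(centers)]
    return VolumeVerdict(positive=bool(cc), cross_centers=cc)


def patient_verdict(volume_verdicts) -> bool:
    """A subject is high risk if any of her volumes is positive."""
    verdicts = list(volume_verdicts)
    if not verdicts:
        raise ValueError("patient has no volume verdicts")
    return any(v.positive if isinstance(v, VolumeVerdict) else bool(v) for v in verdicts)
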