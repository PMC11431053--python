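"""Clinical evaluation statistics.

Confusion-matrix metrics for the binary high-risk task, exact
Clopper-Pearson 95% confidence intervals, rank-based AUC and the
Mann-Whitney U test. Metrics with a zero denominator are reported as
missing (None), never coerced to 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_from_labels",
    "metrics",
    "clopper_pearson",
    "roc_auc",
    "mann_whitney",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.total == 0:
            raise ValueError("confusion counts must not all be zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_from_labels(pred, truth) -> ConfusionCounts:
    """Binary counts from parallel 0/1 label sequences."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    return ConfusionCounts(
        tp=int((pred & truth).sum()),
        fp=int((pred & ~truth).sum()),
        fn=int((~pred & truth).sum()),
        tn=int((~pred & ~truth).sum()),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


@dataclass
class MetricsReport:
    """The six clinical metrics as proportions in [0, 1] (None if undefined),
    with optional exact binomial 95% CIs per metric."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    f1: float | None
    ci: dict[str, tuple[float, float]] | None = None

    def as_percent(self) -> dict:
        out = {}
        for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv", "f1"):
            v = getattr(self, name)
            out[name] = None if v is None else round(100.0 * v, 2)
        return out


def metrics(counts: ConfusionCounts, with_ci: bool = False, alpha: float = 0.05) -> MetricsReport:
    """Accuracy, sensitivity, specificity, PPV, NPV and F1 from counts.

    F1 is the harmonic mean of sensitivity and PPV, equivalently the
    proportion 2TP/(2TP + FP + FN); its CI (like all the others) is the
    exact Clopper-Pearson interval of the corresponding proportion.
    """
    c = counts
    rep = MetricsReport(
        accuracy=_ratio(c.tp + c.tn, c.total),
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        ppv=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
        f1=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    )
    if with_ci:
        pairs = {
            "accuracy": (c.tp + c.tn, c.total),
            "sensitivity": (c.tp, c.tp + c.fn),
            "specificity": (c.tn, c.tn + c.fp),
            "ppv": (c.tp, c.tp + c.fp),
            "npv": (c.tn, c.tn + c.fn),
            "f1": (2 * c.tp, 2 * c.tp + c.fp + c.fn),
        }
        rep.ci = {
            name: clopper_pearson(k, n, alpha) for name, (k, n) in pairs.items() if n > 0
        }
    return rep


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial CI for k successes in n trials, via beta quantiles.

    Lower bound is 0 when k = 0 and upper bound is 1 when k = n.
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"invalid (k={k}, n={n})")
    lower = 0.0 if k == 0 else float(_stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(_stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


def roc_auc(scores, binary_labels) -> float:
    """Area under the ROC curve; equals the rank statistic U/(n1*n2) with
    ties counted half."""
    labels = np.asarray(binary_labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def mann_whitney(sample_x, sample_y) -> tuple[float, float]:
    """Mann-Whitney U (for the first sample) and two-sided p-value.

    Exact enumeration when both samples have at most 8 observations and no
    ties; tie-corrected normal approximation otherwise.
    """
    x = np.asarray(sample_x, dtype=float)
    y = np.asarray(sample_y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    no_ties = len(np.unique(np.concatenate([x, y]))) == x.size + y.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and no_ties) else "asymptotic"
    res = _stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
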