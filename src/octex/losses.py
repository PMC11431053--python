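"""Deeply supervised loss: per-scale auxiliary cross-entropies plus a main
term on the fused prediction, with label-smoothing regularisation.

The total objective is the unweighted sum

    Loss = sum_a L_a(yhat_a, y) + L_m(yhat_m, y),

where each term is the cross-entropy  L(yhat, y) = -sum_i y_i log(yhat_i)
against the smoothed target distribution

    y_i = (1 - eps) * 1[i == true] + eps / C.

With eps = 0.1 the target keeps 90% of the mass on the annotated class and
spreads 10% uniformly over all C classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["smooth_labels", "cross_entropy", "fuse", "total_loss", "LossBreakdown"]

_PROB_FLOOR = 1e-12


def smooth_labels(true_class: int, eps: float, n_classes: int) -> np.ndarray:
    """Label-smoothed target distribution over ``n_classes`` categories."""
    if not (0.0 <= eps < 1.0):
        raise ValueError("smoothing parameter must lie in [0, 1)")
    if not (0 <= true_class < n_classes):
        raise ValueError("true_class out of range")
    y = np.full(n_classes, eps / n_classes, dtype=np.float64)
    y[true_class] += 1.0 - eps
    return y


def cross_entropy(pred_probs: np.ndarray, target: np.ndarray) -> float:
    """-sum_i y_i log(yhat_i); probabilities floored to avoid log(0)."""
    p = np.clip(np.asarray(pred_probs, dtype=np.float64), _PROB_FLOOR, None)
    return float(-(np.asarray(target) * np.log(p)).sum())


def fuse(scale_logits) -> np.ndarray:
    """Fuse per-scale logits into final class probabilities.

    The scale predictions are summed element-wise (on the logit scale) and
    passed through a softmax. Ties in the resulting argmax are broken toward
    the lowest class index (numpy's argmax convention).
    """
    logits = [np.asarray(v, dtype=np.float64) for v in scale_logits]
    n = {v.shape for v in logits}
    if len(n) != 1:
        raise ValueError("scale logit vectors must share one length")
    total = np.sum(logits, axis=0)
    total -= total.max()
    e = np.exp(total)
    return e / e.sum()


@dataclass
class LossBreakdown:
    auxiliary: list[float]  # one L_a per scale
    main: float  # L_m on the fused prediction
    target: np.ndarray  # smoothed target distribution

    @property
    def total(self) -> float:
        return float(sum(self.auxiliary) + self.main)


def total_loss(scale_probs, fused_probs: np.ndarray, true_class: int, eps: float) -> LossBreakdown:
    """Cross-entropy of every auxiliary prediction and the fused prediction
    against one smoothed target; the total is their unweighted sum."""
    first = np.asarray(fused_probs)
    y = smooth_labels(true_class, eps, first.shape[-1])
    aux = [cross_entropy(p, y) for p in scale_probs]
    main = cross_entropy(fused_probs, y)
    return LossBreakdown(auxiliary=aux, main=main, target=y)
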