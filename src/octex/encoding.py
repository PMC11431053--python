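"""Residual texture encoding with a learnable texton dictionary.

A feature map is read as an orderless set of descriptors
``X = {x_i, i = 1..N}`` (one per spatial location). Given a dictionary of K
textons ``C = {c_k}`` with per-texton smoothing factors ``s_k``, each
descriptor is softly assigned to every texton by a softmax over negative
scaled squared residual norms,

    a_ik = exp(-s_k * ||x_i - c_k||^2) / sum_j exp(-s_j * ||x_i - c_j||^2),

and the encoding aggregates assignment-weighted residuals per texton,

    e_k = sum_i a_ik * (x_i - c_k).

The result is K vectors of dimension D, flattened to a K*D texture feature.
Because the aggregation sums over descriptors, the encoding is invariant to
any permutation of spatial positions — it characterises *texture*, not
layout. The defaults are K = 32 textons of dimension D = 128.

These are the reference (pure numpy) forms; the trainable network in
:mod:`octex.network` evaluates the identical arithmetic on the autograd tape
and is tested against these functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TextonDictionary", "assign_weights", "encode", "squared_residual_norms"]


@dataclass
class TextonDictionary:
    """K learnable codewords of dimension D plus per-codeword smoothing factors."""

    codewords: np.ndarray  # (K, D)
    smoothing: np.ndarray  # (K,)

    def __post_init__(self):
        self.codewords = np.asarray(self.codewords, dtype=np.float64)
        self.smoothing = np.asarray(self.smoothing, dtype=np.float64)
        if self.codewords.ndim != 2:
            raise ValueError("codewords must be a (K, D) matrix")
        if self.smoothing.shape != (self.codewords.shape[0],):
            raise ValueError("smoothing must have one factor per codeword")
        if not np.all(np.isfinite(self.codewords)) or not np.all(np.isfinite(self.smoothing)):
            raise ValueError("dictionary entries must be finite")

    @property
    def n_textons(self) -> int:
        return self.codewords.shape[0]

    @property
    def dim(self) -> int:
        return self.codewords.shape[1]

    @classmethod
    def init_random(cls, n_textons: int = 32, dim: int = 128,
                    rng: np.random.Generator | None = None) -> "TextonDictionary":
        """Codewords uniform in (-1/sqrt(K), 1/sqrt(K)); smoothing uniform in (0, 1]."""
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / np.sqrt(n_textons)
        code = rng.uniform(-bound, bound, size=(n_textons, dim))
        smooth = rng.uniform(np.finfo(float).tiny, 1.0, size=n_textons)
        return cls(code, smooth)


def squared_residual_norms(descriptors: np.ndarray, dictionary: TextonDictionary) -> np.ndarray:
    """||x_i - c_k||^2 for every descriptor/texton pair, shape (N, K)."""
    x = np.asarray(descriptors, dtype=np.float64)
    c = dictionary.codewords
    if x.ndim != 2 or x.shape[1] != dictionary.dim:
        raise ValueError(f"descriptors must be (N, {dictionary.dim})")
    if not np.all(np.isfinite(x)):
        raise ValueError("descriptors must be finite")
    # expand ||x - c||^2 = ||x||^2 + ||c||^2 - 2 x.c ; clamp tiny negatives
    d2 = (x * x).sum(1)[:, None] + (c * c).sum(1)[None, :] - 2.0 * (x @ c.T)
    return np.maximum(d2, 0.0)


def assign_weights(descriptors: np.ndarray, dictionary: TextonDictionary) -> np.ndarray:
    """Soft-assignment matrix a_ik, each row a distribution over the K textons.

    Computed as a max-subtracted (numerically stable) softmax over
    ``-s_k * ||x_i - c_k||^2``.
    """
    d2 = squared_residual_norms(descriptors, dictionary)
    logits = -dictionary.smoothing[None, :] * d2
    logits -= logits.max(axis=1, keepdims=True)
    w = np.exp(logits)
    return w / w.sum(axis=1, keepdims=True)


@dataclass
class EncodedTexture:
    """Aggregated residual vectors e_k and their flattened K*D feature."""

    aggregated: np.ndarray  # (K, D)
    assignments: np.ndarray  # (N, K)

    @property
    def flattened(self) -> np.ndarray:
        return self.aggregated.reshape(-1)


def encode(descriptors: np.ndarray, dictionary: TextonDictionary) -> EncodedTexture:
    """Aggregate assignment-weighted residuals: e_k = sum_i a_ik (x_i - c_k)."""
    x = np.asarray(descriptors, dtype=np.float64)
    a = assign_weights(x, dictionary)
    # sum_i a_ik x_i  -  (sum_i a_ik) c_k
    agg = a.T @ x - a.sum(axis=0)[:, None] * dictionary.codewords
    return EncodedTexture(aggregated=agg, assignments=a)
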