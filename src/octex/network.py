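"""The multi-scale texture-encoding classifier.

Architecture, end to end:

1. **Backbone pyramid** — a four-stage residual network over a 224x224
   grayscale patch. The stages emit feature maps at 56x56, 28x28, 14x14 and
   7x7 (halving at every stage), forming a feature pyramid. Two profiles
   share this contract: ``reference`` mirrors a 101-layer bottleneck
   residual network (stage widths 256/512/1024/2048), ``test`` is a shallow
   basic-block network (widths 8/16/32/64) sized for CPU-only training.
2. **Feature encoding module** per scale — a 1x1 conv + batch-norm + ReLU
   block projects the stage output to D channels, and a residual texton
   encoding (see :mod:`octex.encoding`) pools the HxW descriptors into a
   K*D texture vector, independent of spatial arrangement.
3. **Auxiliary classifiers** — L2 normalisation followed by a fully
   connected layer gives per-scale class logits. The four logit vectors are
   summed element-wise and softmaxed into the final prediction; during
   training every scale also receives its own (deeply supervised) loss.

Ablation switches reproduce the structural baselines: ``use_pyramid=False``
keeps only the last scale (single-scale encoding), ``use_encoding=False``
replaces each encoding module with global average pooling (pyramid without
texture encoding), ``deep_supervision=False`` trains on the main loss only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autograd import (
    BatchNorm2d,
    Conv2d,
    Linear,
    MaxPool2d,
    Module,
    Parameter,
    ReLU,
    Sequential,
    Tensor,
)

__all__ = [
    "ModelConfig",
    "Backbone",
    "FeatureEncodingModule",
    "OCTClassifier",
    "save_checkpoint",
    "load_checkpoint",
    "CLASS_NAMES",
    "POSITIVE_CLASSES",
]

CLASS_NAMES = ("MI", "CY", "EP", "HSIL", "CC")
POSITIVE_CLASSES = ("HSIL", "CC")


@dataclass
class ModelConfig:
    """Hyper-parameters of the classifier.

    ``n_textons``/``texton_dim`` default to the reference setting K=32,
    D=128; the CPU test profile typically shrinks both.
    """

    n_classes: int = 5
    class_names: tuple[str, ...] = CLASS_NAMES
    backbone_profile: str = "reference"  # "reference" | "test"
    n_textons: int = 32
    texton_dim: int = 128
    label_smoothing: float = 0.1
    use_pyramid: bool = True
    use_encoding: bool = True
    deep_supervision: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["class_names"] = list(self.class_names)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["class_names"] = tuple(d.get("class_names", CLASS_NAMES))
        return cls(**d)


class _BasicBlock(Module):
    def __init__(self, in_ch, out_ch, stride, rng):
        super().__init__()
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride=stride, rng=rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng=rng)
        self.bn2 = BatchNorm2d(out_ch)
        self.down = None
        if stride != 1 or in_ch != out_ch:
            self.down = Sequential(Conv2d(in_ch, out_ch, 1, stride=stride, pad=0, rng=rng),
                                   BatchNorm2d(out_ch))

    def forward(self, x):
        out = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        sc = x if self.down is None else self.down(x)
        return (out + sc).relu()


class _Bottleneck(Module):
    def __init__(self, in_ch, mid_ch, out_ch, stride, rng):
        super().__init__()
        self.conv1 = Conv2d(in_ch, mid_ch, 1, pad=0, rng=rng)
        self.bn1 = BatchNorm2d(mid_ch)
        self.conv2 = Conv2d(mid_ch, mid_ch, 3, stride=stride, rng=rng)
        self.bn2 = BatchNorm2d(mid_ch)
        self.conv3 = Conv2d(mid_ch, out_ch, 1, pad=0, rng=rng)
        self.bn3 = BatchNorm2d(out_ch)
        self.down = None
        if stride != 1 or in_ch != out_ch:
            self.down = Sequential(Conv2d(in_ch, out_ch, 1, stride=stride, pad=0, rng=rng),
                                   BatchNorm2d(out_ch))

    def forward(self, x):
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out)).relu()
        out = self.bn3(self.conv3(out))
        sc = x if self.down is None else self.down(x)
        return (out + sc).relu()


_PROFILES = {
    # name: (stem_ch, block, blocks-per-stage, stage widths)
    "reference": (64, "bottleneck", (3, 4, 23, 3), (256, 512, 1024, 2048)),
    "test": (8, "basic", (1, 1, 1, 1), (8, 16, 32, 64)),
}


class Backbone(Module):
    """Four-stage residual pyramid: 224 -> 56 -> 28 -> 14 -> 7."""

    def __init__(self, profile: str = "reference", rng: np.random.Generator | None = None):
        super().__init__()
        if profile not in _PROFILES:
            raise ValueError(f"unknown backbone profile {profile!r}")
        rng = rng or np.random.default_rng(0)
        stem_ch, kind, depths, widths = _PROFILES[profile]
        self.profile = profile
        self.stage_channels = list(widths)
        if profile == "test":
            # one stride-4 stem conv straight to 56x56 keeps the CPU cost down
            self.stem = Sequential(Conv2d(1, stem_ch, 7, stride=4, pad=3, rng=rng),
                                   BatchNorm2d(stem_ch), ReLU())
        else:
            self.stem = Sequential(Conv2d(1, stem_ch, 7, stride=2, pad=3, rng=rng),
                                   BatchNorm2d(stem_ch), ReLU(), MaxPool2d())
        stages = []
        in_ch = stem_ch
        for si, (n_blocks, out_ch) in enumerate(zip(depths, widths)):
            stride = 1 if si == 0 else 2
            blocks = []
            for bi in range(n_blocks):
                s = stride if bi == 0 else 1
                if kind == "basic":
                    blocks.append(_BasicBlock(in_ch, out_ch, s, rng))
                else:
                    blocks.append(_Bottleneck(in_ch, out_ch // 4, out_ch, s, rng))
                in_ch = out_ch
            stages.append(Sequential(*blocks))
        self.stages = stages

    def forward(self, x: Tensor) -> list[Tensor]:
        if x.ndim != 4 or x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError("backbone expects (B, 1, H, W) with H, W divisible by 32")
        h = self.stem(x)
        maps = []
        for stage in self.stages:
            h = stage(h)
            maps.append(h)
        return maps


class FeatureEncodingModule(Module):
    """1x1 conv block to D channels followed by residual texton encoding."""

    def __init__(self, in_ch: int, n_textons: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.n_textons = n_textons
        self.dim = dim
        self.conv = Conv2d(in_ch, dim, 1, pad=0, rng=rng)
        self.bn = BatchNorm2d(dim)
        bound = 1.0 / np.sqrt(n_textons)
        self.codewords = Parameter(rng.uniform(-bound, bound, size=(n_textons, dim)))
        self.smoothing = Parameter(rng.uniform(np.finfo(np.float32).tiny, 1.0, size=n_textons))

    def conv_block(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()

    def encode(self, fmap: Tensor) -> Tensor:
        """(B, D, H, W) feature map -> (B, K*D) texture vector."""
        b, d, h, w = fmap.shape
        X = fmap.reshape(b, d, h * w).transpose(0, 2, 1)  # (B, N, D)
        C = self.codewords
        x2 = (X * X).sum(axis=-1, keepdims=True)  # (B, N, 1)
        c2 = (C * C).sum(axis=-1)  # (K,)
        cross = X @ C.transpose(1, 0)  # (B, N, K)
        d2 = x2 + c2 - 2.0 * cross
        logits = d2 * (-1.0 * self.smoothing)
        A = logits.softmax(axis=-1)  # (B, N, K)
        agg = A.transpose(0, 2, 1) @ X  # (B, K, D)
        counts = A.sum(axis=1)  # (B, K)
        agg = agg - counts.reshape(b, self.n_textons, 1) * C
        return agg.reshape(b, self.n_textons * self.dim)

    def forward(self, stage_map: Tensor) -> Tensor:
        return self.encode(self.conv_block(stage_map))


class _AuxClassifier(Module):
    """L2 normalisation followed by a fully connected layer."""

    def __init__(self, in_f: int, n_classes: int, rng: np.random.Generator):
        super().__init__()
        self.fc = Linear(in_f, n_classes, rng=rng)

    def forward(self, feat: Tensor) -> Tensor:
        return self.fc(feat.l2_normalize(axis=-1))


class OCTClassifier(Module):
    def __init__(self, config: ModelConfig | None = None):
        super().__init__()
        self.config = config or ModelConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self.backbone = Backbone(cfg.backbone_profile, rng=rng)
        # z-score statistics of the training split, filled in by the trainer
        self.norm_mean = np.zeros(1, dtype=np.float32)
        self.norm_std = np.ones(1, dtype=np.float32)
        chans = self.backbone.stage_channels
        self.scale_indices = list(range(4)) if cfg.use_pyramid else [3]
        self.encoders = []
        self.heads = []
        for si in self.scale_indices:
            if cfg.use_encoding:
                enc = FeatureEncodingModule(chans[si], cfg.n_textons, cfg.texton_dim, rng)
                head = _AuxClassifier(cfg.n_textons * cfg.texton_dim, cfg.n_classes, rng)
            else:
                enc = None
                head = _AuxClassifier(chans[si], cfg.n_classes, rng)
            self.encoders.append(enc)
            self.heads.append(head)

    def forward(self, x: Tensor) -> dict:
        pyramid = self.backbone(x)
        scale_logits = []
        for enc, head, si in zip(self.encoders, self.heads, self.scale_indices):
            fmap = pyramid[si]
            if enc is not None:
                feat = enc(fmap)
            else:  # global average pooling fallback (no texture encoding)
                b, c, h, w = fmap.shape
                feat = fmap.reshape(b, c, h * w).mean(axis=-1)
            scale_logits.append(head(feat))
        fused = scale_logits[0]
        for lg in scale_logits[1:]:
            fused = fused + lg
        return {
            "pyramid": pyramid,
            "scale_logits": scale_logits,
            "fused_logits": fused,
            "probs": fused.softmax(axis=-1),
        }

    def loss(self, out: dict, labels: np.ndarray) -> dict:
        """Deeply supervised objective on a batch; labels are class indices."""
        cfg = self.config
        b = len(labels)
        targets = np.full((b, cfg.n_classes), cfg.label_smoothing / cfg.n_classes)
        targets[np.arange(b), labels] += 1.0 - cfg.label_smoothing
        y = Tensor(targets.astype(np.float32))
        terms = {}
        total = None
        if cfg.deep_supervision:
            for si, lg in zip(self.scale_indices, out["scale_logits"]):
                la = (-1.0 * (y * lg.log_softmax(axis=-1)).sum(axis=-1)).mean()
                terms[f"aux_scale_{si + 1}"] = la
                total = la if total is None else total + la
        lm = (-1.0 * (y * out["fused_logits"].log_softmax(axis=-1)).sum(axis=-1)).mean()
        terms["main"] = lm
        total = lm if total is None else total + lm
        terms["total"] = total
        return terms

    def predict_probs(self, images: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Class probabilities for (N, 1, H, W) preprocessed patches (eval mode)."""
        self.eval()
        out = []
        for i in range(0, len(images), batch_size):
            res = self.forward(Tensor(images[i : i + batch_size].astype(np.float32)))
            out.append(res["probs"].data)
        self.train()
        return np.concatenate(out, axis=0) if out else np.zeros((0, self.config.n_classes))


def save_checkpoint(model: OCTClassifier, path) -> None:
    """Weights + config + class vocabulary in one npz archive."""
    state = model.named_state()
    meta = json.dumps(model.config.to_dict())
    np.savez(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> OCTClassifier:
    with np.load(path) as z:
        arrays = {k: z[k] for k in z.files}
    raw = arrays.pop("__config__", None)
    if raw is None:
        raise ValueError("not a classifier checkpoint: config record missing")
    cfg = ModelConfig.from_dict(json.loads(raw.tobytes().decode()))
    model = OCTClassifier(cfg)
    model.load_state(arrays)
    model.eval()
    return model
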