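"""Reading, writing and windowing of cervical OCT volumes.

A volume is a multi-page 8-bit grayscale TIFF: an ordered stack of 2-D
frames (B-scans) acquired at one o'clock position on the cervix, ten frames
per volume in the clinical protocol. Patches are extracted with a 1-D
horizontal sliding window per frame, resized to the network input size and
z-score normalised; training-time augmentation applies flips, brightness
jitter and additive noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from skimage.transform import resize as _sk_resize

__all__ = [
    "OCTVolume",
    "PatchGrid",
    "NormStats",
    "AugmentConfig",
    "read_volume",
    "write_volume",
    "extract_patches",
    "window_offsets",
    "preprocess_patch",
    "compute_norm_stats",
    "augment",
    "oversampling_weights",
]


@dataclass
class OCTVolume:
    """Ordered stack of 2-D grayscale frames plus subject metadata."""

    frames: np.ndarray  # (F, H, W) uint8
    patient_id: str = ""
    position_tag: str = ""  # o'clock position on the cervix, optional
    label: str | None = None

    def __post_init__(self):
        f = np.asarray(self.frames)
        if f.ndim == 2:
            f = f[None]
        if f.ndim != 3:
            raise ValueError("frames must be a (F, H, W) stack of 2-D grayscale images")
        self.frames = np.ascontiguousarray(f, dtype=np.uint8)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


def read_volume(path, patient_id: str = "", label: str | None = None) -> OCTVolume:
    """Read a multi-page grayscale TIFF into an :class:`OCTVolume` (page order kept)."""
    with tifffile.TiffFile(path) as tif:
        pages = []
        for page in tif.pages:
            if page.samplesperpixel != 1:
                raise ValueError(
                    f"{path}: unsupported photometric layout "
                    f"({page.samplesperpixel} samples/pixel); expected grayscale"
                )
            pages.append(page.asarray())
    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        raise ValueError(f"{path}: frames have mixed sizes {sorted(shapes)}")
    return OCTVolume(frames=np.stack(pages), patient_id=patient_id, label=label)


def write_volume(volume: OCTVolume, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, volume.frames, photometric="minisblack")


def window_offsets(frame_width: int, window_size: int, stride: int) -> np.ndarray:
    """x-offsets 0, stride, 2*stride, ... of every window that fits."""
    if window_size > frame_width:
        raise ValueError(f"window_size {window_size} exceeds frame width {frame_width}")
    if stride < 1:
        raise ValueError("stride must be positive")
    n = (frame_width - window_size) // stride + 1
    return np.arange(n) * stride


@dataclass
class PatchGrid:
    """Square patches indexed by (frame_index, window_index)."""

    patches: np.ndarray  # (F, n_windows, window, window) uint8
    window_size: int
    stride: int
    offsets: np.ndarray  # x-offset per window index

    @property
    def n_frames(self) -> int:
        return self.patches.shape[0]

    @property
    def n_windows(self) -> int:
        return self.patches.shape[1]


def extract_patches(volume: OCTVolume, window_size: int, stride: int) -> PatchGrid:
    """One horizontal row of sliding windows per frame.

    Patches are window_size x window_size, cropped from the top of the frame
    (frames shorter than the window are rejected).
    """
    h, w = volume.frame_shape
    if h < window_size:
        raise ValueError(f"frame height {h} shorter than window_size {window_size}")
    offsets = window_offsets(w, window_size, stride)
    patches = np.stack(
        [
            np.stack([volume.frames[f, :window_size, o : o + window_size] for o in offsets])
            for f in range(volume.n_frames)
        ]
    )
    return PatchGrid(patches=patches, window_size=window_size, stride=stride, offsets=offsets)


@dataclass
class NormStats:
    """Global z-score statistics, computed over the training split."""

    mean: float
    std: float

    def __post_init__(self):
        if not self.std > 0:
            raise ValueError("z-score normalisation requires std > 0")


def resize_patch(patch: np.ndarray, target_size: int = 224) -> np.ndarray:
    """Bilinear resize to target_size x target_size, intensity range preserved."""
    if patch.size == 0:
        raise ValueError("empty patch")
    return _sk_resize(
        patch.astype(np.float32), (target_size, target_size),
        order=1, preserve_range=True, anti_aliasing=False,
    ).astype(np.float32)


def compute_norm_stats(patches, target_size: int = 224) -> NormStats:
    """Mean/std over all pixels of the (resized) training patches."""
    resized = np.stack([resize_patch(p, target_size) for p in patches])
    return NormStats(mean=float(resized.mean()), std=float(resized.std()))


def preprocess_patch(patch: np.ndarray, stats: NormStats, target_size: int = 224) -> np.ndarray:
    """Resize to the network input size and z-score normalise."""
    return (resize_patch(patch, target_size) - stats.mean) / stats.std


@dataclass
class AugmentConfig:
    """Stochastic training-time transforms: flips, noise, brightness.

    ``noise_sigma`` is in intensity units on the 0-255 scale (default 2% of
    the dynamic range); brightness jitter is multiplicative.
    """

    p_hflip: float = 0.5
    p_vflip: float = 0.5
    p_noise: float = 0.5
    noise_sigma: float = 0.02 * 255.0
    p_brightness: float = 0.5
    brightness_range: tuple[float, float] = (0.8, 1.2)

    def __post_init__(self):
        for p in (self.p_hflip, self.p_vflip, self.p_noise, self.p_brightness):
            if not 0.0 <= p <= 1.0:
                raise ValueError("augmentation probabilities must lie in [0, 1]")

    @classmethod
    def off(cls) -> "AugmentConfig":
        return cls(p_hflip=0.0, p_vflip=0.0, p_noise=0.0, p_brightness=0.0)


def _augment_float(img: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator,
                   lo: float, hi: float) -> np.ndarray:
    if rng.random() < cfg.p_hflip:
        img = img[:, ::-1]
    if rng.random() < cfg.p_vflip:
        img = img[::-1, :]
    if rng.random() < cfg.p_brightness:
        img = img * rng.uniform(*cfg.brightness_range)
    if rng.random() < cfg.p_noise:
        img = img + rng.normal(0.0, cfg.noise_sigma, size=img.shape)
    return np.clip(img, lo, hi)


def augment(patch: np.ndarray, cfg: AugmentConfig, seed: int) -> np.ndarray:
    """Seeded augmentation of an 8-bit patch; intensities clamped to [0, 255]."""
    rng = np.random.default_rng(seed)
    out = _augment_float(patch.astype(np.float64), cfg, rng, 0.0, 255.0)
    return np.round(out).astype(np.uint8)


def oversampling_weights(labels) -> np.ndarray:
    """Per-patch weight 1/(class count): weighted draws with replacement give
    uniform expected class frequencies."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label list")
    _, inverse, counts = np.unique(labels, return_inverse=True, return_counts=True)
    return 1.0 / counts[inverse]
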