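"""Training-time augmentation and deterministic evaluation preprocessing.

Training images go through resize -> random horizontal flip -> small-angle
rotation -> color jitter -> ImageNet normalization, in that order, with
every random draw consumed from a caller-supplied generator. Evaluation
preprocessing is resize + normalize only and is bit-stable.

An offline balancing pass can additionally synthesize augmented copies of
under-represented classes until label counts are equal; copies inherit
their source subject id so subject-wise splits keep them with their
subject, and they are flagged ``augmented=1`` in the manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from skimage.color import hsv2rgb, rgb2hsv
from skimage.transform import resize as sk_resize, rotate as sk_rotate

from .labels import FaceRecord, N_CLASSES

__all__ = [
    "AugmentPolicy", "NormalizationStats", "IMAGENET_STATS",
    "train_transform", "eval_transform", "inverse_normalize",
    "hflip", "balance_offline",
]


@dataclass(frozen=True)
class NormalizationStats:
    mean: tuple[float, float, float]
    std: tuple[float, float, float]

    def __post_init__(self):
        if any(s <= 0 for s in self.std):
            raise ValueError("std must be strictly positive")


IMAGENET_STATS = NormalizationStats(mean=(0.485, 0.456, 0.406),
                                    std=(0.229, 0.224, 0.225))


@dataclass(frozen=True)
class AugmentPolicy:
    hflip_prob: float = 0.5
    rotation_limit_deg: float = 15.0
    brightness: float = 0.2
    contrast: float = 0.2
    saturation: float = 0.2
    hue: float = 0.1

    def __post_init__(self):
        if not 0.0 <= self.hflip_prob <= 1.0:
            raise ValueError("hflip_prob must be in [0,1]")
        for name in ("rotation_limit_deg", "brightness", "contrast",
                     "saturation", "hue"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def identity(cls) -> "AugmentPolicy":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    def to_dict(self) -> dict:
        return asdict(self)


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB image, got shape {image.shape}")
    return image


def _resize(image: np.ndarray, size: int) -> np.ndarray:
    if image.shape[:2] == (size, size):
        return image
    return sk_resize(image, (size, size), order=1, anti_aliasing=True)


def hflip(image: np.ndarray) -> np.ndarray:
    """Horizontal mirror (an involution: applied twice it is the identity)."""
    return _check_rgb(image)[:, ::-1].copy()


def _color_jitter(image: np.ndarray, policy: AugmentPolicy,
                  rng: np.random.Generator) -> np.ndarray:
    if policy.brightness:
        image = image * (1.0 + rng.uniform(-policy.brightness, policy.brightness))
    if policy.contrast:
        f = 1.0 + rng.uniform(-policy.contrast, policy.contrast)
        image = (image - image.mean()) * f + image.mean()
    image = np.clip(image, 0.0, 1.0)
    if policy.saturation or policy.hue:
        hsv = rgb2hsv(image)
        if policy.saturation:
            hsv[..., 1] = np.clip(
                hsv[..., 1] * (1.0 + rng.uniform(-policy.saturation,
                                                 policy.saturation)), 0.0, 1.0)
        if policy.hue:
            hsv[..., 0] = (hsv[..., 0] + rng.uniform(-policy.hue, policy.hue)) % 1.0
        image = hsv2rgb(hsv)
    return np.clip(image, 0.0, 1.0)


def _normalize(image: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    return (image - np.asarray(stats.mean)) / np.asarray(stats.std)


def train_transform(image: np.ndarray, policy: AugmentPolicy,
                    rng: np.random.Generator, size: int = 64,
                    stats: NormalizationStats = IMAGENET_STATS) -> np.ndarray:
    """Stochastic training preprocessing; output is HxWx3, normalized.

    Rotation is bilinear with exposed corners filled with 0 (before
    normalization). The generator is the only source of randomness.
    """
    image = _resize(_check_rgb(image), size)
    if policy.hflip_prob and rng.random() < policy.hflip_prob:
        image = image[:, ::-1]
    if policy.rotation_limit_deg:
        angle = rng.uniform(-policy.rotation_limit_deg, policy.rotation_limit_deg)
        image = sk_rotate(image, angle, order=1, mode="constant", cval=0.0)
    image = _color_jitter(image, policy, rng)
    return _normalize(image, stats)


def eval_transform(image: np.ndarray, size: int = 64,
                   stats: NormalizationStats = IMAGENET_STATS) -> np.ndarray:
    """Deterministic evaluation preprocessing: resize + normalize only."""
    return _normalize(_resize(_check_rgb(image), size), stats)


def inverse_normalize(image: np.ndarray,
                      stats: NormalizationStats = IMAGENET_STATS) -> np.ndarray:
    """Undo :func:`eval_transform`'s normalization (for display/overlays)."""
    return image * np.asarray(stats.std) + np.asarray(stats.mean)


def to_nchw(images: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Stack HxWx3 images into the model's (N,3,H,W) float32 layout."""
    arr = np.stack([np.asarray(im) for im in images])
    return np.ascontiguousarray(arr.transpose(0, 3, 1, 2)).astype(np.float32)


def balance_offline(records: list[FaceRecord], seed: int = 42,
                    policy: AugmentPolicy | None = None) -> list[FaceRecord]:
    """Equalize label counts by synthesizing augmented minority copies.

    Copies are produced by horizontal flip / moderate rotation / brightness
    (+-20%) of randomly chosen source images of that class, carry
    ``augmented=True`` and inherit the source subject id. Requires
    in-memory image arrays.
    """
    if policy is None:
        policy = AugmentPolicy(hflip_prob=0.5, rotation_limit_deg=15.0,
                               brightness=0.2, contrast=0.0, saturation=0.0,
                               hue=0.0)
    rng = np.random.default_rng(seed)
    by_label: dict[int, list[FaceRecord]] = {c: [] for c in range(N_CLASSES)}
    for r in records:
        by_label[r.label].append(r)
    target = max(len(v) for v in by_label.values())
    out = list(records)
    for label, group in by_label.items():
        if not group:
            raise ValueError(f"cannot balance: class {label} has no samples")
        deficit = target - len(group)
        for _ in range(deficit):
            src = group[rng.integers(len(group))]
            img = np.asarray(src.image_ref, dtype=np.float64)
            if img.ndim != 3:
                raise ValueError("balance_offline needs in-memory image arrays")
            if rng.random() < policy.hflip_prob:
                img = img[:, ::-1]
            if policy.rotation_limit_deg:
                img = sk_rotate(img, rng.uniform(-policy.rotation_limit_deg,
                                                 policy.rotation_limit_deg),
                                order=1, mode="constant", cval=0.0)
            if policy.brightness:
                img = np.clip(img * (1.0 + rng.uniform(-policy.brightness,
                                                       policy.brightness)), 0, 1)
            out.append(FaceRecord(image_ref=img.astype(np.float32),
                                  subject_id=src.subject_id,
                                  pspi_score=src.pspi_score, augmented=True))
    return out
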