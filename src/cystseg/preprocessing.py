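"""Image preprocessing: green-channel muting, augmentation, normalization.

The relevant fluorescence signal lives in the red (tissue) and blue
(nuclei) channels; the green channel carries noise or markers unrelated
to cyst detection.  "no-G" preprocessing zeroes the green channel while
keeping a 3-channel layout so pretrained 3-channel backbones still
accept the images.

The training-time augmentation pipeline applies, in order: horizontal
flip (p=0.5), right-angle rotation of +/-90 degrees (p=0.5), random
brightness (factor within +/-0.2, p=1), random contrast (factor within
+/-0.2, p=1), random gamma in [0.8, 1.2] (p=0.5), CLAHE (p=0.5), and
normalization to reference per-channel statistics (ImageNet by default).
Geometric transforms are applied identically to image and mask;
photometric transforms never touch the mask.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from skimage import exposure

__all__ = [
    "IMAGENET_MEAN",
    "IMAGENET_STD",
    "AugmentationConfig",
    "remove_green",
    "augment",
    "normalize",
    "denormalize",
    "apply_clahe",
    "hflip_pair",
    "rot90_pair",
]

IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)


@dataclass(frozen=True)
class AugmentationConfig:
    """Per-transform probabilities and parameters.

    Brightness/contrast limits are multiplicative: a limit of 0.2 means a
    factor drawn uniformly from [0.8, 1.2].  The gamma limit is in
    percent, (80, 120) meaning gamma in [0.8, 1.2].  The CLAHE clip limit
    follows the OpenCV convention (4.0) and is mapped internally to
    scikit-image's normalized clip limit.
    """

    hflip_p: float = 0.5
    rotate90_p: float = 0.5
    brightness_limit: float = 0.2
    brightness_p: float = 1.0
    contrast_limit: float = 0.2
    contrast_p: float = 1.0
    gamma_limit: tuple[float, float] = (80.0, 120.0)
    gamma_p: float = 0.5
    clahe_clip_limit: float = 4.0
    clahe_tile_grid: int = 8
    clahe_p: float = 0.5
    normalize_p: float = 1.0
    channel_means: tuple[float, float, float] = IMAGENET_MEAN
    channel_stds: tuple[float, float, float] = IMAGENET_STD
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hflip_p", "rotate90_p", "brightness_p", "contrast_p",
                     "gamma_p", "clahe_p", "normalize_p"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def disabled(cls, **overrides) -> "AugmentationConfig":
        """All transforms off — useful as an identity baseline."""
        params = dict(hflip_p=0.0, rotate90_p=0.0, brightness_p=0.0,
                      contrast_p=0.0, gamma_p=0.0, clahe_p=0.0, normalize_p=0.0)
        params.update(overrides)
        return cls(**params)


def remove_green(image: np.ndarray) -> np.ndarray:
    """Zero the green channel, keeping red/blue and the 3-channel layout."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) image, got shape {image.shape}")
    out = image.copy()
    out[..., 1] = 0
    return out


def normalize(
    image: np.ndarray,
    channel_means: tuple[float, float, float] = IMAGENET_MEAN,
    channel_stds: tuple[float, float, float] = IMAGENET_STD,
) -> np.ndarray:
    """Map a uint8 RGB image to float: per channel (x/255 - mean) / std."""
    stds = np.asarray(channel_stds, dtype=np.float64)
    if np.any(stds <= 0):
        raise ValueError("channel stds must be positive")
    means = np.asarray(channel_means, dtype=np.float64)
    return (np.asarray(image, dtype=np.float64) / 255.0 - means) / stds


def denormalize(
    image: np.ndarray,
    channel_means: tuple[float, float, float] = IMAGENET_MEAN,
    channel_stds: tuple[float, float, float] = IMAGENET_STD,
) -> np.ndarray:
    """Inverse of :func:`normalize`; returns a float array on the 0-255 scale."""
    stds = np.asarray(channel_stds, dtype=np.float64)
    means = np.asarray(channel_means, dtype=np.float64)
    return (np.asarray(image, dtype=np.float64) * stds + means) * 255.0


def apply_clahe(image: np.ndarray, clip_limit: float = 4.0, tile_grid: int = 8) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on each channel.

    ``clip_limit`` uses the OpenCV scale; it is divided by the histogram
    bin count (256) to obtain scikit-image's normalized clip limit.
    """
    img = np.asarray(image)
    kernel = (max(img.shape[0] // tile_grid, 1), max(img.shape[1] // tile_grid, 1))
    out = np.empty_like(img)
    for ch in range(img.shape[2]):
        eq = exposure.equalize_adapthist(
            img[..., ch], kernel_size=kernel, clip_limit=clip_limit / 256.0
        )
        out[..., ch] = (eq * 255.0).astype(img.dtype)
    return out


def _scale_clip(image: np.ndarray, factor: float) -> np.ndarray:
    return np.clip(image.astype(np.float64) * factor, 0.0, 255.0).astype(np.uint8)


def hflip_pair(image: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Horizontal flip applied jointly (an involution)."""
    return image[:, ::-1], mask[:, ::-1]


def rot90_pair(image: np.ndarray, mask: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Lossless right-angle rotation by k * 90 degrees, jointly."""
    return np.rot90(image, k), np.rot90(mask, k)


def augment(
    image: np.ndarray,
    mask: np.ndarray,
    config: AugmentationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the augmentation pipeline jointly to an image and its mask.

    With all probabilities at 0 the pair is returned unchanged.  The mask
    stays strictly boolean: only flips/rotations (lossless, no
    interpolation) touch it.
    """
    if image.shape[:2] != np.asarray(mask).shape[:2]:
        raise ValueError("image and mask must share height and width")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    img = np.asarray(image)
    msk = np.asarray(mask).astype(bool)

    if rng.random() < config.hflip_p:
        img, msk = hflip_pair(img, msk)
    if rng.random() < config.rotate90_p:
        k = 1 if rng.random() < 0.5 else 3  # +90 or -90 degrees
        img, msk = rot90_pair(img, msk, k)
    if rng.random() < config.brightness_p:
        factor = 1.0 + rng.uniform(-config.brightness_limit, config.brightness_limit)
        img = _scale_clip(img, factor)
    if rng.random() < config.contrast_p:
        factor = 1.0 + rng.uniform(-config.contrast_limit, config.contrast_limit)
        mean = img.mean()
        img = np.clip((img.astype(np.float64) - mean) * factor + mean, 0, 255).astype(np.uint8)
    if rng.random() < config.gamma_p:
        lo, hi = config.gamma_limit
        gamma = rng.uniform(lo, hi) / 100.0
        img = (255.0 * (img.astype(np.float64) / 255.0) ** gamma).astype(np.uint8)
    if rng.random() < config.clahe_p:
        img = apply_clahe(img, config.clahe_clip_limit, config.clahe_tile_grid)
    if rng.random() < config.normalize_p:
        img = normalize(img, config.channel_means, config.channel_stds)
    return np.ascontiguousarray(img), np.ascontiguousarray(msk)
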