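"""Image preprocessing: CLAHE enhancement, standardization, augmentation.

CLAHE (contrast-limited adaptive histogram equalization) is applied to the
luminance channel of a LAB decomposition so local contrast is boosted without
hue distortion — standard practice for fundus images.  The implementation
follows the classic tile-grid formulation in which the clip limit is a
multiple of the mean tile histogram height (the convention the reference
parameters, clip 2.0 with an 8x8 grid, are stated in): per-tile histograms
are clipped, the excess is redistributed uniformly, and per-pixel values are
bilinearly interpolated between the four neighbouring tile mappings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color
from skimage.transform import resize, rotate

__all__ = [
    "PreprocessConfig",
    "IMAGENET_MEAN",
    "IMAGENET_STD",
    "apply_clahe",
    "standardize",
    "augment",
    "preprocess_set",
]

#: de facto standard ImageNet per-channel normalization statistics
IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)


@dataclass(frozen=True)
class PreprocessConfig:
    clahe_clip_limit: float = 2.0
    clahe_tile_grid: tuple[int, int] = (8, 8)
    target_size: int = 224
    normalization_mean: tuple[float, float, float] = IMAGENET_MEAN
    normalization_std: tuple[float, float, float] = IMAGENET_STD
    augment: bool = False
    rotation_degrees: float = 15.0
    jitter_strength: float = 0.1
    hflip_prob: float = 0.5

    def __post_init__(self):
        if self.clahe_clip_limit <= 0:
            raise ValueError("clahe_clip_limit must be positive")
        if min(self.clahe_tile_grid) < 1:
            raise ValueError("clahe_tile_grid must be at least 1x1")
        if self.target_size < 32:
            raise ValueError("target_size must be >= 32")


def _clahe_channel(channel: np.ndarray, clip_limit: float, grid: tuple[int, int]) -> np.ndarray:
    """CLAHE on a single uint8 channel; clip limit in multiples of the mean
    tile histogram height, midpoint-CDF tile mappings, bilinear blending."""
    nbins = 256
    h, w = channel.shape
    gy, gx = grid
    th = -(-h // gy)  # ceil division
    tw = -(-w // gx)
    ph, pw = th * gy, tw * gx
    padded = np.pad(channel, ((0, ph - h), (0, pw - w)), mode="reflect")
    tiles = padded.reshape(gy, th, gx, tw).transpose(0, 2, 1, 3).reshape(gy, gx, th * tw)
    area = th * tw
    clip = max(int(clip_limit * area / nbins), 1)

    luts = np.empty((gy, gx, nbins), dtype=np.float64)
    for i in range(gy):
        for j in range(gx):
            hist = np.bincount(tiles[i, j], minlength=nbins).astype(np.float64)
            excess = np.maximum(hist - clip, 0.0).sum()
            hist = np.minimum(hist, clip) + excess / nbins
            cdf = hist.cumsum()
            luts[i, j] = (cdf - hist / 2.0) * (255.0 / area)

    ty = (np.arange(ph) + 0.5) / th - 0.5
    tx = (np.arange(pw) + 0.5) / tw - 0.5
    iy0 = np.floor(ty).astype(int)
    ix0 = np.floor(tx).astype(int)
    fy = (ty - iy0)[:, None]
    fx = (tx - ix0)[None, :]
    iy0c = np.clip(iy0, 0, gy - 1)
    iy1c = np.clip(iy0 + 1, 0, gy - 1)
    ix0c = np.clip(ix0, 0, gx - 1)
    ix1c = np.clip(ix0 + 1, 0, gx - 1)

    v00 = luts[iy0c[:, None], ix0c[None, :], padded]
    v01 = luts[iy0c[:, None], ix1c[None, :], padded]
    v10 = luts[iy1c[:, None], ix0c[None, :], padded]
    v11 = luts[iy1c[:, None], ix1c[None, :], padded]
    out = (1 - fy) * ((1 - fx) * v00 + fx * v01) + fy * ((1 - fx) * v10 + fx * v11)
    return np.clip(np.rint(out[:h, :w]), 0, 255).astype(np.uint8)


def _validate_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.size == 0:
        raise ValueError("expected a non-empty H x W x 3 RGB image")
    return image


def apply_clahe(image: np.ndarray, config: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """CLAHE on the LAB luminance channel; returns an RGB uint8 image."""
    image = _validate_rgb(image)
    lab = color.rgb2lab(image.astype(np.float64) / 255.0)
    lum = np.clip(np.rint(lab[..., 0] * 255.0 / 100.0), 0, 255).astype(np.uint8)
    enhanced = _clahe_channel(lum, config.clahe_clip_limit, tuple(config.clahe_tile_grid))
    lab[..., 0] = enhanced.astype(np.float64) * 100.0 / 255.0
    rgb = color.lab2rgb(lab)
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


def standardize(image: np.ndarray, config: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Resize (bilinear), scale to [0,1], per-channel normalize; returns C x H x W."""
    image = _validate_rgb(image)
    t = config.target_size
    scaled = image.astype(np.float64) / 255.0
    if image.shape[:2] != (t, t):
        scaled = resize(scaled, (t, t), order=1, anti_aliasing=False, preserve_range=True)
    mean = np.asarray(config.normalization_mean)
    std = np.asarray(config.normalization_std)
    out = (scaled - mean) / std
    return np.ascontiguousarray(out.transpose(2, 0, 1), dtype=np.float32)


def augment(
    image: np.ndarray, config: PreprocessConfig, rng: np.random.Generator
) -> np.ndarray:
    """Training-time augmentation: horizontal flip, rotation, colour jitter.

    Deterministic under the supplied generator; returns a uint8 RGB image of
    the same shape.  The random draws are made unconditionally so the stream
    consumed per image is fixed regardless of which transforms fire.
    """
    image = _validate_rgb(image)
    flip = rng.uniform() < config.hflip_prob
    angle = rng.uniform(-config.rotation_degrees, config.rotation_degrees)
    j = config.jitter_strength
    brightness, contrast, saturation = 1.0 + rng.uniform(-j, j, 3)

    out = image.astype(np.float64)
    if flip:
        out = out[:, ::-1, :]
    if angle != 0.0:
        out = rotate(out, angle, resize=False, preserve_range=True, mode="edge", order=1)
    out = out * brightness
    out = (out - out.mean()) * contrast + out.mean()
    gray = out.mean(axis=2, keepdims=True)
    out = gray + (out - gray) * saturation
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def preprocess_set(
    images: list[np.ndarray],
    config: PreprocessConfig = PreprocessConfig(),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Full pipeline over a list of images -> (N, 3, H, W) float32 batch.

    Order: CLAHE (full resolution) -> augmentation (training only, requires
    ``rng``) -> resize + normalize.  Without ``rng`` this is the deterministic
    evaluation-time pipeline.
    """
    out = []
    for img in images:
        x = apply_clahe(img, config)
        if config.augment and rng is not None:
            x = augment(x, config, rng)
        out.append(standardize(x, config))
    return np.stack(out)
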