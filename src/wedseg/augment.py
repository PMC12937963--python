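"""Paired image/mask augmentation.

Geometric transforms (affine, flip, resize) are applied jointly to the image
and its mask — bilinear resampling for intensities, nearest-neighbor for
labels so the label set {0,1} is preserved exactly.  Photometric transforms
(Gaussian noise, brightness/contrast, HSV shifts) touch the image only.
``augment_to_count`` expands a small source set to a fixed target size,
keeping the originals and synthesizing the remainder round-robin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage.transform import resize as sk_resize

from .synthetic import ImageMaskPair

__all__ = [
    "AugmentationPolicy", "horizontal_flip", "affine_transform", "add_gaussian_noise",
    "random_brightness_contrast", "hsv_shift", "resize_pair", "augment_to_count",
]


@dataclass
class AugmentationPolicy:
    """Per-transform probabilities and parameter ranges.

    Defaults: affine p=0.7 (rotation +-30 deg, scale 0.9-1.1, shift +-10% of
    the side), horizontal flip p=0.5, Gaussian noise p=0.3 (sigma 5-15),
    brightness/contrast p=0.3 (+-0.2), HSV p=0.3 (+-10 deg hue, +-20 sat/val).
    Composition order is fixed: geometric first, then photometric, noise last.
    """

    target_count: int = 3000
    size: int = 128
    seed: int = 0
    p_affine: float = 0.7
    rotation_range: tuple[float, float] = (-30.0, 30.0)
    scale_range: tuple[float, float] = (0.9, 1.1)
    shift_fraction: float = 0.1
    p_flip: float = 0.5
    p_noise: float = 0.3
    noise_sigma_range: tuple[float, float] = (5.0, 15.0)
    p_brightness_contrast: float = 0.3
    brightness_limit: float = 0.2
    contrast_limit: float = 0.2
    p_hsv: float = 0.3
    hue_shift_limit: float = 10.0
    sat_shift_limit: float = 20.0
    val_shift_limit: float = 20.0

    def __post_init__(self) -> None:
        for p in (self.p_affine, self.p_flip, self.p_noise,
                  self.p_brightness_contrast, self.p_hsv):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0,1]")
        if self.size % 16:
            raise ValueError(f"size must be divisible by 16, got {self.size}")


def horizontal_flip(pair: ImageMaskPair) -> ImageMaskPair:
    """Mirror image and mask about the vertical axis."""
    return ImageMaskPair(image=pair.image[:, ::-1].copy(), mask=pair.mask[:, ::-1].copy())


def _affine_matrix(height: int, width: int, rotation: float, scale: float,
                   shift: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Inverse map (output -> input) for rotation+scale about the image
    center followed by a (row, col) translation."""
    theta = np.deg2rad(rotation)
    c, s = np.cos(theta), np.sin(theta)
    # Forward: p_out = scale * R @ (p_in - center) + center + shift
    # Inverse: p_in = R^T @ (p_out - center - shift) / scale + center
    center = np.array([(height - 1) / 2.0, (width - 1) / 2.0])
    rot = np.array([[c, -s], [s, c]])
    inv = rot.T / scale
    offset = center - inv @ (center + np.asarray(shift, dtype=np.float64))
    return inv, offset


def affine_transform(pair: ImageMaskPair, rotation: float = 0.0, scale: float = 1.0,
                     shift: tuple[float, float] = (0.0, 0.0)) -> ImageMaskPair:
    """Apply one geometric map to both grids.

    ``shift`` is (row, col) pixels; positive values move content down/right.
    The image is resampled bilinearly, the mask nearest-neighbor; pixels
    mapped from outside the frame become 0.
    """
    if scale <= 0:
        raise ValueError(f"scale must be > 0, got {scale}")
    if rotation == 0.0 and scale == 1.0 and tuple(shift) == (0.0, 0.0):
        return pair
    h, w = pair.mask.shape
    inv, offset = _affine_matrix(h, w, rotation, scale, shift)
    image = np.stack([
        ndimage.affine_transform(pair.image[..., ch].astype(np.float64), inv,
                                 offset=offset, order=1, mode="constant", cval=0.0)
        for ch in range(3)
    ], axis=-1)
    mask = ndimage.affine_transform(pair.mask, inv, offset=offset, order=0,
                                    mode="constant", cval=0)
    return ImageMaskPair(image=np.clip(np.rint(image), 0, 255).astype(np.uint8),
                         mask=mask.astype(np.uint8))


def add_gaussian_noise(image: np.ndarray, sigma: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Add i.i.d. per-pixel normal noise, clipping to [0, 255]."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return image.copy()
    noisy = image.astype(np.float64) + rng.normal(0.0, sigma, size=image.shape)
    return np.clip(np.rint(noisy), 0, 255).astype(np.uint8)


def random_brightness_contrast(image: np.ndarray, brightness_delta: float = 0.0,
                               contrast_factor: float = 1.0) -> np.ndarray:
    """out = (in - 128) * contrast_factor + 128 + 255 * brightness_delta."""
    out = (image.astype(np.float64) - 128.0) * contrast_factor + 128.0
    out += 255.0 * brightness_delta
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def hsv_shift(image: np.ndarray, dh: float = 0.0, ds: float = 0.0,
              dv: float = 0.0) -> np.ndarray:
    """Shift hue by ``dh`` degrees and saturation/value by 8-bit offsets."""
    hsv = skcolor.rgb2hsv(image.astype(np.float64) / 255.0)
    hsv[..., 0] = (hsv[..., 0] + dh / 360.0) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] + ds / 255.0, 0.0, 1.0)
    hsv[..., 2] = np.clip(hsv[..., 2] + dv / 255.0, 0.0, 1.0)
    rgb = skcolor.hsv2rgb(hsv)
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


def resize_pair(pair: ImageMaskPair, size: int) -> ImageMaskPair:
    """Resize to size x size: image bilinearly, mask nearest-neighbor."""
    if size % 16:
        raise ValueError(f"size must be divisible by 16, got {size}")
    if pair.mask.shape == (size, size):
        return pair
    image = sk_resize(pair.image, (size, size), order=1, preserve_range=True,
                      anti_aliasing=False)
    mask = sk_resize(pair.mask, (size, size), order=0, preserve_range=True,
                     anti_aliasing=False)
    return ImageMaskPair(image=np.clip(np.rint(image), 0, 255).astype(np.uint8),
                         mask=mask.astype(np.uint8))


def _augment_one(pair: ImageMaskPair, policy: AugmentationPolicy,
                 rng: np.random.Generator) -> ImageMaskPair:
    """One randomly parameterized copy: geometric, then photometric, noise last."""
    out = pair
    if rng.random() < policy.p_affine:
        rotation = rng.uniform(*policy.rotation_range)
        scale = rng.uniform(*policy.scale_range)
        lim = policy.shift_fraction * policy.size
        shift = (rng.uniform(-lim, lim), rng.uniform(-lim, lim))
        out = affine_transform(out, rotation=rotation, scale=scale, shift=shift)
    if rng.random() < policy.p_flip:
        out = horizontal_flip(out)
    image = out.image
    if rng.random() < policy.p_brightness_contrast:
        image = random_brightness_contrast(
            image,
            brightness_delta=rng.uniform(-policy.brightness_limit, policy.brightness_limit),
            contrast_factor=1.0 + rng.uniform(-policy.contrast_limit, policy.contrast_limit),
        )
    if rng.random() < policy.p_hsv:
        image = hsv_shift(
            image,
            dh=rng.uniform(-policy.hue_shift_limit, policy.hue_shift_limit),
            ds=rng.uniform(-policy.sat_shift_limit, policy.sat_shift_limit),
            dv=rng.uniform(-policy.val_shift_limit, policy.val_shift_limit),
        )
    if rng.random() < policy.p_noise:
        image = add_gaussian_noise(image, rng.uniform(*policy.noise_sigma_range), rng)
    return ImageMaskPair(image=image, mask=out.mask)


def augment_to_count(pairs: list[ImageMaskPair],
                     policy: AugmentationPolicy) -> list[ImageMaskPair]:
    """Expand ``pairs`` to exactly ``policy.target_count`` pairs.

    The resized originals come first; augmented copies are generated
    round-robin over the originals.  Deterministic under ``policy.seed``.
    """
    if not pairs:
        raise ValueError("source pair list is empty")
    if policy.target_count < len(pairs):
        raise ValueError(
            f"target_count {policy.target_count} < number of source pairs {len(pairs)}"
        )
    originals = [resize_pair(p, policy.size) for p in pairs]
    out = list(originals)
    rng = np.random.default_rng(policy.seed)
    i = 0
    while len(out) < policy.target_count:
        out.append(_augment_one(originals[i % len(originals)], policy, rng))
        i += 1
    return out
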