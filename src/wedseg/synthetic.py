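"""Synthetic H&E-like nuclei images with exact ground-truth masks.

Hematoxylin-stained nuclei appear as dark blue/purple ellipses over a pink
eosin background.  The generator rasterizes a configurable number of
(possibly touching) ellipses, records their union as the pixel-accurate
binary mask, and adds Gaussian sensor noise.  Every downstream stage —
augmentation, watershed mask construction, network training — is exercised
against these fixtures, so generation is fully deterministic under a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["SyntheticConfig", "ImageMaskPair", "generate_pair", "generate_dataset", "save_dataset"]


@dataclass(frozen=True)
class ImageMaskPair:
    """An RGB image grid with its aligned binary ground-truth mask."""

    image: np.ndarray  # H x W x 3, uint8
    mask: np.ndarray  # H x W, {0, 1}, uint8

    def __post_init__(self) -> None:
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError(f"image must be HxWx3, got {self.image.shape}")
        if self.mask.shape != self.image.shape[:2]:
            raise ValueError(
                f"mask shape {self.mask.shape} != image plane {self.image.shape[:2]}"
            )
        bad = set(np.unique(self.mask)) - {0, 1}
        if bad:
            raise ValueError(f"mask values must be in {{0,1}}, found {sorted(bad)}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic nuclei scene.

    Sizes must be divisible by 16 so a 4-stage encoder (four 2x2 poolings)
    accepts the images without cropping.
    """

    height: int = 128
    width: int = 128
    n_nuclei: int = 8
    radius_range: tuple[int, int] = (6, 14)
    eccentricity_range: tuple[float, float] = (0.0, 0.6)
    overlap_fraction: float = 0.15
    nucleus_color_mean: tuple[int, int, int] = (90, 50, 130)  # dark purple
    background_color_mean: tuple[int, int, int] = (235, 190, 215)  # pink
    noise_sigma: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height % 16 or self.width % 16:
            raise ValueError(
                f"height/width must be divisible by 16, got {self.height}x{self.width}"
            )
        rmin, rmax = self.radius_range
        if rmin < 2 or rmax < rmin:
            raise ValueError(f"degenerate radius_range {self.radius_range}")
        if rmax >= min(self.height, self.width) / 2:
            raise ValueError("radius_range.max must be < min(height,width)/2")
        emin, emax = self.eccentricity_range
        if not (0.0 <= emin <= emax < 1.0):
            raise ValueError(f"eccentricity_range must lie in [0,1), got {self.eccentricity_range}")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in [0,1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")


def _ellipse_interior(height: int, width: int, cy: float, cx: float,
                      a: float, b: float, theta: float) -> np.ndarray:
    """Boolean grid of pixels whose *centers* satisfy the ellipse inequality.

    Deciding membership on pixel centers fixes boundary pixels
    deterministically.
    """
    yy, xx = np.mgrid[0:height, 0:width]
    dy = yy - cy
    dx = xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _sample_center(rng: np.random.Generator, config: SyntheticConfig,
                   placed: list[tuple[float, float, float]], radius: float) -> tuple[float, float]:
    """Sample a nucleus center.

    With probability ``overlap_fraction`` (when another nucleus exists) the
    center lands within 1.5 radii of an existing nucleus, producing the
    touching/intersecting cases that make watershed separation necessary.
    Otherwise centers are rejection-sampled to keep nuclei disjoint.
    """
    h, w = config.height, config.width
    margin = radius + 1
    if placed and rng.random() < config.overlap_fraction:
        cy0, cx0, r0 = placed[rng.integers(len(placed))]
        for _ in range(64):
            ang = rng.uniform(0, 2 * np.pi)
            d = rng.uniform(0.5, 1.5) * r0
            cy, cx = cy0 + d * np.sin(ang), cx0 + d * np.cos(ang)
            if margin <= cy < h - margin and margin <= cx < w - margin:
                return cy, cx
    for _ in range(256):
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        if all((cy - py) ** 2 + (cx - px) ** 2 > (radius + pr + 1) ** 2
               for py, px, pr in placed):
            return cy, cx
    # Crowded scene: accept the last candidate rather than failing.
    return cy, cx


def generate_pair(config: SyntheticConfig) -> ImageMaskPair:
    """Render one H&E-like scene and its exact binary nucleus mask.

    The mask is the union of the rasterized ellipse interiors; the image
    paints each nucleus with a per-nucleus color jitter (uniform +-10 per
    channel) over the background mean, then adds i.i.d. Gaussian noise with
    ``noise_sigma`` and clips to [0, 255].  Identical config (including seed)
    yields bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width
    image = np.empty((h, w, 3), dtype=np.float64)
    image[:] = np.asarray(config.background_color_mean, dtype=np.float64)
    mask = np.zeros((h, w), dtype=np.uint8)

    placed: list[tuple[float, float, float]] = []
    for _ in range(config.n_nuclei):
        rmin, rmax = config.radius_range
        radius = rng.uniform(rmin, rmax) if rmax > rmin else float(rmin)
        ecc = rng.uniform(*config.eccentricity_range)
        # a is the semi-major axis; eccentricity e gives b = a*sqrt(1-e^2).
        a = radius
        b = radius * np.sqrt(1.0 - ecc**2)
        theta = rng.uniform(0, np.pi)
        cy, cx = _sample_center(rng, config, placed, radius)
        interior = _ellipse_interior(h, w, cy, cx, a, b, theta)
        jitter = rng.uniform(-10, 10, size=3)
        image[interior] = np.asarray(config.nucleus_color_mean, dtype=np.float64) + jitter
        mask[interior] = 1
        placed.append((cy, cx, radius))

    if config.noise_sigma > 0:
        image += rng.normal(0.0, config.noise_sigma, size=image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    return ImageMaskPair(image=image, mask=mask)


def generate_dataset(config: SyntheticConfig, n_pairs: int, seed: int) -> list[ImageMaskPair]:
    """Generate ``n_pairs`` scenes with per-pair seeds ``seed + index``."""
    if n_pairs < 1:
        raise ValueError(f"n_pairs must be >= 1, got {n_pairs}")
    return [
        generate_pair(dataclasses.replace(config, seed=seed + i))
        for i in range(n_pairs)
    ]


def save_dataset(pairs: list[ImageMaskPair], root: str | Path) -> None:
    """Write pairs as ``images/NNNN.png`` (RGB) and ``masks/NNNN.png`` (0/255)."""
    from .io import write_image, write_mask

    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)
    for i, pair in enumerate(pairs):
        stem = f"{i:04d}.png"
        write_image(root / "images" / stem, pair.image)
        write_mask(root / "masks" / stem, pair.mask * 255)
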