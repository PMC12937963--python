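"""PNG dataset I/O and the on-disk layout shared by every pipeline stage.

Datasets live as flat directories of PNG files paired by stem name:
``images/`` (8-bit RGB), ``masks/`` (binary ground truth, stored 0/255),
``watershed_masks/`` (paletted label images over {0,1,2}).  Stems sorted
lexicographically define dataset order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .synthetic import ImageMaskPair

logger = logging.getLogger("wedseg")

# Palette for 3-class label PNGs: background black, nucleus white, edge red.
_LABEL_PALETTE = [0, 0, 0, 255, 255, 255, 255, 0, 0] + [0] * (256 * 3 - 9)
# Preview colors loosely mimicking a color-coded watershed overlay.
PREVIEW_COLORS = np.array([[30, 30, 30], [120, 60, 160], [255, 230, 0]], dtype=np.uint8)


@dataclass
class DatasetLayout:
    """Directory layout pairing images with masks by identical stem names."""

    root: Path
    images_dir: str = "images"
    masks_dir: str = "masks"
    watershed_masks_dir: str = "watershed_masks"

    def __post_init__(self) -> None:
        self.root = Path(self.root)

    @property
    def images(self) -> Path:
        return self.root / self.images_dir

    @property
    def masks(self) -> Path:
        return self.root / self.masks_dir

    @property
    def watershed_masks(self) -> Path:
        return self.root / self.watershed_masks_dir


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG as an H x W x 3 uint8 grid; RGBA alpha is dropped with a warning."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with Image.open(path) as im:
        if im.mode == "RGBA":
            warnings.warn(f"{path.name}: dropping alpha channel", stacklevel=2)
            im = im.convert("RGB")
        elif im.mode != "RGB":
            im = im.convert("RGB")
        arr = np.asarray(im, dtype=np.uint8)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{path}: expected 3 channels, got shape {arr.shape}")
    return arr


def read_mask(path: str | Path) -> np.ndarray:
    """Read a label mask PNG.

    Grayscale 0/255 masks are normalized to {0,1}; paletted/grayscale images
    whose values already lie in {0,1,2} are returned unchanged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with Image.open(path) as im:
        if im.mode == "P":
            arr = np.asarray(im, dtype=np.uint8)
        else:
            arr = np.asarray(im.convert("L"), dtype=np.uint8)
    values = set(np.unique(arr))
    if values <= {0, 1, 2}:
        return arr
    if values <= {0, 255}:
        return (arr > 127).astype(np.uint8)
    # Anti-aliased or noisy binary scan: threshold at midpoint.
    return (arr > 127).astype(np.uint8)


def write_image(path: str | Path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a label grid losslessly.

    Grids over {0,1,2} are written as paletted PNGs; 0/255 binary masks as
    grayscale.
    """
    arr = np.asarray(mask, dtype=np.uint8)
    if set(np.unique(arr)) <= {0, 1, 2}:
        im = Image.fromarray(arr, mode="P")
        im.putpalette(_LABEL_PALETTE)
        im.save(path)
    else:
        Image.fromarray(arr, mode="L").save(path)


def write_preview(path: str | Path, classes: np.ndarray) -> None:
    """Write a color-coded RGB rendering of a 3-class mask for inspection."""
    write_image(path, PREVIEW_COLORS[np.asarray(classes, dtype=np.uint8)])


def load_paired_dataset(layout: DatasetLayout) -> list[ImageMaskPair]:
    """Load image/mask pairs in stem order, warning on orphans.

    Raises if no stem appears in both directories.
    """
    if not layout.images.is_dir() or not layout.masks.is_dir():
        raise FileNotFoundError(f"dataset dirs missing under {layout.root}")
    image_stems = {p.stem: p for p in layout.images.glob("*.png")}
    mask_stems = {p.stem: p for p in layout.masks.glob("*.png")}
    common = sorted(image_stems.keys() & mask_stems.keys())
    for orphan in sorted(set(image_stems) ^ set(mask_stems)):
        warnings.warn(f"unpaired stem {orphan!r} skipped", stacklevel=2)
    if not common:
        raise ValueError(f"no matched image/mask pairs under {layout.root}")
    pairs = [
        ImageMaskPair(image=read_image(image_stems[s]), mask=read_mask(mask_stems[s]))
        for s in common
    ]
    logger.info("loaded %d pairs from %s", len(pairs), layout.root)
    return pairs


@dataclass
class LabeledDataset:
    """Images with 3-class watershed targets, loaded by stem pairing."""

    images: list[np.ndarray] = field(default_factory=list)
    targets: list[np.ndarray] = field(default_factory=list)


def load_labeled_dataset(images_dir: str | Path, masks_dir: str | Path) -> LabeledDataset:
    images_dir, masks_dir = Path(images_dir), Path(masks_dir)
    image_stems = {p.stem: p for p in images_dir.glob("*.png")}
    mask_stems = {p.stem: p for p in masks_dir.glob("*.png")}
    common = sorted(image_stems.keys() & mask_stems.keys())
    if not common:
        raise ValueError(f"no matched pairs between {images_dir} and {masks_dir}")
    ds = LabeledDataset()
    for s in common:
        ds.images.append(read_image(image_stems[s]))
        ds.targets.append(read_mask(mask_stems[s]))
    return ds
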