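"""Images, per-lesion-class masks, and their on-disk layout.

Four lesion classes are segmented in diabetic-retinopathy fundus
photographs: microaneurysms (``MA``), hemorrhages (``HE``), hard exudates
and soft exudates (cotton-wool spots).  Each image is paired with one
binary mask per class, stored as 8-bit PNGs named
``<source_id>_<class>.png``; a missing file means "no lesions of that
class".  Any nonzero mask value counts as lesion, since annotation tools
variously write 1 or 255.

Coordinates are 0-based, row-major ``(row, col)`` throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.segmentation import find_boundaries

__all__ = [
    "CLASSES",
    "CLASS_COLORS",
    "FundusImage",
    "LesionMaskSet",
    "read_image",
    "write_image",
    "read_mask_set",
    "write_mask_set",
    "write_overlay",
]

#: Lesion classes, in canonical order.
CLASSES = ("MA", "HE", "hard_exudate", "soft_exudate")

#: Display colors: MA red, HE green, hard exudate blue, soft exudate yellow.
CLASS_COLORS = {
    "MA": (255, 0, 0),
    "HE": (0, 255, 0),
    "hard_exudate": (0, 0, 255),
    "soft_exudate": (255, 255, 0),
}


@dataclass
class FundusImage:
    """An RGB fundus photograph with provenance.

    Attributes
    ----------
    pixels
        ``(H, W, 3)`` uint8 array, intensities in [0, 255].
    source_id
        Identifier tying the image to its mask files.
    preprocess_record
        Geometry of any size normalization applied (see
        :mod:`funduseg.preprocess`), or ``None`` for raw images.
    """

    pixels: np.ndarray
    source_id: str = ""
    preprocess_record: object | None = None

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"expected (H, W, 3) pixels, got shape {px.shape}")
        if not np.isfinite(px).all():
            raise ValueError("image contains non-finite values")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        self.pixels = px.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class LesionMaskSet:
    """Four pixel-aligned binary masks, one per lesion class.

    Absent classes are materialised as all-zero masks so downstream code
    never special-cases them.
    """

    masks: dict[str, np.ndarray] = field(default_factory=dict)
    source_id: str = ""

    def __post_init__(self):
        clean: dict[str, np.ndarray] = {}
        shape = None
        for cls in self.masks:
            if cls not in CLASSES:
                raise ValueError(f"unknown lesion class {cls!r}")
        for cls, m in self.masks.items():
            m = (np.asarray(m) > 0).astype(np.uint8)
            if m.ndim != 2:
                raise ValueError(f"mask for {cls} must be 2-D, got shape {m.shape}")
            if shape is None:
                shape = m.shape
            elif m.shape != shape:
                raise ValueError(
                    f"mask for {cls} has shape {m.shape}, expected {shape}"
                )
            clean[cls] = m
        self.masks = clean

    @property
    def shape(self) -> tuple[int, int] | None:
        for m in self.masks.values():
            return m.shape
        return None

    def mask(self, cls: str, shape: tuple[int, int] | None = None) -> np.ndarray:
        """Mask for ``cls``; an absent class yields zeros of ``shape``."""
        if cls in self.masks:
            return self.masks[cls]
        shape = shape or self.shape
        if shape is None:
            raise ValueError("mask set is empty and no shape was given")
        return np.zeros(shape, dtype=np.uint8)

    def as_array(self, shape: tuple[int, int] | None = None) -> np.ndarray:
        """Stack all four classes into a ``(4, H, W)`` binary array."""
        shape = shape or self.shape
        return np.stack([self.mask(c, shape) for c in CLASSES])

    def validate_against(self, image: FundusImage):
        s = self.shape
        if s is not None and s != image.shape:
            raise ValueError(
                f"mask shape {s} does not match image shape {image.shape}"
            )


def read_image(path) -> FundusImage:
    """Read a PNG/JPEG/TIFF raster; grayscale is replicated to 3 channels."""
    path = Path(path)
    try:
        px = iio.imread(path)
    except Exception as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if px.ndim == 2:
        px = np.stack([px] * 3, axis=-1)
    elif px.ndim == 3 and px.shape[2] == 4:
        px = px[:, :, :3]
    return FundusImage(pixels=px, source_id=path.stem)


def write_image(image: FundusImage, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, image.pixels)


def read_mask_set(directory, source_id: str,
                  image_shape: tuple[int, int] | None = None) -> LesionMaskSet:
    """Load per-class masks ``<source_id>_<class>.png`` from ``directory``.

    Missing class files become all-zero masks (shape taken from
    ``image_shape`` or from the first present mask); nonzero pixels are
    binarized to 1.
    """
    directory = Path(directory)
    masks: dict[str, np.ndarray] = {}
    for cls in CLASSES:
        p = directory / f"{source_id}_{cls}.png"
        if p.exists():
            try:
                m = iio.imread(p)
            except Exception as exc:
                raise IOError(f"cannot read mask {p}: {exc}") from exc
            if m.ndim == 3:
                m = m.max(axis=2)
            if image_shape is not None and m.shape != tuple(image_shape):
                raise ValueError(
                    f"mask {p.name} has shape {m.shape}, expected {tuple(image_shape)}"
                )
            masks[cls] = m
    shape = image_shape
    if shape is None:
        for m in masks.values():
            shape = m.shape
            break
    if shape is None:
        raise ValueError(
            f"no mask files for {source_id!r} in {directory} and no image_shape given"
        )
    for cls in CLASSES:
        if cls not in masks:
            masks[cls] = np.zeros(shape, dtype=np.uint8)
    return LesionMaskSet(masks=masks, source_id=source_id)


def write_mask_set(masks: LesionMaskSet, directory):
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    shape = masks.shape
    for cls in CLASSES:
        m = masks.mask(cls, shape)
        iio.imwrite(directory / f"{masks.source_id}_{cls}.png", (m * 255).astype(np.uint8))


def write_overlay(image: FundusImage, masks: LesionMaskSet, path) -> np.ndarray:
    """Write the image with class-colored lesion contours; returns the raster."""
    masks.validate_against(image)
    out = image.pixels.copy()
    for cls in CLASSES:
        m = masks.mask(cls, image.shape)
        if not m.any():
            continue
        edge = find_boundaries(m.astype(bool), mode="inner")
        out[edge] = CLASS_COLORS[cls]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, out)
    return out
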