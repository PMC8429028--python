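"""Size normalization of fundus photographs.

Fundus cameras produce a circular field of view on a black frame whose
margins vary by device.  Normalization makes every image square and of a
fixed size without distorting retinal anatomy:

1. crop the tightest box containing non-black content;
2. pad the short side with black to a square (split evenly, odd remainder
   to bottom/right);
3. resize to ``target_size`` x ``target_size`` (default 1024);

and, for network input, a further resize to ``train_size`` (default 512).
The identical geometric transform is applied to masks with
nearest-neighbor resampling, then re-binarized, so labels never bleed.
Every step is recorded in a :class:`PreprocessRecord` so predictions can
be mapped back to original coordinates.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from skimage.transform import resize

from .io_masks import CLASSES, FundusImage, LesionMaskSet

__all__ = [
    "PreprocessRecord",
    "find_content_box",
    "normalize",
    "to_train_resolution",
    "invert_record",
    "DEFAULT_BORDER_THRESHOLD",
]

#: Intensity above which a pixel counts as content rather than black border.
DEFAULT_BORDER_THRESHOLD = 10


@dataclass
class PreprocessRecord:
    """Geometry of one normalization, sufficient to invert it.

    ``crop_box`` is half-open ``(row_min, row_max, col_min, col_max)`` in the
    original raster; ``pad`` is ``(top, bottom, left, right)`` black padding
    applied after the crop; ``scale_factor`` maps the padded square to
    ``target_size``.
    """

    crop_box: tuple[int, int, int, int]
    pad: tuple[int, int, int, int]
    scale_factor: float
    target_size: int = 1024
    train_size: int = 512
    original_size: tuple[int, int] = (0, 0)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "PreprocessRecord":
        d = json.loads(s)
        d["crop_box"] = tuple(d["crop_box"])
        d["pad"] = tuple(d["pad"])
        d["original_size"] = tuple(d["original_size"])
        return cls(**d)


def find_content_box(image: FundusImage,
                     threshold: int = DEFAULT_BORDER_THRESHOLD) -> tuple[int, int, int, int]:
    """Tightest half-open box of pixels whose max channel exceeds ``threshold``.

    An all-black image (nothing above threshold) yields the full frame.
    """
    bright = image.pixels.max(axis=2) > threshold
    rows = np.flatnonzero(bright.any(axis=1))
    cols = np.flatnonzero(bright.any(axis=0))
    H, W = image.shape
    if rows.size == 0:
        return (0, H, 0, W)
    return (int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1)


def _resize_image(px: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    out = resize(px.astype(np.float64), size, order=1, mode="edge",
                 anti_aliasing=px.shape[0] > size[0], preserve_range=True)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _resize_mask(m: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    out = resize(m.astype(np.float64), size, order=0, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    return (out > 0.5).astype(np.uint8)


def normalize(image: FundusImage, masks: LesionMaskSet | None = None,
              target_size: int = 1024,
              threshold: int = DEFAULT_BORDER_THRESHOLD,
              ) -> tuple[FundusImage, LesionMaskSet, PreprocessRecord]:
    """Crop black borders, pad to square, resize to ``target_size``."""
    if masks is None:
        masks = LesionMaskSet(source_id=image.source_id)
    masks.validate_against(image)
    r0, r1, c0, c1 = find_content_box(image, threshold)
    crop = image.pixels[r0:r1, c0:c1]
    h, w = crop.shape[:2]
    side = max(h, w)
    pt = (side - h) // 2
    pb = side - h - pt
    pl = (side - w) // 2
    pr = side - w - pl
    padded = np.pad(crop, ((pt, pb), (pl, pr), (0, 0)))
    record = PreprocessRecord(
        crop_box=(r0, r1, c0, c1),
        pad=(pt, pb, pl, pr),
        scale_factor=target_size / side,
        target_size=target_size,
        original_size=image.shape,
    )
    out_px = _resize_image(padded, (target_size, target_size))
    out_img = FundusImage(out_px, source_id=image.source_id, preprocess_record=record)
    out_masks = {}
    shape = image.shape
    for cls in CLASSES:
        m = masks.mask(cls, shape)[r0:r1, c0:c1]
        m = np.pad(m, ((pt, pb), (pl, pr)))
        out_masks[cls] = _resize_mask(m, (target_size, target_size))
    return out_img, LesionMaskSet(out_masks, source_id=masks.source_id), record


def to_train_resolution(image: FundusImage, masks: LesionMaskSet,
                        train_size: int = 512) -> tuple[FundusImage, LesionMaskSet]:
    """Resize a normalized pair down to the network's input resolution."""
    if image.shape == (train_size, train_size):
        return image, masks
    record = image.preprocess_record
    if isinstance(record, PreprocessRecord):
        record.train_size = train_size
    px = _resize_image(image.pixels, (train_size, train_size))
    out_img = FundusImage(px, source_id=image.source_id, preprocess_record=record)
    shape = image.shape
    out_masks = {cls: _resize_mask(masks.mask(cls, shape), (train_size, train_size))
                 for cls in CLASSES}
    return out_img, LesionMaskSet(out_masks, source_id=masks.source_id)


def invert_record(record: PreprocessRecord, mask_at_target: np.ndarray) -> np.ndarray:
    """Map a mask at ``target_size`` back to original image coordinates."""
    m = np.asarray(mask_at_target)
    if m.shape != (record.target_size, record.target_size):
        raise ValueError(
            f"mask shape {m.shape} does not match target size {record.target_size}"
        )
    pt, pb, pl, pr = record.pad
    r0, r1, c0, c1 = record.crop_box
    side = (r1 - r0) + pt + pb
    m = _resize_mask(m, (side, side))
    m = m[pt:side - pb, pl:side - pr]
    out = np.zeros(tuple(record.original_size), dtype=np.uint8)
    out[r0:r1, c0:c1] = m
    return out
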