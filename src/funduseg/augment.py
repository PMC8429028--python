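"""Joint geometric augmentation of images and their lesion masks.

Each emitted sample applies a random subset of the enabled transform
families — horizontal/vertical flips, per-axis scaling, translation,
rotation — never all of them at once by construction (a family is
included with probability 1/2, resampled if the subset comes out empty).
The same parameters are applied to the image (bilinear) and to every mask
(nearest-neighbor, re-binarized), so annotations stay pixel-aligned.
Out-of-bounds regions are filled with black, matching the fundus
background.  Transform magnitudes are configurable; the defaults are
conservative so lesions stay inside the field of view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import AffineTransform, warp

from .io_masks import CLASSES, FundusImage, LesionMaskSet

__all__ = ["AugmentConfig", "TransformParams", "apply_transform", "augment_dataset"]


@dataclass
class AugmentConfig:
    flip_h: bool = True
    flip_v: bool = True
    scale_range: tuple[float, float] = (0.9, 1.1)
    translate_range: tuple[float, float] = (-0.1, 0.1)
    rotate_range: tuple[float, float] = (-15.0, 15.0)
    expansion_factor: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.expansion_factor < 1:
            raise ValueError(
                f"expansion_factor must be >= 1, got {self.expansion_factor}"
            )


@dataclass
class TransformParams:
    """Fully specified parameters of one joint transform."""

    flip_h: bool = False
    flip_v: bool = False
    scale: tuple[float, float] = (1.0, 1.0)      # (row factor, col factor)
    translate: tuple[float, float] = (0.0, 0.0)  # fraction of (H, W)
    rotate_deg: float = 0.0


def _affine_about_center(shape: tuple[int, int], params: TransformParams) -> AffineTransform:
    H, W = shape
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    sy, sx = params.scale
    ty = params.translate[0] * H
    tx = params.translate[1] * W
    # skimage transforms act on (x, y) = (col, row)
    shift = AffineTransform(translation=(-cx, -cy))
    core = AffineTransform(scale=(sx, sy), rotation=np.deg2rad(params.rotate_deg))
    back = AffineTransform(translation=(cx + tx, cy + ty))
    return shift + core + back


def apply_transform(image: FundusImage, masks: LesionMaskSet,
                    params: TransformParams) -> tuple[FundusImage, LesionMaskSet]:
    """Apply one fully specified transform jointly to image and masks."""
    px = image.pixels
    shape = image.shape
    mask_arrays = {cls: masks.mask(cls, shape) for cls in CLASSES}
    if params.flip_h:
        px = px[:, ::-1]
        mask_arrays = {c: m[:, ::-1] for c, m in mask_arrays.items()}
    if params.flip_v:
        px = px[::-1]
        mask_arrays = {c: m[::-1] for c, m in mask_arrays.items()}
    tform = _affine_about_center(shape, params)
    identity = (params.scale == (1.0, 1.0) and params.translate == (0.0, 0.0)
                and params.rotate_deg == 0.0)
    if not identity:
        px = warp(px.astype(np.float64), tform.inverse, order=1, cval=0.0,
                  preserve_range=True)
        px = np.clip(np.rint(px), 0, 255).astype(np.uint8)
        mask_arrays = {
            c: (warp(m.astype(np.float64), tform.inverse, order=0, cval=0.0,
                     preserve_range=True) > 0.5).astype(np.uint8)
            for c, m in mask_arrays.items()
        }
    else:
        px = np.ascontiguousarray(px)
        mask_arrays = {c: np.ascontiguousarray(m) for c, m in mask_arrays.items()}
    out_img = FundusImage(px, source_id=image.source_id,
                          preprocess_record=image.preprocess_record)
    return out_img, LesionMaskSet(mask_arrays, source_id=masks.source_id)


def _sample_params(cfg: AugmentConfig, rng: np.random.Generator) -> TransformParams:
    families = ["flip_h"] * cfg.flip_h + ["flip_v"] * cfg.flip_v + [
        "scale", "translate", "rotate"]
    while True:
        chosen = [f for f in families if rng.random() < 0.5]
        if chosen:
            break
    p = TransformParams()
    if "flip_h" in chosen:
        p.flip_h = True
    if "flip_v" in chosen:
        p.flip_v = True
    if "scale" in chosen:
        p.scale = (rng.uniform(*cfg.scale_range), rng.uniform(*cfg.scale_range))
    if "translate" in chosen:
        p.translate = (rng.uniform(*cfg.translate_range),
                       rng.uniform(*cfg.translate_range))
    if "rotate" in chosen:
        p.rotate_deg = rng.uniform(*cfg.rotate_range)
    return p


def augment_dataset(pairs: list[tuple[FundusImage, LesionMaskSet]],
                    config: AugmentConfig,
                    ) -> list[tuple[FundusImage, LesionMaskSet]]:
    """Expand ``pairs`` to ``len(pairs) * expansion_factor`` samples.

    Originals are always included; the remainder are random transforms.
    Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    out: list[tuple[FundusImage, LesionMaskSet]] = []
    for image, masks in pairs:
        out.append((image, masks))
        for _ in range(config.expansion_factor - 1):
            out.append(apply_transform(image, masks, _sample_params(config, rng)))
    return out
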