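"""Synthetic fundus images with exact per-class lesion masks.

The generator emulates the geometry and first-order statistics of real
fundus photographs: a bright circular field of view on a black frame (so
border-cropping code is exercised), a reddish-orange retinal background
with low-frequency shading, dark curvilinear vessel-like strokes (a known
confounder for hemorrhage detection), and four lesion classes rendered
with their clinical morphology:

* microaneurysms — small circular dark-red dots;
* hemorrhages — larger irregular dark-red blobs;
* hard exudates — bright yellow sharp-edged blobs;
* soft exudates — pale blobs feathered with a Gaussian in the image only
  (the mask keeps the pre-blur support, mirroring how annotators outline
  cotton-wool spots).

Per-class area budgets default to the composition of a public
lesion-segmentation benchmark (MA 0.10%, HE 1.03%, hard exudate 0.90%,
soft exudate 0.38% of image area).  Lesions are rejection-sampled to
stay inside the field of view and, by default, not overlap across
classes, so component counts in the masks equal the number of lesions
placed.  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter
from scipy.ndimage import label as cc_label
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from .io_masks import CLASSES, FundusImage, LesionMaskSet, write_image, write_mask_set

__all__ = ["LesionSpec", "SyntheticConfig", "generate_image", "generate_dataset"]


@dataclass
class LesionSpec:
    """How one lesion class is generated.

    If ``area_fraction`` is set, per-lesion radii are derived from the
    class area budget divided over the drawn count; otherwise radii are
    sampled uniformly from ``radius_range`` (pixels).
    """

    count_range: tuple[int, int]
    radius_range: tuple[float, float]
    area_fraction: float | None
    roughness: float  # 0 = circle; fraction of radial jitter
    color: tuple[int, int, int]
    fuzzy: bool = False


def _default_lesions() -> dict[str, LesionSpec]:
    return {
        "MA": LesionSpec((3, 8), (2, 5), 0.0010, 0.0, (95, 15, 10)),
        "HE": LesionSpec((2, 5), (5, 20), 0.0103, 0.5, (115, 28, 18)),
        "hard_exudate": LesionSpec((2, 6), (4, 15), 0.0090, 0.4, (250, 238, 80)),
        "soft_exudate": LesionSpec((1, 3), (10, 25), 0.0038, 0.3, (238, 226, 180), fuzzy=True),
    }


@dataclass
class SyntheticConfig:
    image_size: tuple[int, int] = (256, 256)
    fov_radius_fraction: float = 0.48
    lesions: dict[str, LesionSpec] = field(default_factory=_default_lesions)
    n_vessels: int = 4
    allow_overlap: bool = False
    seed: int = 0

    def __post_init__(self):
        H, W = self.image_size
        fov_area = np.pi * (self.fov_radius_fraction * min(H, W)) ** 2
        total = sum(s.area_fraction or 0.0 for s in self.lesions.values()) * H * W
        if total > 0.25 * fov_area:
            raise ValueError(
                f"requested lesion area ({total:.0f} px) exceeds a quarter of the "
                f"field of view ({fov_area:.0f} px); placement is infeasible"
            )


def _blob_mask(shape, center, radius, roughness, rng) -> np.ndarray:
    """Binary support of one lesion: a disk or a radially jittered polygon."""
    m = np.zeros(shape, dtype=bool)
    if roughness <= 0 or radius < 2.5:
        rr, cc = draw_disk(center, max(radius, 1.0), shape=shape)
    else:
        k = 14
        ang = np.sort(rng.uniform(0, 2 * np.pi, k))
        rad = radius * (1 + roughness * rng.uniform(-1, 1, k))
        rows = center[0] + rad * np.sin(ang)
        cols = center[1] + rad * np.cos(ang)
        rr, cc = draw_polygon(rows, cols, shape=shape)
    m[rr, cc] = True
    # a very thin polygon can rasterize into islands; keep the largest so
    # one lesion is always one connected component
    labels, n = cc_label(m, structure=np.ones((3, 3)))
    if n > 1:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        m = labels == sizes.argmax()
    return m


def _draw_vessels(img: np.ndarray, center, fov_r, n: int, thickness: float,
                  rng) -> None:
    """Dark curvilinear strokes from near the disc center outward."""
    H, W = img.shape[:2]
    yy, xx = np.mgrid[0:H, 0:W]
    for _ in range(n):
        pos = np.array(center, dtype=float) + rng.uniform(-0.2, 0.2, 2) * fov_r
        heading = rng.uniform(0, 2 * np.pi)
        color = np.array([120, 30, 20], dtype=float) * rng.uniform(0.85, 1.05)
        for _ in range(int(fov_r * 1.5)):
            heading += rng.normal(0, 0.25)
            pos += np.array([np.sin(heading), np.cos(heading)]) * 1.5
            if np.hypot(pos[0] - center[0], pos[1] - center[1]) > fov_r * 0.95:
                break
            rr, cc = draw_disk(pos, max(thickness, 1.0), shape=(H, W))
            img[rr, cc] = color


def generate_image(config: SyntheticConfig,
                   ) -> tuple[FundusImage, LesionMaskSet, dict[str, int]]:
    """Render one synthetic fundus image with exact lesion masks."""
    rng = np.random.default_rng(config.seed)
    H, W = config.image_size
    center = ((H - 1) / 2.0, (W - 1) / 2.0)
    fov_r = config.fov_radius_fraction * min(H, W)
    yy, xx = np.mgrid[0:H, 0:W]
    fov = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= fov_r**2

    img = np.zeros((H, W, 3), dtype=float)
    shading = gaussian_filter(rng.normal(0, 1, (H, W)), sigma=max(H, W) / 8.0)
    shading = 18.0 * shading / max(np.abs(shading).max(), 1e-9)
    base = np.array([200.0, 92.0, 48.0])
    img[fov] = base + shading[fov, None]

    scale = min(H, W) / 1024.0
    _draw_vessels(img, center, fov_r, config.n_vessels,
                  thickness=max(1.0, 3.0 * scale), rng=rng)

    occupied = ~fov  # lesions must stay inside the field of view
    masks: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for cls in CLASSES:
        spec = config.lesions.get(cls)
        cls_mask = np.zeros((H, W), dtype=np.uint8)
        placed = 0
        if spec is not None:
            lo, hi = spec.count_range
            n = int(rng.integers(lo, hi + 1)) if hi > lo else lo
            if n > 0:
                if spec.area_fraction is not None:
                    budget = spec.area_fraction * H * W
                    weights = rng.uniform(0.6, 1.6, n)
                    areas = budget * weights / weights.sum()
                    radii = np.sqrt(areas / np.pi)
                else:
                    radii = rng.uniform(*spec.radius_range, n)
                radii = np.maximum(radii, 1.0)
                for r in radii:
                    for _ in range(300):  # rejection sampling
                        ang = rng.uniform(0, 2 * np.pi)
                        rho = np.sqrt(rng.uniform(0, 1)) * max(fov_r - r - 2, 1.0)
                        c = (center[0] + rho * np.sin(ang), center[1] + rho * np.cos(ang))
                        blob = _blob_mask((H, W), c, r, spec.roughness, rng)
                        if not blob.any():
                            continue
                        if not config.allow_overlap:
                            # dilate so separate lesions never touch, even
                            # diagonally: component counts stay exact
                            grown = binary_dilation(blob, np.ones((3, 3), bool))
                            if (grown & occupied).any():
                                continue
                        cls_mask |= blob.astype(np.uint8)
                        occupied |= blob
                        placed += 1
                        if spec.fuzzy:
                            lesion = np.zeros((H, W), dtype=float)
                            lesion[blob] = 1.0
                            soft = gaussian_filter(lesion, sigma=max(1.0, r / 4.0))
                            soft = np.clip(soft / max(soft.max(), 1e-9), 0, 1)
                            w = soft[..., None] * fov[..., None]
                            img = img * (1 - w) + np.array(spec.color, dtype=float) * w
                        else:
                            img[blob] = spec.color
                        break
        masks[cls] = cls_mask
        counts[cls] = placed

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    source_id = f"synth_{config.seed:08d}"
    return (FundusImage(img, source_id=source_id),
            LesionMaskSet(masks, source_id=source_id), counts)


def generate_dataset(config: SyntheticConfig, n_images: int, out_dir,
                     ) -> list[dict]:
    """Write ``n_images`` image/mask sets plus a manifest; returns the manifest."""
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    mask_dir = out_dir / "masks"
    img_dir.mkdir(parents=True, exist_ok=True)
    mask_dir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.default_rng(config.seed).integers(2**31, size=n_images)
    manifest = []
    for i, s in enumerate(seeds):
        cfg = replace(config, seed=int(s))
        image, masks, counts = generate_image(cfg)
        sid = f"img_{i:03d}"
        image.source_id = sid
        masks.source_id = sid
        write_image(image, img_dir / f"{sid}.png")
        write_mask_set(masks, mask_dir)
        H, W = image.shape
        manifest.append({
            "source_id": sid,
            "seed": int(s),
            "counts": counts,
            "area_fractions": {
                cls: float(masks.mask(cls, (H, W)).sum() / (H * W)) for cls in CLASSES
            },
        })
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
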