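"""Component-overlap evaluation of lesion segmentations.

Pixel-exact confusion counts penalise small lesions too harshly: a
detection that covers most of a microaneurysm but is shifted by a pixel
scores near zero.  The matching-degree metric instead works on connected
components.  With detected components D_1..D_N (union D) and ground-truth
components G_1..G_M (union G), and an overlap threshold sigma in [0, 1]:

* TP pixels: D∩G, plus every pixel of any D_i with |D_i∩G|/|D_i| > sigma,
  plus every pixel of any G_j with |G_j∩D|/|G_j| > sigma;
* FP pixels: components D_i that miss G entirely, and D_i\\G where the
  D_i ratio is <= sigma;
* FN pixels: components G_j untouched by D, and G_j\\D where the G_j
  ratio is <= sigma;
* TN: everything else.

The inequality is strict, so sigma = 0 reduces to touch-matching: any
detection touching the truth is credited entirely.  A pixel that
satisfies a TP rule is TP regardless of the other rules.  The default
sigma is 0.2.

Also provided: pixel-level ROC/AUC and precision-recall/AUPR curves, the
five ratio metrics (sensitivity, specificity, precision, accuracy, F1),
and connected-component lesion counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label
from sklearn.metrics import auc as _auc
from sklearn.metrics import precision_recall_curve as _pr_curve
from sklearn.metrics import roc_curve as _roc_curve

from .io_masks import CLASSES, LesionMaskSet

__all__ = [
    "ComponentSet",
    "MatchConfig",
    "ConfusionCounts",
    "MetricsReport",
    "extract_components",
    "classify_pixels",
    "compute_metrics",
    "roc_curve",
    "pr_curve",
    "count_lesions",
    "LABEL_TN",
    "LABEL_TP",
    "LABEL_FP",
    "LABEL_FN",
]

# per-pixel label raster codes
LABEL_TN, LABEL_TP, LABEL_FP, LABEL_FN = 0, 1, 2, 3


@dataclass
class MatchConfig:
    sigma: float = 0.2
    connectivity: int = 8

    def __post_init__(self):
        if not 0.0 <= self.sigma <= 1.0:
            raise ValueError(f"sigma must lie in [0, 1], got {self.sigma}")
        if self.connectivity not in (4, 8):
            raise ValueError(f"connectivity must be 4 or 8, got {self.connectivity}")


@dataclass
class ComponentSet:
    """Connected components of a binary mask.

    ``labels`` assigns 1..N to component pixels and 0 to background;
    ``components`` lists each component's pixel coordinates.
    """

    labels: np.ndarray
    n_components: int
    image_shape: tuple[int, int]

    @property
    def components(self) -> list[np.ndarray]:
        return [np.argwhere(self.labels == i) for i in range(1, self.n_components + 1)]

    @property
    def union(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0
    TN: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.FP + other.FP,
                               self.FN + other.FN, self.TN + other.TN)

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass
class MetricsReport:
    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    f1: float
    auc: float | None = None
    aupr: float | None = None
    undefined: list[str] = field(default_factory=list)


def extract_components(mask: np.ndarray, connectivity: int = 8) -> ComponentSet:
    """Maximal connected components under 4- or 8-connectivity."""
    m = (np.asarray(mask) > 0).astype(np.uint8)
    if m.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {m.shape}")
    conn = 1 if connectivity == 4 else 2
    labels, n = cc_label(m, connectivity=conn, return_num=True)
    return ComponentSet(labels=labels, n_components=n, image_shape=m.shape)


def classify_pixels(detected: ComponentSet, truth: ComponentSet,
                    config: MatchConfig | None = None,
                    ) -> tuple[ConfusionCounts, np.ndarray]:
    """Apply the sigma-overlap matching rules.

    Returns the pixel confusion counts and a label raster with codes
    TN=0, TP=1, FP=2, FN=3.
    """
    config = config or MatchConfig()
    if detected.image_shape != truth.image_shape:
        raise ValueError(
            f"shape mismatch: {detected.image_shape} vs {truth.image_shape}"
        )
    sigma = config.sigma
    D, G = detected.union, truth.union
    ld, lg = detected.labels, truth.labels
    tp = D & G
    if detected.n_components:
        sizes = np.bincount(ld.ravel(), minlength=detected.n_components + 1)
        overlap = np.bincount(ld[G].ravel(), minlength=detected.n_components + 1)
        promoted = (overlap / np.maximum(sizes, 1)) > sigma
        promoted[0] = False
        tp |= promoted[ld]
    if truth.n_components:
        sizes = np.bincount(lg.ravel(), minlength=truth.n_components + 1)
        overlap = np.bincount(lg[D].ravel(), minlength=truth.n_components + 1)
        promoted = (overlap / np.maximum(sizes, 1)) > sigma
        promoted[0] = False
        tp |= promoted[lg]
    # TP has priority; whatever remains of D is FP, of G is FN
    fp = D & ~tp
    fn = G & ~tp
    raster = np.full(detected.image_shape, LABEL_TN, dtype=np.uint8)
    raster[tp] = LABEL_TP
    raster[fp] = LABEL_FP
    raster[fn] = LABEL_FN
    H, W = detected.image_shape
    counts = ConfusionCounts(
        TP=int(tp.sum()), FP=int(fp.sum()), FN=int(fn.sum()),
        TN=int(H * W - tp.sum() - fp.sum() - fn.sum()),
    )
    return counts, raster


def _ratio(num: float, den: float, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Sensitivity, specificity, precision, accuracy and F1 from counts.

    A zero denominator yields 0 and the metric's name in ``undefined``.
    """
    undefined: list[str] = []
    tp, fp, fn, tn = counts.TP, counts.FP, counts.FN, counts.TN
    se = _ratio(tp, tp + fn, "sensitivity", undefined)
    sp = _ratio(tn, tn + fp, "specificity", undefined)
    pr = _ratio(tp, tp + fp, "precision", undefined)
    acc = _ratio(tp + tn, tp + tn + fp + fn, "accuracy", undefined)
    f1 = _ratio(2 * se * pr, se + pr, "f1", undefined)
    return MetricsReport(sensitivity=se, specificity=sp, precision=pr,
                         accuracy=acc, f1=f1, undefined=undefined)


def roc_curve(prob_maps: np.ndarray, truth_masks: np.ndarray,
              ) -> tuple[tuple[np.ndarray, np.ndarray, np.ndarray], float]:
    """Pixel-level ROC over a descending threshold sweep, AUC by trapezoid.

    Raises if the truth is constant (the curve is undefined).
    """
    y = (np.asarray(truth_masks).ravel() > 0).astype(int)
    s = np.asarray(prob_maps, dtype=np.float64).ravel()
    if y.shape != s.shape:
        raise ValueError("probability and truth sizes differ")
    if y.min() == y.max():
        raise ValueError("ROC curve undefined for constant truth")
    fpr, tpr, thr = _roc_curve(y, s)
    return (fpr, tpr, thr), float(_auc(fpr, tpr))


def pr_curve(prob_maps: np.ndarray, truth_masks: np.ndarray,
             ) -> tuple[tuple[np.ndarray, np.ndarray, np.ndarray], float]:
    """Pixel-level precision-recall curve and trapezoidal AUPR.

    At recall 0 the precision is taken as the curve's endpoint from
    scikit-learn's convention (precision 1 at the highest threshold).
    Requires at least one positive truth pixel.
    """
    y = (np.asarray(truth_masks).ravel() > 0).astype(int)
    s = np.asarray(prob_maps, dtype=np.float64).ravel()
    if y.shape != s.shape:
        raise ValueError("probability and truth sizes differ")
    if y.max() == 0:
        raise ValueError("PR curve undefined without positive truth pixels")
    precision, recall, thr = _pr_curve(y, s)
    # recall is decreasing; integrate over increasing recall
    aupr = float(_auc(recall[::-1], precision[::-1]))
    return (precision, recall, thr), aupr


def count_lesions(masks: LesionMaskSet, connectivity: int = 8) -> dict[str, int]:
    """Connected-component lesion count per class."""
    shape = masks.shape
    out = {}
    for cls in CLASSES:
        if shape is None:
            out[cls] = 0
        else:
            out[cls] = extract_components(masks.mask(cls, shape), connectivity).n_components
    return out
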