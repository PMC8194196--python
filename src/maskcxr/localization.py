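"""Weakly-supervised lesion localization via class activation maps.

A class activation map (CAM) is the channel-weighted sum of the final
convolutional feature map, using the linear head's weight row for the class
of interest.  Rectifying at zero and upsampling to image resolution gives a
heatmap; thresholding it at a fraction of its maximum and taking the largest
4-connected component yields a single predicted bounding box per image and
class, scored against ground-truth boxes by intersection-over-union.

Box convention throughout the package: 0-based pixel coordinates, x
rightward, y downward, half-open width/height (a box covers columns
``x .. x+w-1``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize

CAM_THRESHOLD_FRAC = 0.2  # relative-to-max binarisation level for box extraction


@dataclass(frozen=True)
class BBox:
    """Axis-aligned pixel box: top-left (x, y), half-open extent (w, h)."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self):
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"degenerate box {self}")

    @property
    def area(self) -> int:
        return self.w * self.h

    @property
    def x2(self) -> int:  # exclusive
        return self.x + self.w

    @property
    def y2(self) -> int:  # exclusive
        return self.y + self.h

    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)


class NoActivation:
    """Sentinel returned when a heatmap carries no positive activation."""

    def __repr__(self):
        return "NoActivation()"


NO_ACTIVATION = NoActivation()


def upsample_bilinear(plane: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Bilinear upsampling shared by CAM heatmaps and mask-support checks."""
    return resize(plane.astype(np.float64), out_hw, order=1, mode="edge",
                  anti_aliasing=False, preserve_range=True)


def compute_cam(features: np.ndarray, head_weights_row: np.ndarray,
                out_size: tuple[int, int] | None = None) -> np.ndarray:
    """CAM heatmap for one class.

    ``features`` is the final convolutional map ``[c_feat, h, w]`` (global or
    mask-weighted, per configuration); ``head_weights_row`` the class's weight
    vector of length ``c_feat``.  The raw map ``sum_j w_j f_j`` is rectified at
    zero and, if ``out_size`` is given, bilinearly upsampled to that size.
    """
    features = np.asarray(features, dtype=np.float64)
    w = np.asarray(head_weights_row, dtype=np.float64).ravel()
    if features.ndim != 3 or w.shape[0] != features.shape[0]:
        raise ValueError(f"weight row length {w.shape[0]} does not match {features.shape[0]} channels")
    raw = np.tensordot(w, features, axes=(0, 0))
    heat = np.maximum(raw, 0.0)
    if out_size is not None:
        heat = upsample_bilinear(heat, out_size)
    return heat


def cam_to_bbox(heat: np.ndarray, threshold_frac: float = CAM_THRESHOLD_FRAC):
    """Extract one box from a heatmap: binarise at ``threshold_frac * max``,
    keep the largest 4-connected component, return its tight bounding box.

    Returns :data:`NO_ACTIVATION` for an identically-zero (or negative-free,
    all-zero after rectification) heatmap.
    """
    if not (0.0 < threshold_frac < 1.0):
        raise ValueError("threshold_frac must lie in (0, 1)")
    heat = np.asarray(heat, dtype=np.float64)
    peak = heat.max()
    if peak <= 0.0:
        return NO_ACTIVATION
    fg = heat >= threshold_frac * peak
    labels, n = ndimage.label(fg)  # default structure = 4-connectivity
    if n == 0:
        return NO_ACTIVATION
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    comp = labels == (int(np.argmax(sizes)) + 1)
    ys, xs = np.nonzero(comp)
    return BBox(x=int(xs.min()), y=int(ys.min()),
                w=int(xs.max() - xs.min() + 1), h=int(ys.max() - ys.min() + 1))


def iou(a: BBox, b: BBox) -> float:
    """Intersection over union of two half-open pixel boxes; 0 when disjoint."""
    ix = max(0, min(a.x2, b.x2) - max(a.x, b.x))
    iy = max(0, min(a.y2, b.y2) - max(a.y, b.y))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


def central_box(image_size: int, area_frac: float = 0.25) -> BBox:
    """Fixed centred box covering ``area_frac`` of a square image (blind baseline)."""
    side = int(round(image_size * np.sqrt(area_frac)))
    off = (image_size - side) // 2
    return BBox(off, off, side, side)


def predicted_box_for_class(model, sample, class_index: int,
                            threshold_frac: float = CAM_THRESHOLD_FRAC,
                            features: np.ndarray | None = None):
    """CAM -> box for one phantom sample and class, using the model's own
    configuration (mask-weighted features when weighting is enabled).
    ``features`` allows reusing a precomputed feature map for the sample."""
    from .classifier import model_features_for_sample
    feats = model_features_for_sample(model, sample) if features is None else features
    h, w = sample.image.shape[-2:]
    heat = compute_cam(feats, model.head.weight.value[class_index], out_size=(h, w))
    return cam_to_bbox(heat, threshold_frac)


def evaluate_localization(model, samples, class_names: list[str],
                          threshold_frac: float = CAM_THRESHOLD_FRAC) -> pd.DataFrame:
    """Per-class mean IoU of CAM-predicted boxes against ground-truth boxes.

    Only classes with at least one ground-truth box are scored; when an image
    carries several boxes of the class, the best (max) IoU counts.  A
    no-activation prediction scores 0 for that image.
    """
    from .classifier import model_features_for_sample
    per_class: dict[int, list[float]] = {}
    for sample in samples:
        by_class: dict[int, list[BBox]] = {}
        for k, box in sample.boxes:
            by_class.setdefault(k, []).append(box)
        if not by_class:
            continue
        feats = model_features_for_sample(model, sample)
        for k, gt_boxes in by_class.items():
            pred = predicted_box_for_class(model, sample, k, threshold_frac, features=feats)
            score = 0.0 if isinstance(pred, NoActivation) else max(iou(pred, g) for g in gt_boxes)
            per_class.setdefault(k, []).append(score)
    rows = []
    for k, name in enumerate(class_names):
        if k not in per_class:
            warnings.warn(f"class '{name}' has no ground-truth boxes; omitted from IoU table")
            continue
        rows.append({"class": name, "mean_iou": float(np.mean(per_class[k])),
                     "n_images": len(per_class[k])})
    return pd.DataFrame(rows, columns=["class", "mean_iou", "n_images"])
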