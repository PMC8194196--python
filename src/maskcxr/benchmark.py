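"""Published ChestX-ray14 benchmark-split statistics and reference results.

These tables are the printed inputs that the package's aggregation arithmetic
is checked against: per-class image counts of the benchmark train/test/box
splits, the reported per-class test AUROCs of the segmentation-weighted
attention model (with and without the feature-weighting stage), and the
reported per-class mean IoU of CAM localization on the box set for the
feature extractor with and without the multi-scale attention module.
"""

from __future__ import annotations

from .classifier import CHESTXRAY14_CLASSES

#: per-class image counts of the benchmark split (train, test, box)
SPLIT_COUNTS = {
    "Atelectasis": (8280, 3279, 180),
    "Cardiomegaly": (1707, 1069, 146),
    "Effusion": (8659, 4658, 153),
    "Infiltration": (13782, 6112, 123),
    "Mass": (4034, 1748, 85),
    "Nodule": (4708, 1623, 79),
    "Pneumonia": (876, 555, 120),
    "Pneumothorax": (2637, 2665, 98),
    "Consolidation": (2852, 1815, 0),
    "Edema": (1378, 925, 0),
    "Emphysema": (1423, 1093, 0),
    "Fibrosis": (1251, 435, 0),
    "Pleural Thickening": (2242, 1143, 0),
    "Hernia": (141, 86, 0),
}

#: split totals as printed: images with >= 1 finding, "No Finding" images, total
SPLIT_TOTALS = {
    "finding": (36024, 15735, 984),
    "no_finding": (50500, 9861, 0),
    "total": (86524, 25596, 984),
}

#: reported per-class test AUROC of the full model (feature weighting on)
REPORTED_AUROC_WEIGHTED = {
    "Atelectasis": 0.8073, "Cardiomegaly": 0.9069, "Effusion": 0.8401,
    "Infiltration": 0.7901, "Mass": 0.8131, "Nodule": 0.8377,
    "Pneumonia": 0.7465, "Pneumothorax": 0.8728, "Consolidation": 0.7831,
    "Edema": 0.8575, "Emphysema": 0.8605, "Fibrosis": 0.8494,
    "Pleural Thickening": 0.8123, "Hernia": 0.8915,
}

#: reported per-class test AUROC of the ablation without feature weighting
REPORTED_AUROC_UNWEIGHTED = {
    "Atelectasis": 0.8151, "Cardiomegaly": 0.9100, "Effusion": 0.8779,
    "Infiltration": 0.6923, "Mass": 0.8290, "Nodule": 0.7553,
    "Pneumonia": 0.7401, "Pneumothorax": 0.8516, "Consolidation": 0.8038,
    "Edema": 0.8858, "Emphysema": 0.8849, "Fibrosis": 0.8077,
    "Pleural Thickening": 0.7573, "Hernia": 0.8995,
}

#: the 8 box-annotated classes, in table order
BOX_CLASSES = ("Atelectasis", "Cardiomegaly", "Effusion", "Infiltration",
               "Mass", "Nodule", "Pneumonia", "Pneumothorax")

#: reported per-class mean IoU of CAM boxes, feature extractor with the
#: multi-scale attention module
REPORTED_IOU_ATTENTION = {
    "Atelectasis": 0.1713, "Cardiomegaly": 0.5515, "Effusion": 0.3242,
    "Infiltration": 0.3819, "Mass": 0.1768, "Nodule": 0.0460,
    "Pneumonia": 0.3097, "Pneumothorax": 0.3345,
}

#: same, without the multi-scale attention module
REPORTED_IOU_NO_ATTENTION = {
    "Atelectasis": 0.1212, "Cardiomegaly": 0.4430, "Effusion": 0.3258,
    "Infiltration": 0.2783, "Mass": 0.1429, "Nodule": 0.0418,
    "Pneumonia": 0.2328, "Pneumothorax": 0.2640,
}

#: reported AUROC of the strongest fusion-based comparison method on
#: Infiltration (the class where feature weighting helps most)
INFILTRATION_BASELINE_AUROC = 0.7000


def box_counts() -> list[int]:
    return [SPLIT_COUNTS[c][2] for c in BOX_CLASSES]


def auroc_vector(table: dict) -> list[float]:
    """Per-class values in the canonical 14-class order."""
    return [table[c] for c in CHESTXRAY14_CLASSES]


def iou_vector(table: dict) -> list[float]:
    return [table[c] for c in BOX_CLASSES]
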