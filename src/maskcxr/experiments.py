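"""Desk-scale phantom studies.

These are the package's reference experiments, sized to run on a single CPU
in minutes: (1) segmentation quality of the tiny U-Net on phantoms, (2) the
feature-weighting ablation — does zeroing features outside the segmented
anatomy improve multi-label AUROC when distractor lesions lie outside it —
and (3) CAM localization against a blind central-box baseline.  Every study
is deterministic given its base seed; multi-seed variants report the
per-seed values and their median.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np

from .classifier import ClsTrainConfig, train_classifier, predict_proba
from .localization import central_box, evaluate_localization, iou, CAM_THRESHOLD_FRAC
from .metrics import macro_auroc
from .phantom import PhantomConfig, generate_phantom, split_phantom
from .segmentation import SegTrainConfig, train_segmenter, predict_masks, dice_coefficient


def heldout_mean_dice(segmenter, samples) -> float:
    """Mean over samples of the 3-structure mean dice vs. ground truth."""
    scores = []
    for s in samples:
        pred = predict_masks(s.image, segmenter).stack()
        scores.append(np.mean([dice_coefficient(g, p) for g, p in zip(s.masks.stack(), pred)]))
    return float(np.mean(scores))


def segmentation_study(base_seed: int = 0, n_seeds: int = 3, n_samples: int = 50,
                       image_size: int = 64, base_width: int = 8, depth: int = 3,
                       epochs: int = 16) -> dict:
    """Train the tiny U-Net on small phantom sets and measure held-out dice."""
    per_seed = []
    for i in range(n_seeds):
        seed = base_seed + 101 * i
        cfg = PhantomConfig(image_size=image_size, n_samples=n_samples, n_classes=4,
                            seed=seed)
        samples = generate_phantom(cfg)
        train, val, test = split_phantom(samples, 0.8, 0.1, seed=seed)
        seg, _ = train_segmenter(train, val, SegTrainConfig(
            epochs=epochs, base_width=base_width, depth=depth, seed=seed))
        per_seed.append(heldout_mean_dice(seg, test))
    return {"per_seed": per_seed, "median": float(np.median(per_seed)),
            "n_samples": n_samples, "image_size": image_size}


def weighting_ablation_study(base_seed: int = 0, n_seeds: int = 3,
                             n_samples: int = 1400, image_size: int = 64,
                             distractor_rate: float = 0.8, label_prior: float = 0.5,
                             n_classes: int = 4, epochs: int = 15, lr: float = 3e-3,
                             batch_size: int = 32, seg_epochs: int = 8,
                             keep_models: bool = False) -> dict:
    """Feature-weighted vs. unweighted classifier on distractor-rich phantoms.

    Both arms share the phantom data, the frozen segmenter, the attention
    module and all hyperparameters; only the mask-weighting stage differs.
    Reports held-out macro AUROC per arm and the per-seed gap.
    """
    per_seed = []
    extras = {}
    for i in range(n_seeds):
        seed = base_seed + 101 * i
        cfg = PhantomConfig(image_size=image_size, n_samples=n_samples,
                            n_classes=n_classes, distractor_rate=distractor_rate,
                            label_prior=label_prior, seed=seed)
        samples = generate_phantom(cfg)
        train, val, test = split_phantom(samples, 0.85, 0.15, seed=seed)
        seg, _ = train_segmenter(train[:60], val[:12], SegTrainConfig(
            epochs=seg_epochs, base_width=8, depth=3, seed=seed))
        y_true = np.stack([s.labels for s in test])
        aucs = {}
        models = {}
        mask_cache: dict = {}  # segmenter masks shared across the two arms
        for arm, weighting in (("weighted", True), ("unweighted", False)):
            model, _ = train_classifier(train, val, seg, ClsTrainConfig(
                epochs=epochs, lr=lr, batch_size=batch_size, seed=seed,
                weighting_enabled=weighting), mask_cache=mask_cache)
            aucs[arm] = macro_auroc(y_true, predict_proba(model, test, mask_cache))
            models[arm] = model
        per_seed.append({"seed": seed, "auroc_weighted": aucs["weighted"],
                         "auroc_unweighted": aucs["unweighted"],
                         "gap": aucs["weighted"] - aucs["unweighted"]})
        if keep_models and i == 0:
            extras = {"model_weighted": models["weighted"],
                      "model_unweighted": models["unweighted"],
                      "segmenter": seg, "test_samples": test,
                      "class_names": cfg.class_names}
    gaps = [r["gap"] for r in per_seed]
    return {"per_seed": per_seed, "median_gap": float(np.median(gaps)),
            "median_auroc_weighted": float(np.median([r["auroc_weighted"] for r in per_seed])),
            "median_auroc_unweighted": float(np.median([r["auroc_unweighted"] for r in per_seed])),
            "n_samples": n_samples, **extras}


def localization_study(model, test_samples, class_names,
                       threshold_frac: float = CAM_THRESHOLD_FRAC) -> dict:
    """CAM-derived boxes vs. a fixed central box covering 25 % of the image."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = evaluate_localization(model, test_samples, class_names, threshold_frac)
    image_size = test_samples[0].image.shape[-1]
    baseline = central_box(image_size)
    base_scores: dict[int, list[float]] = {}
    for s in test_samples:
        by_class: dict[int, list] = {}
        for k, box in s.boxes:
            by_class.setdefault(k, []).append(box)
        for k, boxes in by_class.items():
            base_scores.setdefault(k, []).append(max(iou(baseline, g) for g in boxes))
    table = table.copy()
    table["central_baseline_iou"] = [
        float(np.mean(base_scores[class_names.index(row["class"])]))
        for _, row in table.iterrows()]
    return {"table": table,
            "mean_cam_iou": float(table["mean_iou"].mean()),
            "mean_central_iou": float(table["central_baseline_iou"].mean())}
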