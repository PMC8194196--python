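"""Dataset readers/writers, run configuration and the end-to-end pipeline.

Datasets live in a directory of plain files: ``images/*.png`` (8-bit
grayscale, replicated to 3 channels on load), ``masks/<structure>/*.png``
(0/255 foreground convention), ``labels.csv`` with columns
``Image Index, Finding Labels`` (pipe-separated disease names, ``No Finding``
for an all-zero label vector) and ``bbox.csv`` with
``Image Index, Finding Label, x, y, w, h`` (a tolerant reader also accepts
the bracketed single-string box column found in some distributions).
Coordinates are 0-based, x rightward, y downward, half-open width/height.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import __version__
from .classifier import ClsTrainConfig, train_classifier, predict_proba, CHESTXRAY14_CLASSES
from .localization import BBox, evaluate_localization, CAM_THRESHOLD_FRAC
from .metrics import evaluate_classifier
from .phantom import (PhantomConfig, PhantomSample, LesionSpec, generate_phantom,
                      split_phantom)
from .segmentation import (STRUCTURES, StructureMaskSet, SegTrainConfig,
                           train_segmenter, predict_masks, dice_coefficient)

logger = logging.getLogger("maskcxr")


# ---------------------------------------------------------------------------
# dataset directory I/O
# ---------------------------------------------------------------------------

def write_dataset(samples: list[PhantomSample], out_dir, class_names: list[str]) -> Path:
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    for structure in STRUCTURES:
        (out / "masks" / structure).mkdir(parents=True, exist_ok=True)
    label_rows = []
    bbox_rows = []
    for s in samples:
        gray = np.clip(np.rint(s.image[0] * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(gray).save(out / "images" / s.sample_id)
        for structure, mask in zip(STRUCTURES, s.masks.arrays()):
            Image.fromarray((mask * 255).astype(np.uint8)).save(out / "masks" / structure / s.sample_id)
        finding = "|".join(class_names[k] for k in range(len(class_names)) if s.labels[k]) or "No Finding"
        label_rows.append({"Image Index": s.sample_id, "Finding Labels": finding})
        for k, box in s.boxes:
            bbox_rows.append({"Image Index": s.sample_id, "Finding Label": class_names[k],
                              "x": box.x, "y": box.y, "w": box.w, "h": box.h})
    pd.DataFrame(label_rows).to_csv(out / "labels.csv", index=False)
    pd.DataFrame(bbox_rows, columns=["Image Index", "Finding Label", "x", "y", "w", "h"]).to_csv(
        out / "bbox.csv", index=False)
    return out


def load_image(path, size: int | None = None) -> np.ndarray:
    """Load a PNG as [3, H, W] float32 in [0, 1].  When ``size`` is given and
    differs from the stored size, resize to ``size * 8 // 7`` and centre-crop
    (the usual resize-256-crop-224 convention, scaled)."""
    img = Image.open(path).convert("L")
    if size is not None and img.size != (size, size):
        inter = size * 8 // 7
        img = img.resize((inter, inter), Image.BILINEAR)
        off = (inter - size) // 2
        img = img.crop((off, off, off + size, off + size))
    arr = np.asarray(img, dtype=np.float32) / 255.0
    return np.repeat(arr[None], 3, axis=0)


def load_dataset(data_dir, class_names: list[str]) -> list[PhantomSample]:
    """Read a dataset directory back into samples (distractor boxes are not
    serialised and come back empty)."""
    data_dir = Path(data_dir)
    manifest = read_manifest(data_dir / "labels.csv",
                             data_dir / "bbox.csv" if (data_dir / "bbox.csv").exists() else None,
                             class_names)
    samples = []
    for rec in manifest.records:
        image = load_image(data_dir / "images" / rec["image_id"])
        mask_arrays = {}
        for structure in STRUCTURES:
            m = np.asarray(Image.open(data_dir / "masks" / structure / rec["image_id"]).convert("L"))
            mask_arrays[structure] = (m >= 128).astype(np.uint8)
        samples.append(PhantomSample(
            sample_id=rec["image_id"], image=image,
            masks=StructureMaskSet(**mask_arrays),
            labels=rec["labels"], boxes=rec["boxes"], distractor_boxes=[]))
    return samples


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

@dataclass
class DatasetManifest:
    """Parsed label/box records: each record has ``image_id``, a binary
    ``labels`` vector and a (possibly empty) list of (class index, BBox)."""

    records: list[dict]
    class_names: list[str]
    split: str = ""


def parse_finding_labels(finding: str, class_names: list[str]) -> np.ndarray:
    labels = np.zeros(len(class_names), dtype=np.uint8)
    finding = (finding or "").strip()
    if finding in ("", "No Finding"):
        return labels
    unknown = []
    for name in finding.split("|"):
        name = name.strip()
        if name in class_names:
            labels[class_names.index(name)] = 1
        else:
            unknown.append(name)
    if unknown:
        raise ValueError(f"unknown finding names: {unknown}")
    return labels


def _parse_bbox_row(row: pd.Series) -> tuple[float, float, float, float]:
    numeric = [v for v in row.iloc[2:].tolist() if pd.notna(v)]
    if len(numeric) == 1 and isinstance(numeric[0], str):
        parts = numeric[0].replace("[", " ").replace("]", " ").replace(",", " ").split()
        numeric = [float(p) for p in parts]
    if len(numeric) < 4:
        raise ValueError(f"bounding-box row needs 4 coordinates: {row.tolist()}")
    return tuple(float(v) for v in numeric[:4])


def read_manifest(labels_csv, bbox_csv=None, class_names=CHESTXRAY14_CLASSES) -> DatasetManifest:
    class_names = list(class_names)
    df = pd.read_csv(labels_csv)
    required = {"Image Index", "Finding Labels"}
    if not required.issubset(df.columns):
        raise ValueError(f"labels CSV must have columns {sorted(required)}")
    records = {}
    for i, row in df.iterrows():
        try:
            labels = parse_finding_labels(row["Finding Labels"], class_names)
        except ValueError as e:
            raise ValueError(f"row {i + 1} of {labels_csv}: {e}") from None
        image_id = str(row["Image Index"])
        if image_id in records:
            raise ValueError(f"duplicate image id '{image_id}'")
        records[image_id] = {"image_id": image_id, "labels": labels, "boxes": []}
    if bbox_csv is not None:
        bdf = pd.read_csv(bbox_csv)
        for i, row in bdf.iterrows():
            name = str(row["Finding Label"]).strip()
            if name not in class_names:
                raise ValueError(f"row {i + 1} of {bbox_csv}: unknown class '{name}'")
            x, y, w, h = _parse_bbox_row(row)
            image_id = str(row["Image Index"])
            if image_id in records:
                records[image_id]["boxes"].append(
                    (class_names.index(name), BBox(int(round(x)), int(round(y)),
                                                   int(round(w)), int(round(h)))))
    return DatasetManifest(records=list(records.values()), class_names=class_names)


def manifest_statistics(manifest: DatasetManifest) -> pd.DataFrame:
    """Per-class image counts plus multi-label / finding / no-finding / total
    rows, mirroring the usual benchmark-split statistics table."""
    rows = []
    label_matrix = (np.stack([r["labels"] for r in manifest.records])
                    if manifest.records else np.zeros((0, len(manifest.class_names)), dtype=np.uint8))
    for k, name in enumerate(manifest.class_names):
        rows.append({"row": name, "count": int(label_matrix[:, k].sum())})
    any_finding = label_matrix.any(axis=1) if len(label_matrix) else np.zeros(0, dtype=bool)
    rows.append({"row": "Multi-label totals", "count": int(label_matrix.sum())})
    rows.append({"row": "Finding", "count": int(any_finding.sum())})
    rows.append({"row": "No finding", "count": int((~any_finding).sum())})
    rows.append({"row": "Totals", "count": len(manifest.records)})
    return pd.DataFrame(rows, columns=["row", "count"])


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    phantom: PhantomConfig = field(default_factory=lambda: PhantomConfig(
        image_size=64, n_samples=200, n_classes=4))
    seg: SegTrainConfig = field(default_factory=lambda: SegTrainConfig(base_width=8, depth=3, epochs=8))
    cls: ClsTrainConfig = field(default_factory=lambda: ClsTrainConfig(epochs=6))
    train_frac: float = 0.9
    val_frac: float = 0.1
    cam_threshold: float = CAM_THRESHOLD_FRAC
    seed: int = 0
    out_dir: str = "runs/phantom"

    def resolve_seeds(self) -> "RunConfig":
        """Propagate the global seed into every stage config."""
        cfg = dataclasses.replace(self)
        cfg.phantom = dataclasses.replace(cfg.phantom, seed=cfg.seed)
        cfg.seg = dataclasses.replace(cfg.seg, seed=cfg.seed + 1)
        cfg.cls = dataclasses.replace(cfg.cls, seed=cfg.seed + 2)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phantom"]["lesion_specs"] = {
            k: {"family": v.family, "size_range": list(v.size_range),
                "intensity_range": list(v.intensity_range)}
            for k, v in self.phantom.lesion_specs.items()}
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        ph = dict(d.pop("phantom", {}))
        if "lesion_specs" in ph:
            ph["lesion_specs"] = {k: LesionSpec(v["family"], tuple(v["size_range"]),
                                                tuple(v["intensity_range"]))
                                  for k, v in ph["lesion_specs"].items()}
        if "label_prior" in ph and isinstance(ph["label_prior"], list):
            ph["label_prior"] = list(ph["label_prior"])
        seg = SegTrainConfig(**d.pop("seg", {}))
        cls_cfg = d.pop("cls", {})
        if "scale_kernels" in cls_cfg:
            cls_cfg["scale_kernels"] = tuple(cls_cfg["scale_kernels"])
        return cls(phantom=PhantomConfig(**ph), seg=seg, cls=ClsTrainConfig(**cls_cfg), **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Generate phantoms, train the segmenter and the classifier, evaluate
    classification and localization, and write all artifacts under
    ``config.out_dir``.  Returns a dict of results and artifact paths."""
    config = config.resolve_seeds()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    (out / "VERSION").write_text(__version__ + "\n")

    results: dict = {"out_dir": str(out)}
    t0 = time.time()
    current = {"stage": "init"}

    def stage(name):
        current["stage"] = name
        logger.info("stage %-12s t=%.1fs", name, time.time() - t0)

    try:
        stage("generate")
        samples = generate_phantom(config.phantom)
        write_dataset(samples, out / "dataset", config.phantom.class_names)
        train, val, test = split_phantom(samples, config.train_frac, config.val_frac,
                                         seed=config.seed)

        stage("train-seg")
        segmenter, seg_log = train_segmenter(train, val, config.seg)
        pd.DataFrame(seg_log).to_csv(out / "seg_log.csv", index=False)

        stage("train-cls")
        model, cls_log = train_classifier(train, val, segmenter, config.cls)
        pd.DataFrame(cls_log).to_csv(out / "cls_log.csv", index=False)

        stage("evaluate")
        y_true = np.stack([s.labels for s in test])
        y_score = predict_proba(model, test)
        report = evaluate_classifier(y_true, y_score, config.phantom.class_names)
        report.to_csv(out / "classification_report.csv", index=False)
        seg_dice = float(np.mean([
            np.mean([dice_coefficient(g, p) for g, p in
                     zip(s.masks.stack(), predict_masks(s.image, segmenter).stack())])
            for s in test]))

        stage("localize")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            iou_table = evaluate_localization(model, test, config.phantom.class_names,
                                              config.cam_threshold)
        iou_table.to_csv(out / "localization_report.csv", index=False)

        results.update({
            "segmenter": segmenter, "model": model,
            "classification_report": report, "localization_report": iou_table,
            "test_mean_dice": seg_dice,
            "n_train": len(train), "n_val": len(val), "n_test": len(test),
        })
    except Exception as e:
        raise RuntimeError(f"pipeline stage '{current['stage']}' failed: {e}") from e
    stage("done")
    return results
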