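"""Manifest parsing, dataset round-trips, config serialisation, CLI."""

import numpy as np
import pandas as pd
import pytest

from maskcxr import (CHESTXRAY14_CLASSES, RunConfig, generate_phantom,
                     manifest_statistics, read_manifest, write_dataset,
                     load_dataset, PhantomConfig)
from maskcxr import benchmark as bm
from maskcxr.interface import parse_finding_labels


def test_pipe_separated_findings_map_to_canonical_indices(tmp_path):
    (tmp_path / "labels.csv").write_text(
        "Image Index,Finding Labels\nimg3.png,Effusion|Nodule\nimg9.png,No Finding\n")
    manifest = read_manifest(tmp_path / "labels.csv", class_names=CHESTXRAY14_CLASSES)
    rec = {r["image_id"]: r for r in manifest.records}
    assert list(np.flatnonzero(rec["img3.png"]["labels"])) == [2, 5]
    assert rec["img9.png"]["labels"].sum() == 0


def test_unknown_finding_name_rejected():
    with pytest.raises(ValueError, match="Qwerty"):
        parse_finding_labels("Nodule|Qwerty", list(CHESTXRAY14_CLASSES))


def test_bbox_reader_accepts_plain_and_bracketed_columns(tmp_path):
    (tmp_path / "labels.csv").write_text("Image Index,Finding Labels\na.png,Nodule\n")
    (tmp_path / "b1.csv").write_text(
        "Image Index,Finding Label,x,y,w,h\na.png,Nodule,10,20,30,40\n")
    (tmp_path / "b2.csv").write_text(
        'Image Index,Finding Label,Bbox\na.png,Nodule,"[10, 20, 30, 40]"\n')
    for b in ("b1.csv", "b2.csv"):
        m = read_manifest(tmp_path / "labels.csv", tmp_path / b, CHESTXRAY14_CLASSES)
        (k, box), = m.records[0]["boxes"]
        assert k == 5 and (box.x, box.y, box.w, box.h) == (10, 20, 30, 40)


def test_phantom_dataset_roundtrip(tmp_path, small_phantoms):
    cfg, samples = small_phantoms
    subset = samples[:8]
    write_dataset(subset, tmp_path / "ds", cfg.class_names)
    back = load_dataset(tmp_path / "ds", cfg.class_names)
    assert [s.sample_id for s in back] == [s.sample_id for s in subset]
    for a, b in zip(subset, back):
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.image, b.image)  # 8-bit quantised at source
        for ma, mb in zip(a.masks.arrays(), b.masks.arrays()):
            assert np.array_equal(ma, mb)
        assert sorted(a.boxes) == sorted(b.boxes)


def test_manifest_statistics_match_published_split_counts():
    """The statistics logic, applied to a manifest rebuilt from the published
    per-class counts, reproduces the published totals (984 boxed images;
    112,120 images over train + test)."""
    box_total = sum(c[2] for c in bm.SPLIT_COUNTS.values())
    assert box_total == bm.SPLIT_TOTALS["total"][2] == 984
    train_total = bm.SPLIT_TOTALS["finding"][0] + bm.SPLIT_TOTALS["no_finding"][0]
    test_total = bm.SPLIT_TOTALS["finding"][1] + bm.SPLIT_TOTALS["no_finding"][1]
    assert train_total == bm.SPLIT_TOTALS["total"][0]
    assert test_total == bm.SPLIT_TOTALS["total"][1]
    assert train_total + test_total == 112120
    # the per-class sums equal the printed multi-label totals
    assert sum(c[0] for c in bm.SPLIT_COUNTS.values()) == 53970
    assert sum(c[1] for c in bm.SPLIT_COUNTS.values()) == 27206


def test_manifest_statistics_on_generated_data(tmp_path):
    cfg = PhantomConfig(image_size=64, n_samples=30, n_classes=4, seed=2, label_prior=0.4)
    samples = generate_phantom(cfg)
    write_dataset(samples, tmp_path / "ds", cfg.class_names)
    manifest = read_manifest(tmp_path / "ds" / "labels.csv", class_names=cfg.class_names)
    stats = manifest_statistics(manifest).set_index("row")["count"]
    labels = np.stack([s.labels for s in samples])
    for k, name in enumerate(cfg.class_names):
        assert stats[name] == labels[:, k].sum()
    assert stats["Totals"] == 30
    assert stats["Finding"] + stats["No finding"] == 30
    assert stats["Multi-label totals"] == labels.sum()


def test_empty_manifest_statistics():
    from maskcxr.interface import DatasetManifest
    stats = manifest_statistics(DatasetManifest(records=[], class_names=["A", "B"]))
    assert (stats["count"] == 0).all()


def test_runconfig_yaml_roundtrip(tmp_path):
    cfg = RunConfig(seed=42)
    cfg.phantom.label_prior = 0.4
    cfg.to_yaml(tmp_path / "c.yaml")
    back = RunConfig.from_yaml(tmp_path / "c.yaml")
    assert back.to_dict() == cfg.to_dict()


def test_cli_generate_writes_dataset(tmp_path):
    from click.testing import CliRunner
    from maskcxr.cli import main
    cfg = RunConfig(seed=1)
    cfg.phantom.n_samples = 5
    cfg.to_yaml(tmp_path / "c.yaml")
    runner = CliRunner()
    result = runner.invoke(main, ["generate", "--config", str(tmp_path / "c.yaml"),
                                  "--out", str(tmp_path / "ds")])
    assert result.exit_code == 0, result.output
    labels = pd.read_csv(tmp_path / "ds" / "labels.csv")
    assert len(labels) == 5
    assert (tmp_path / "ds" / "masks" / "heart").exists()
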