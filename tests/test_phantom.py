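"""Phantom generator: determinism, mask containment, label semantics, splits."""

import numpy as np
import pytest

from maskcxr import PhantomConfig, generate_phantom, split_phantom, auroc
from maskcxr.phantom import default_class_names


def test_identical_configs_are_byte_identical():
    cfg = PhantomConfig(image_size=64, n_samples=10, n_classes=4, seed=7)
    a = generate_phantom(cfg)
    b = generate_phantom(cfg)
    for sa, sb in zip(a, b):
        assert np.array_equal(sa.image, sb.image)
        assert np.array_equal(sa.labels, sb.labels)
        assert sa.boxes == sb.boxes and sa.distractor_boxes == sb.distractor_boxes


def test_zero_prior_zero_distractors_gives_empty_findings():
    cfg = PhantomConfig(image_size=64, n_samples=15, n_classes=4, seed=1,
                        label_prior=0.0, distractor_rate=0.0)
    for s in generate_phantom(cfg):
        assert s.labels.sum() == 0 and not s.boxes and not s.distractor_boxes


def test_prevalence_matches_binomial_prior():
    """Empirical per-class prevalence stays within 3 binomial standard
    deviations of the 0.5 prior at n=200."""
    n, p = 200, 0.5
    cfg = PhantomConfig(image_size=64, n_samples=n, n_classes=4, seed=1, label_prior=p)
    labels = np.stack([s.labels for s in generate_phantom(cfg)])
    sd = np.sqrt(p * (1 - p) / n)
    assert np.all(np.abs(labels.mean(axis=0) - p) <= 3 * sd)


def test_lesions_inside_mask_distractors_outside(small_phantoms):
    """Label-bearing boxes overlap the anatomy heavily; distractor boxes have
    zero pixel overlap with the merged mask; labels match inserted lesions."""
    _, samples = small_phantoms
    for s in samples:
        merged = s.merged_mask.mask[0].astype(bool)
        classes_with_boxes = set()
        for k, b in s.boxes:
            classes_with_boxes.add(k)
            region = merged[b.y:b.y2, b.x:b.x2]
            assert region.mean() >= 0.5  # box is anatomy-dominated
        for b in s.distractor_boxes:
            assert not merged[b.y:b.y2, b.x:b.x2].any()
        assert classes_with_boxes == {k for k in range(4) if s.labels[k]}


def test_structure_masks_are_binary_and_consistent(small_phantoms):
    _, samples = small_phantoms
    for s in samples[:10]:
        for m in s.masks.arrays():
            assert set(np.unique(m)).issubset({0, 1})
        assert np.array_equal(
            s.merged_mask.mask[0],
            np.clip(sum(m.astype(int) for m in s.masks.arrays()), 0, 1))


def test_bright_disc_class_is_learnable_by_pixel_threshold(small_phantoms):
    """A trivial high-intensity pixel count inside the anatomy separates the
    disc (nodule-like) class from its absence: AUROC strictly above 0.5."""
    cfg, samples = small_phantoms
    k = cfg.class_names.index("Nodule")
    scores, labels = [], []
    for s in samples:
        lungs = ((s.masks.left_lung | s.masks.right_lung) & ~s.masks.heart).astype(bool)
        scores.append(float((s.image[0][lungs] > 0.48).sum()))
        labels.append(int(s.labels[k]))
    assert auroc(np.array(scores), np.array(labels)) > 0.5


def test_invalid_config_rejected_with_field_name():
    with pytest.raises(ValueError, match="image_size"):
        PhantomConfig(image_size=16)
    with pytest.raises(ValueError, match="n_classes"):
        PhantomConfig(n_classes=15)
    with pytest.raises(ValueError, match="distractor_rate"):
        PhantomConfig(distractor_rate=1.5)
    with pytest.raises(ValueError, match="label_prior"):
        PhantomConfig(label_prior=[0.5, 2.0, 0.5, 0.5])


def test_split_sizes_membership_and_determinism():
    cfg = PhantomConfig(image_size=64, n_samples=100, n_classes=4, seed=5, label_prior=0.3)
    samples = generate_phantom(cfg)
    train, val, test = split_phantom(samples, 0.9, 0.1, seed=11)
    assert (len(train), len(val), len(test)) == (81, 9, 10)
    ids = [s.sample_id for s in train + val + test]
    assert len(set(ids)) == len(ids) == 100
    train2, val2, test2 = split_phantom(samples, 0.9, 0.1, seed=11)
    assert [s.sample_id for s in train2] == [s.sample_id for s in train]
    assert [s.sample_id for s in val2] == [s.sample_id for s in val]
    assert [s.sample_id for s in test2] == [s.sample_id for s in test]


def test_default_class_names_extend_to_14():
    assert default_class_names(4) == ["Cardiomegaly", "Infiltration", "Nodule", "Consolidation"]
    assert len(default_class_names(14)) == 14
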