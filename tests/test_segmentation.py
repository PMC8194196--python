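"""Dice objective, mask merging, and the U-Net segmenter contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from maskcxr import (StructureMaskSet, SegTrainConfig, UNet, dice_coefficient,
                     dice_loss, merge_masks, predict_masks, train_segmenter,
                     split_phantom)
from maskcxr.experiments import heldout_mean_dice
from maskcxr.segmentation import predict_soft


def test_dice_identity_disjoint_and_hand_count():
    a = np.zeros((6, 6))
    a[1:3, 1:3] = 1  # 4 pixels
    assert dice_coefficient(a, a) == pytest.approx(1.0, abs=0.15)  # eps-smoothed
    b = np.zeros((6, 6))
    b[4:6, 4:6] = 1
    assert dice_coefficient(a, b) == pytest.approx(0.0, abs=0.15)
    # 4 vs 4 foreground pixels with overlap 2 -> 2*2/(4+4) = 0.5
    c = np.zeros((6, 6))
    c[2:4, 1:3] = 1
    assert dice_coefficient(a, c, smooth=0.0) == pytest.approx(0.5)
    assert dice_loss(a, c, smooth=0.0) == pytest.approx(0.5)


def test_dice_smoothing_handles_empty_masks():
    empty = np.zeros((8, 8))
    assert dice_coefficient(empty, empty) == pytest.approx(1.0)
    assert dice_loss(empty, empty) == pytest.approx(0.0)


def test_dice_rejects_bad_inputs():
    with pytest.raises(ValueError):
        dice_coefficient(np.zeros((4, 4)), np.zeros((5, 4)))
    with pytest.raises(ValueError):
        dice_coefficient(np.full((4, 4), 2.0), np.zeros((4, 4)))


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 2 ** 16 - 1))
def test_dice_symmetric_bounded_and_monotone(bits):
    """For binary masks dice is symmetric, in [0,1], and flipping a
    false-negative pixel to 1 never decreases it."""
    rng = np.random.default_rng(bits)
    gt = (rng.random((4, 4)) < 0.5).astype(float)
    pred = (rng.random((4, 4)) < 0.5).astype(float)
    d = dice_coefficient(gt, pred)
    assert 0.0 <= d <= 1.0
    assert d == pytest.approx(dice_coefficient(pred, gt))
    fn = np.argwhere((gt == 1) & (pred == 0))
    if len(fn):
        pred2 = pred.copy()
        pred2[tuple(fn[0])] = 1.0
        assert dice_coefficient(gt, pred2) >= d


def test_merge_masks_is_elementwise_or():
    rng = np.random.default_rng(0)
    trio = [(rng.random((8, 8)) < 0.4).astype(np.uint8) for _ in range(3)]
    masks = StructureMaskSet(*trio)
    merged = merge_masks(masks).mask[0]
    ref = np.zeros((8, 8), dtype=np.uint8)
    for y in range(8):
        for x in range(8):
            ref[y, x] = 1 if (trio[0][y, x] or trio[1][y, x] or trio[2][y, x]) else 0
    assert np.array_equal(merged, ref)
    # overlap clips to 1, empties stay empty
    assert merged.max() <= 1
    empty = merge_masks(StructureMaskSet(*[np.zeros((4, 4), np.uint8)] * 3))
    assert empty.mask.sum() == 0
    # subadditivity under union
    assert merged.sum() <= sum(t.sum() for t in trio)


def test_untrained_segmenter_output_contract(small_phantoms):
    """Any image through any segmenter yields a valid {0,1} StructureMaskSet."""
    net = UNet(base_width=4, depth=3, seed=0)
    net.eval()
    blank = np.zeros((3, 32, 32), dtype=np.float32)
    masks = predict_masks(blank, net)
    for m in masks.arrays():
        assert m.shape == (32, 32)
        assert set(np.unique(m)).issubset({0, 1})
    soft = predict_soft(blank, net)
    assert soft.min() >= 0.0 and soft.max() <= 1.0
    # constant 0.4 probability thresholds to an all-zero mask at 0.5
    assert ((np.full((16, 16), 0.4) > 0.5).astype(np.uint8) == 0).all()


def test_training_is_seed_deterministic(small_phantoms):
    _, samples = small_phantoms
    train, val, _ = split_phantom(samples, 0.8, 0.1, seed=3)
    cfg = SegTrainConfig(epochs=2, base_width=4, depth=3, seed=9)
    _, log1 = train_segmenter(train[:12], val[:3], cfg)
    _, log2 = train_segmenter(train[:12], val[:3], cfg)
    assert log1 == log2


def test_best_epoch_no_worse_than_initial(trained_segmenter):
    _, log, _ = trained_segmenter
    assert min(r["val_loss"] for r in log) <= log[0]["val_loss"]


def test_trained_segmenter_recovers_anatomy(trained_segmenter):
    """Per-structure dice against ground truth on held-out phantoms."""
    seg, _, (_, _, test) = trained_segmenter
    for s in test:
        pred = predict_masks(s.image, seg).stack()
        for g, p in zip(s.masks.stack(), pred):
            assert dice_coefficient(g, p) >= 0.85


def test_empty_training_set_rejected():
    with pytest.raises(ValueError):
        train_segmenter([], [], SegTrainConfig(epochs=1))
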