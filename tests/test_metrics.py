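"""AUROC, ROC thresholds and the two benchmark aggregators."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from maskcxr import (auroc, choose_threshold, macro_average, relative_improvement,
                     roc_result, weighted_average)
from maskcxr import benchmark as bm


def pairwise_auroc(scores, labels):
    """O(n^2) Mann-Whitney oracle with half-credit ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_auroc_separated_ties_and_hand_case():
    assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
    assert auroc([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1]) == 0.5
    assert auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)


def test_auroc_matches_pairwise_oracle():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = int(rng.integers(4, 30))
        labels = rng.integers(0, 2, n)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 0, 1
        scores = np.round(rng.random(n), 1)  # coarse grid forces ties
        assert auroc(scores, labels) == pytest.approx(pairwise_auroc(scores, labels))


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 2 ** 16 - 1))
def test_auroc_invariant_under_increasing_transform(bits):
    rng = np.random.default_rng(bits)
    labels = rng.integers(0, 2, 20)
    if len(np.unique(labels)) < 2:
        labels[:2] = [0, 1]
    scores = rng.random(20)
    assert auroc(scores, labels) == pytest.approx(auroc(np.exp(3 * scores), labels))


def test_single_class_labels_are_undefined_with_warning():
    with pytest.warns(UserWarning):
        assert auroc([0.1, 0.2], [1, 1]) is None


def test_roc_points_monotone_and_area_consistent():
    rng = np.random.default_rng(2)
    labels = rng.integers(0, 2, 100)
    labels[:2] = [0, 1]
    scores = np.clip(labels * 0.3 + rng.random(100) * 0.7, 0, 1)
    r = roc_result(scores, labels)
    assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)
    assert (r.fpr[0], r.tpr[0]) == (0.0, 0.0) and (r.fpr[-1], r.tpr[-1]) == (1.0, 1.0)
    assert r.auroc == pytest.approx(np.trapezoid(r.tpr, r.fpr))


def test_youden_threshold_separating_and_random_cases():
    r = roc_result([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
    assert 0.2 < r.operating_threshold <= 0.8
    j = (r.tpr - r.fpr).max()
    assert j == pytest.approx(1.0)
    # independent labels: J stays small but a threshold is still returned
    for seed in range(5):
        rng = np.random.default_rng(seed)
        scores = rng.random(200)
        labels = rng.integers(0, 2, 200)
        r = roc_result(scores, labels)
        assert (r.tpr - r.fpr).max() <= 0.3
        assert np.isfinite(r.operating_threshold)


def test_threshold_choice_is_rank_invariant():
    scores = np.array([0.05, 0.2, 0.3, 0.55, 0.7, 0.9])
    labels = np.array([0, 0, 1, 0, 1, 1])
    r1 = roc_result(scores, labels)
    r2 = roc_result(scores ** 3, labels)  # strictly increasing relabeling
    assert np.argmin(np.abs(scores - r1.operating_threshold)) == \
        np.argmin(np.abs(scores ** 3 - r2.operating_threshold))


def test_macro_average_reproduces_reported_benchmark_means():
    assert macro_average(bm.auroc_vector(bm.REPORTED_AUROC_WEIGHTED)) == 0.8335
    assert macro_average(bm.auroc_vector(bm.REPORTED_AUROC_UNWEIGHTED)) == 0.8222
    assert macro_average([0.7] * 5) == 0.7


def test_box_weighted_average_reproduces_reported_iou_aggregates():
    w = bm.box_counts()
    assert weighted_average(bm.iou_vector(bm.REPORTED_IOU_ATTENTION), w) == 0.3014
    assert weighted_average(bm.iou_vector(bm.REPORTED_IOU_NO_ATTENTION), w) == 0.2437
    vals = [0.2, 0.4, 0.9]
    assert weighted_average(vals, [1, 1, 1]) == macro_average(vals)
    with pytest.raises(ValueError):
        weighted_average([1.0], [0.0])


def test_relative_improvement_cases():
    assert relative_improvement(0.7901, bm.INFILTRATION_BASELINE_AUROC) == 12.87
    assert relative_improvement(0.5, 0.5) == 0.0
    assert relative_improvement(1.0, 0.5) == 100.0
    with pytest.raises(ValueError):
        relative_improvement(0.5, 0.0)


def test_empty_macro_average_rejected():
    with pytest.raises(ValueError):
        macro_average([])
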