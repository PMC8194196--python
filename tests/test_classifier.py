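"""Feature extraction, mask weighting, the multi-label head and BCE."""

import numpy as np
import pytest

from maskcxr import (ChestXRayClassifier, bce_loss, classify, downsample_mask,
                     extract_features, feature_weighting, preprocess_image)
from maskcxr.classifier import (DenseNetBackbone, TinyBackbone,
                                adaptive_avg_pool2d, sample_feature_mask,
                                model_features_for_sample)
from maskcxr.segmentation import merge_masks, predict_masks
from maskcxr import nn


def test_tiny_backbone_feature_grid():
    model = ChestXRayClassifier(4, backbone="tiny", seed=0)
    img = preprocess_image(np.random.default_rng(0).random((3, 64, 64)))
    f_g = extract_features(img, model)
    assert f_g.shape == (32, 8, 8)


def test_dense_backbone_feature_grid_at_224():
    """The 121-layer dense backbone maps 224x224 to a 1024-channel 7x7 map
    (five stride-2 stages: 224 / 32 = 7)."""
    backbone = DenseNetBackbone(seed=0)
    backbone.eval()
    x = np.random.default_rng(1).standard_normal((1, 3, 224, 224)).astype(np.float32)
    assert backbone.forward(x).shape == (1, 1024, 7, 7)


def test_identity_gate_equals_disabled_attention():
    """With the gate forced to 1 the attended path equals the no-attention
    path for identical backbone weights."""
    on = ChestXRayClassifier(4, seed=5, attention_enabled=True)
    off = ChestXRayClassifier(4, seed=5, attention_enabled=False)
    off.backbone.set_state(on.backbone.get_state())
    off.head.set_state(on.head.get_state())
    # force the fusion conv to emit a huge positive logit -> gate ~ 1
    on.attention.fuse.weight.value[...] = 0.0
    on.attention.fuse.bias.value[...] = 500.0
    img = preprocess_image(np.random.default_rng(2).random((3, 64, 64)))
    on.eval(), off.eval()
    f_on = extract_features(img, on)
    f_off = extract_features(img, off)
    assert np.allclose(f_on, f_off, atol=1e-4)


def test_adaptive_pooling_hand_case_and_mask_binarisation():
    m = np.zeros((1, 4, 4))
    m[0, 0, 1] = 1.0
    pooled = adaptive_avg_pool2d(m, (2, 2))
    assert pooled[0, 0, 0] == pytest.approx(0.25)
    assert pooled[0, 0, 1] == 0.0
    dm = downsample_mask(m, 2, 2)
    assert np.array_equal(dm[0], [[1, 0], [0, 0]])
    ones = downsample_mask(np.ones((1, 16, 16)), 3, 3)
    assert ones.sum() == 9
    zeros = downsample_mask(np.zeros((1, 16, 16)), 5, 5)
    assert zeros.sum() == 0
    with pytest.raises(ValueError):
        downsample_mask(np.ones((1, 4, 4)), 8, 8)


def test_feature_weighting_identity_annihilator_and_oracle():
    rng = np.random.default_rng(3)
    f_g = rng.standard_normal((6, 5, 5))
    assert np.array_equal(feature_weighting(f_g, np.ones((1, 5, 5))), f_g)
    assert not feature_weighting(f_g, np.zeros((1, 5, 5))).any()
    m = (rng.random((1, 5, 5)) < 0.5).astype(float)
    f_l = feature_weighting(f_g, m)
    ref = np.empty_like(f_g)
    for k in range(6):
        for y in range(5):
            for x in range(5):
                ref[k, y, x] = f_g[k, y, x] * m[0, y, x]
    assert np.array_equal(f_l, ref)
    assert not f_l[:, m[0] == 0].any()  # bitwise zero outside the mask
    with pytest.raises(ValueError):
        feature_weighting(f_g, np.ones((1, 4, 5)))


def test_classify_hand_arithmetic_and_zero_head():
    f_l = np.array([[[3.0]], [[1.0]]])  # c_feat=2, h=w=1
    w = np.array([[1.0, -1.0]])
    probs = classify(f_l, w, np.zeros(1))
    assert probs[0] == pytest.approx(1 / (1 + np.exp(-2.0)), abs=1e-6)
    rng = np.random.default_rng(4)
    f = rng.standard_normal((8, 3, 3))
    assert np.allclose(classify(f, np.zeros((5, 8)), np.zeros(5)), 0.5)


def test_zero_mask_blackout_depends_only_on_bias():
    """With an all-zero mask the prediction is sigmoid(bias), image-independent."""
    model = ChestXRayClassifier(3, seed=6, attention_enabled=False)
    model.eval()
    rng = np.random.default_rng(7)
    masks = np.zeros((1, 1, 8, 8), dtype=np.float32)
    p1, _ = model.forward(preprocess_image(rng.random((3, 64, 64)))[None], masks)
    p2, _ = model.forward(preprocess_image(rng.random((3, 64, 64)))[None], masks)
    assert np.allclose(p1, p2, atol=1e-7)
    assert np.allclose(p1[0], nn.sigmoid(model.head.bias.value), atol=1e-6)


def test_bce_closed_forms_and_loop_oracle():
    assert bce_loss(np.array([1.0, 0.0]), np.array([1.0, 0.0])) == pytest.approx(0.0, abs=1e-5)
    assert bce_loss(np.array([1.0]), np.array([0.5])) == pytest.approx(np.log(2), abs=1e-9)
    assert bce_loss(np.zeros(14), np.full(14, 0.5)) == pytest.approx(np.log(2), abs=1e-9)
    rng = np.random.default_rng(8)
    for _ in range(20):
        c = int(rng.integers(1, 15))
        y = (rng.random(c) < 0.5).astype(float)
        p = rng.uniform(0.01, 0.99, c)
        ref = 0.0
        for i in range(c):
            ref -= (y[i] * np.log(p[i]) + (1 - y[i]) * np.log(1 - p[i]))
        assert bce_loss(y, p) == pytest.approx(ref / c, abs=1e-10)
    with pytest.raises(ValueError):
        bce_loss(np.zeros(3), np.full(4, 0.5))


def test_masked_features_bitwise_zero_for_any_model():
    model = ChestXRayClassifier(4, seed=9)
    model.eval()
    x = preprocess_image(np.random.default_rng(10).random((3, 64, 64)))[None]
    masks = np.zeros((1, 1, 8, 8), dtype=np.float32)
    masks[0, 0, 2:5, 3:6] = 1.0
    f_g = model.backbone.forward(model.attention.forward(x)[0])
    f_l = f_g * masks
    assert not f_l[0][:, masks[0, 0] == 0].any()


def test_out_of_mask_perturbation_invariance():
    """With attention disabled and weighting on, editing pixels whose
    receptive fields only reach mask-zero feature cells leaves the prediction
    bitwise unchanged (tiny backbone: cell (i,j) sees a 15 px field around
    stride-8 centres)."""
    model = ChestXRayClassifier(4, seed=11, attention_enabled=False)
    model.eval()
    rng = np.random.default_rng(12)
    img = rng.random((3, 64, 64)).astype(np.float32)
    masks = np.zeros((1, 1, 8, 8), dtype=np.float32)
    masks[0, 0, :4, :4] = 1.0  # only the top-left quadrant is kept
    p1, _ = model.forward(preprocess_image(img)[None], masks)
    img2 = img.copy()
    img2[:, 48:, 48:] = rng.random((3, 16, 16))  # far corner: outside every kept field
    p2, _ = model.forward(preprocess_image(img2)[None], masks)
    assert np.array_equal(p1, p2)


def test_composition_consistency(trained_segmenter, small_phantoms):
    """forward(image) equals the explicit chain predict_masks -> merge ->
    downsample -> extract -> weight -> classify."""
    seg, _, _ = trained_segmenter
    _, samples = small_phantoms
    s = samples[0]
    model = ChestXRayClassifier(4, seed=13)
    model.segmenter = seg
    model.eval()
    x = preprocess_image(s.image)
    m = downsample_mask(merge_masks(predict_masks(s.image, seg)), 8, 8)
    manual = classify(feature_weighting(extract_features(x, model), m),
                      model.head.weight.value, model.head.bias.value)
    auto, _ = model.forward(x[None], m[None].astype(np.float32))
    assert np.allclose(manual, auto[0], atol=1e-5)
    # and the package-level helper gives the same features
    assert np.allclose(model_features_for_sample(model, s),
                       feature_weighting(extract_features(x, model), m), atol=1e-6)
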