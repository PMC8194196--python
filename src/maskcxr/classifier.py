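"""Multi-label thoracic-disease classifier with segmentation-weighted features.

Pipeline (the framework's main path): the input radiograph is gated by the
multi-scale attention module, fed to a convolutional backbone, and the
backbone's last feature map — the *global attention map* ``F_g`` of shape
``[c_feat, h, w]`` — is multiplied element-wise with the merged lung/heart
mask downsampled to feature resolution.  The resulting *local attention map*
``F_l`` is exactly zero outside the anatomy and feeds a channel-wise average
pooling plus a fully-connected sigmoid head that outputs one independent
probability per disease.  Training minimises the per-class-averaged binary
cross-entropy; an all-zero label vector encodes "No Finding".

Two backbones are provided: a densely-connected 121-layer network (feature
width 1024, spatial reduction 32 — randomly initialised, since no pretrained
weights ship with the package) and a tiny 3-stage strided CNN (width 32,
reduction 8) for desk-scale experiments.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .attention import MultiScaleAttention, DEFAULT_SCALE_KERNELS, DEFAULT_FUSION_KERNEL
from .segmentation import UNet, merge_masks, predict_masks, MergedMask

#: channel statistics used to normalise inputs (the standard statistics of the
#: large natural-image corpus that pretrained backbones are trained on)
NORMALIZE_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
NORMALIZE_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)

BCE_EPS = 1e-7  # probabilities are clipped to [eps, 1-eps] before the logs

#: canonical 14-disease label order of the ChestX-ray14 benchmark
CHESTXRAY14_CLASSES = (
    "Atelectasis", "Cardiomegaly", "Effusion", "Infiltration", "Mass",
    "Nodule", "Pneumonia", "Pneumothorax", "Consolidation", "Edema",
    "Emphysema", "Fibrosis", "Pleural Thickening", "Hernia",
)


def preprocess_image(image: np.ndarray) -> np.ndarray:
    """Channel-normalise a [3, H, W] image already scaled to [0, 1]."""
    image = np.asarray(image, dtype=np.float32)
    return (image - NORMALIZE_MEAN[:, None, None]) / NORMALIZE_STD[:, None, None]


# ---------------------------------------------------------------------------
# Backbones
# ---------------------------------------------------------------------------

class TinyBackbone(nn.Module):
    """3 stride-2 conv stages (3->24->48->32), spatial reduction 8.

    Receptive field of one output cell is 15 px, which makes the
    out-of-mask invariance of the weighted classifier directly testable.
    Reflect padding keeps the backbone translation-invariant: absolute
    position enters the model only through the explicit anatomy mask,
    never through zero-border signatures.
    """

    out_channels = 32
    reduction = 8

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.net = nn.Sequential(
            nn.Conv2d(3, 24, 3, stride=2, rng=rng, pad_mode="reflect"), nn.BatchNorm2d(24), nn.ReLU(),
            nn.Conv2d(24, 48, 3, stride=2, rng=rng, pad_mode="reflect"), nn.BatchNorm2d(48), nn.ReLU(),
            nn.Conv2d(48, 32, 3, stride=2, rng=rng, pad_mode="reflect"), nn.BatchNorm2d(32), nn.ReLU(),
        )

    def forward(self, x):
        return self.net.forward(x)

    def backward(self, dy):
        return self.net.backward(dy)


class _DenseLayer(nn.Module):
    def __init__(self, cin, growth, bn_size, rng):
        self.bn1 = nn.BatchNorm2d(cin)
        self.relu1 = nn.ReLU()
        self.conv1 = nn.Conv2d(cin, bn_size * growth, 1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(bn_size * growth)
        self.relu2 = nn.ReLU()
        self.conv2 = nn.Conv2d(bn_size * growth, growth, 3, bias=False, rng=rng)

    def forward(self, x):
        return self.conv2.forward(self.relu2.forward(self.bn2.forward(
            self.conv1.forward(self.relu1.forward(self.bn1.forward(x))))))

    def backward(self, dy):
        return self.bn1.backward(self.relu1.backward(self.conv1.backward(
            self.bn2.backward(self.relu2.backward(self.conv2.backward(dy))))))


class _DenseBlock(nn.Module):
    def __init__(self, cin, n_layers, growth, bn_size, rng):
        self.layers = [_DenseLayer(cin + i * growth, growth, bn_size, rng)
                       for i in range(n_layers)]
        self.out_channels = cin + n_layers * growth

    def forward(self, x):
        feats = [x]
        for layer in self.layers:
            feats.append(layer.forward(np.concatenate(feats, axis=1)))
        self._csizes = [f.shape[1] for f in feats]
        return np.concatenate(feats, axis=1)

    def backward(self, dy):
        csz = self._csizes
        offsets = np.cumsum([0] + csz)
        grads = [dy[:, offsets[i]:offsets[i + 1]].copy() for i in range(len(csz))]
        for idx in range(len(self.layers), 0, -1):
            dcat = self.layers[idx - 1].backward(grads[idx])
            off = 0
            for j in range(idx):
                grads[j] += dcat[:, off:off + csz[j]]
                off += csz[j]
        return grads[0]


class _Transition(nn.Module):
    def __init__(self, cin, cout, rng):
        self.bn = nn.BatchNorm2d(cin)
        self.relu = nn.ReLU()
        self.conv = nn.Conv2d(cin, cout, 1, bias=False, rng=rng)
        self.pool = nn.AvgPool2d()

    def forward(self, x):
        return self.pool.forward(self.conv.forward(self.relu.forward(self.bn.forward(x))))

    def backward(self, dy):
        return self.bn.backward(self.relu.backward(self.conv.backward(self.pool.backward(dy))))


class DenseNetBackbone(nn.Module):
    """121-layer densely-connected backbone (blocks 6/12/24/16, growth 32);
    the last convolutional feature map has 1024 channels at 1/32 resolution."""

    out_channels = 1024
    reduction = 32

    def __init__(self, seed: int = 0, block_config=(6, 12, 24, 16),
                 growth: int = 32, init_features: int = 64, bn_size: int = 4):
        rng = np.random.default_rng(seed)
        self.stem_conv = nn.Conv2d(3, init_features, 7, stride=2, padding=3, bias=False, rng=rng)
        self.stem_bn = nn.BatchNorm2d(init_features)
        self.stem_relu = nn.ReLU()
        self.stem_pool = nn.MaxPool2d(3, 2, 1)
        ch = init_features
        self.blocks = []
        self.transitions = []
        for i, n_layers in enumerate(block_config):
            block = _DenseBlock(ch, n_layers, growth, bn_size, rng)
            self.blocks.append(block)
            ch = block.out_channels
            if i < len(block_config) - 1:
                self.transitions.append(_Transition(ch, ch // 2, rng))
                ch //= 2
        self.final_bn = nn.BatchNorm2d(ch)
        self.final_relu = nn.ReLU()
        self.out_channels = ch

    def forward(self, x):
        x = self.stem_pool.forward(self.stem_relu.forward(self.stem_bn.forward(self.stem_conv.forward(x))))
        for i, block in enumerate(self.blocks):
            x = block.forward(x)
            if i < len(self.transitions):
                x = self.transitions[i].forward(x)
        return self.final_relu.forward(self.final_bn.forward(x))

    def backward(self, dy):
        dy = self.final_bn.backward(self.final_relu.backward(dy))
        for i in range(len(self.blocks) - 1, -1, -1):
            if i < len(self.transitions):
                dy = self.transitions[i].backward(dy)
            dy = self.blocks[i].backward(dy)
        return self.stem_conv.backward(self.stem_bn.backward(self.stem_relu.backward(self.stem_pool.backward(dy))))


BACKBONES = {"tiny": TinyBackbone, "dense121": DenseNetBackbone}


# ---------------------------------------------------------------------------
# Feature weighting and the multi-label head
# ---------------------------------------------------------------------------

def adaptive_avg_pool2d(x: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Average over automatically sized cells (floor/ceil boundaries), matching
    the standard adaptive-pooling convention."""
    *lead, h, w = x.shape
    ho, wo = out_hw
    if ho > h or wo > w:
        raise ValueError(f"target {out_hw} exceeds input {(h, w)}")
    out = np.empty((*lead, ho, wo), dtype=np.float64)
    for i in range(ho):
        y0, y1 = (i * h) // ho, -(-((i + 1) * h) // ho)
        for j in range(wo):
            x0, x1 = (j * w) // wo, -(-((j + 1) * w) // wo)
            out[..., i, j] = x[..., y0:y1, x0:x1].mean(axis=(-1, -2))
    return out


def downsample_mask(m_g, h: int, w: int, threshold: float = 0.0) -> np.ndarray:
    """Merged mask [1, H, W] -> feature-resolution binary mask [1, h, w].

    Adaptive average pooling followed by ``pooled > threshold`` binarisation;
    the default ``> 0`` rule marks every cell with any lung/heart overlap,
    which preserves small structures.
    """
    mask = m_g.mask if isinstance(m_g, MergedMask) else np.asarray(m_g)
    if mask.ndim == 2:
        mask = mask[None]
    pooled = adaptive_avg_pool2d(mask.astype(np.float64), (h, w))
    return (pooled > threshold).astype(np.float32)


def feature_weighting(f_g: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Local attention map ``F_l = F_g * M`` (mask broadcast over channels);
    features outside the anatomy are zeroed exactly."""
    f_g = np.asarray(f_g)
    m = np.asarray(m)
    if f_g.shape[-2:] != m.shape[-2:]:
        raise ValueError(f"spatial mismatch: features {f_g.shape[-2:]} vs mask {m.shape[-2:]}")
    return f_g * m


def classify(f_l: np.ndarray, weight: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Channel-wise spatial average of ``F_l`` -> linear head -> sigmoid."""
    f_l = np.asarray(f_l)
    v = f_l.mean(axis=(-2, -1))
    if weight.shape[1] != v.shape[-1]:
        raise ValueError(f"head expects {weight.shape[1]} features, got {v.shape[-1]}")
    return nn.sigmoid(v @ weight.T + bias)


def bce_loss(y: np.ndarray, y_hat: np.ndarray, eps: float = BCE_EPS) -> float:
    """Per-class-averaged binary cross-entropy; for batches, the sample mean."""
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {y_hat.shape}")
    p = np.clip(y_hat, eps, 1.0 - eps)
    per_class = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    return float(per_class.mean(axis=-1).mean())


# ---------------------------------------------------------------------------
# The full model
# ---------------------------------------------------------------------------

class ChestXRayClassifier(nn.Module):
    """Attention gate (optional) -> backbone -> mask weighting (optional)
    -> average pooling -> linear sigmoid head."""

    def __init__(self, n_classes: int, backbone: str = "tiny", seed: int = 0,
                 attention_enabled: bool = True, weighting_enabled: bool = True,
                 scale_kernels=DEFAULT_SCALE_KERNELS, fusion_kernel: int = DEFAULT_FUSION_KERNEL,
                 masked_mean: bool = False):
        rng = np.random.default_rng(seed)
        self.n_classes = n_classes
        self.attention = (MultiScaleAttention(scale_kernels, fusion_kernel, rng=rng)
                          if attention_enabled else None)
        self.backbone = BACKBONES[backbone](seed=seed + 1)
        self.head = nn.Linear(self.backbone.out_channels, n_classes, rng=rng)
        self.weighting_enabled = weighting_enabled
        self.masked_mean = masked_mean
        # the frozen segmenter is attached for inference-time mask computation;
        # held in a dict so parameters() (and thus the optimiser) never sees it
        self._frozen: dict = {"segmenter": None}
        self.mask_threshold: float = 0.0

    @property
    def segmenter(self) -> UNet | None:
        return self._frozen["segmenter"]

    @segmenter.setter
    def segmenter(self, seg: UNet | None) -> None:
        self._frozen["segmenter"] = seg

    def feature_grid(self, h: int, w: int) -> tuple[int, int]:
        r = self.backbone.reduction
        return h // r, w // r

    def forward(self, x: np.ndarray, masks: np.ndarray | None = None):
        """Returns ``(probs, logits)`` for a [N, 3, H, W] batch; ``masks`` is
        the per-sample feature-resolution mask [N, 1, h, w] (required when
        weighting is enabled)."""
        if self.attention is not None:
            gated, _ = self.attention.forward(x)
        else:
            gated = x
        f_g = self.backbone.forward(gated)
        if self.weighting_enabled:
            if masks is None:
                raise ValueError("weighting enabled but no masks supplied")
            f = f_g * masks
        else:
            f = f_g
        if self.masked_mean and self.weighting_enabled:
            counts = np.maximum(masks.sum(axis=(2, 3)), 1.0)
            v = f.sum(axis=(2, 3)) / counts
        else:
            v = f.mean(axis=(2, 3))
        logits = self.head.forward(v)
        self._cache = (masks, f_g.shape)
        return nn.sigmoid(logits), logits

    def backward(self, dlogits: np.ndarray) -> None:
        masks, fshape = self._cache
        n, c_feat, h, w = fshape
        dv = self.head.backward(dlogits)
        if self.masked_mean and self.weighting_enabled:
            counts = np.maximum(masks.sum(axis=(2, 3)), 1.0)
            df = (dv / counts)[:, :, None, None] * np.ones((1, 1, h, w), dtype=dv.dtype)
        else:
            df = np.broadcast_to((dv / (h * w))[:, :, None, None], fshape).astype(dv.dtype)
        if self.weighting_enabled:
            df = df * masks
        dgated = self.backbone.backward(np.ascontiguousarray(df))
        if self.attention is not None:
            self.attention.backward(dgated)


def extract_features(image: np.ndarray, model: ChestXRayClassifier) -> np.ndarray:
    """Global attention map ``F_g`` for one preprocessed [3, H, W] image."""
    model.eval()
    x = image[None].astype(np.float32)
    gated = model.attention.forward(x)[0] if model.attention is not None else x
    return model.backbone.forward(gated)[0]


def sample_feature_mask(model: ChestXRayClassifier, image: np.ndarray) -> np.ndarray:
    """Segment one raw [3, H, W] image with the model's attached segmenter and
    downsample the merged mask to the model's feature grid."""
    if model.segmenter is None:
        raise ValueError("model has no attached segmenter")
    masks = predict_masks(image, model.segmenter)
    h, w = model.feature_grid(*image.shape[-2:])
    return downsample_mask(merge_masks(masks), h, w, model.mask_threshold)


def model_features_for_sample(model: ChestXRayClassifier, sample) -> np.ndarray:
    """Feature map used for prediction/CAM on one phantom sample: ``F_l`` when
    weighting is enabled (with the segmenter-derived mask), else ``F_g``."""
    f_g = extract_features(preprocess_image(sample.image), model)
    if not model.weighting_enabled:
        return f_g
    m = sample_feature_mask(model, sample.image)
    return feature_weighting(f_g, m)


def predict_proba(model: ChestXRayClassifier, samples,
                  mask_cache: dict | None = None) -> np.ndarray:
    """[N, c] disease probabilities for a list of phantom samples.

    ``mask_cache`` maps sample id to a precomputed feature-resolution mask;
    missing entries are computed with the attached segmenter (and cached).
    """
    model.eval()
    x = np.stack([preprocess_image(s.image) for s in samples])
    masks = None
    if model.weighting_enabled:
        masks = np.stack([_cached_mask(model, s, mask_cache) for s in samples])
    probs, _ = model.forward(x, masks)
    return probs


def _cached_mask(model: ChestXRayClassifier, sample, mask_cache: dict | None) -> np.ndarray:
    if mask_cache is not None and sample.sample_id in mask_cache:
        return mask_cache[sample.sample_id]
    m = sample_feature_mask(model, sample.image)
    if mask_cache is not None:
        mask_cache[sample.sample_id] = m
    return m


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class ClsTrainConfig:
    epochs: int = 10
    batch_size: int = 32
    lr: float = 1e-3
    weight_decay: float = 1e-4
    seed: int = 0
    backbone: str = "tiny"
    attention_enabled: bool = True
    weighting_enabled: bool = True
    scale_kernels: tuple = DEFAULT_SCALE_KERNELS
    fusion_kernel: int = DEFAULT_FUSION_KERNEL
    masked_mean: bool = False
    mask_threshold: float = 0.0


def _precompute(samples, segmenter, model: ChestXRayClassifier, weighting: bool,
                mask_cache: dict | None = None):
    x = np.stack([preprocess_image(s.image) for s in samples])
    y = np.stack([np.asarray(s.labels, dtype=np.float32) for s in samples])
    masks = None
    if weighting:
        masks = np.stack([_cached_mask(model, s, mask_cache) for s in samples])
    return x, y, masks


def train_classifier(train_samples, val_samples, segmenter: UNet | None,
                     config: ClsTrainConfig | None = None,
                     mask_cache: dict | None = None):
    """Train the multi-label classifier with BCE; the segmenter stays frozen
    and its masks are computed once per image and cached.

    The returned model carries the parameters of the epoch with the highest
    validation macro AUROC; the log records per-epoch train/val BCE and the
    validation AUROC.
    """
    from .metrics import macro_auroc
    if config is None:
        config = ClsTrainConfig()
    if len(train_samples) == 0 or len(val_samples) == 0:
        raise ValueError("empty train or validation split")
    if config.weighting_enabled and segmenter is None:
        raise ValueError("weighting enabled requires a trained segmenter")

    n_classes = len(train_samples[0].labels)
    model = ChestXRayClassifier(
        n_classes, backbone=config.backbone, seed=config.seed,
        attention_enabled=config.attention_enabled,
        weighting_enabled=config.weighting_enabled,
        scale_kernels=config.scale_kernels, fusion_kernel=config.fusion_kernel,
        masked_mean=config.masked_mean)
    model.segmenter = segmenter
    model.mask_threshold = config.mask_threshold

    x_tr, y_tr, m_tr = _precompute(train_samples, segmenter, model,
                                   config.weighting_enabled, mask_cache)
    x_va, y_va, m_va = _precompute(val_samples, segmenter, model,
                                   config.weighting_enabled, mask_cache)

    opt = nn.Adam(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed + 1)
    bs = config.batch_size

    def val_metrics():
        model.eval()
        probs = []
        for i in range(0, len(x_va), bs):
            mb = None if m_va is None else m_va[i:i + bs]
            probs.append(model.forward(x_va[i:i + bs], mb)[0])
        model.train()
        probs = np.concatenate(probs)
        return bce_loss(y_va, probs), macro_auroc(y_va, probs)

    log = []
    best = (-np.inf, None)
    for epoch in range(config.epochs):
        order = rng.permutation(len(x_tr))
        losses = []
        for i in range(0, len(order), bs):
            idx = order[i:i + bs]
            mb = None if m_tr is None else m_tr[idx]
            probs, logits = model.forward(x_tr[idx], mb)
            yb = y_tr[idx]
            losses.append(bce_loss(yb, probs) * len(idx))
            dlogits = (probs - yb) / (yb.shape[1] * len(idx))
            model.zero_grad()
            model.backward(dlogits.astype(np.float32))
            opt.step()
        vloss, vauc = val_metrics()
        log.append({"epoch": epoch, "train_loss": float(np.sum(losses) / len(x_tr)),
                    "val_loss": vloss, "val_auroc": vauc})
        if vauc is not None and vauc > best[0]:
            best = (vauc, model.get_state())
    if best[1] is not None:
        model.set_state(best[1])
    model.eval()
    return model, log
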