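"""Pixel-wise lung/heart segmentation with a U-Net trained under soft-dice loss.

The segmenter predicts three foreground-probability maps — left lung, right
lung, heart — from a radiograph.  Thresholding at 0.5 gives three binary
masks, and their pixel-wise union is the merged anatomy mask ``M_g`` used to
weight classifier features (pixels 1 inside lung/heart, 0 elsewhere).

Masks are exchanged on disk as 0/255 PNGs (foreground 255, background 0,
the common annotation convention for chest-radiograph delineations);
internally they are {0, 1} arrays.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import nn

STRUCTURES = ("left_lung", "right_lung", "heart")

#: smoothing added to numerator and denominator of the soft dice ratio so the
#: coefficient is defined (and equal to 1) when both masks are empty
DICE_SMOOTH = 1.0

MASK_THRESHOLD = 0.5


@dataclass
class StructureMaskSet:
    """Binary {0,1} masks for the three thoracic structures, all same shape."""

    left_lung: np.ndarray
    right_lung: np.ndarray
    heart: np.ndarray

    def __post_init__(self):
        shapes = {m.shape for m in self.arrays()}
        if len(shapes) != 1:
            raise ValueError(f"structure masks differ in shape: {shapes}")
        for name, m in zip(STRUCTURES, self.arrays()):
            vals = np.unique(m)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError(f"mask '{name}' has values outside {{0,1}}")

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.left_lung, self.right_lung, self.heart)

    def stack(self) -> np.ndarray:
        """[3, H, W] array in the canonical structure order."""
        return np.stack(self.arrays()).astype(np.float32)


@dataclass
class MergedMask:
    """Union of the three structure masks: [1, H, W], 1 inside lung/heart."""

    mask: np.ndarray

    def __post_init__(self):
        if self.mask.ndim != 3 or self.mask.shape[0] != 1:
            raise ValueError("merged mask must have shape [1, H, W]")
        if not np.all(np.isin(np.unique(self.mask), (0, 1))):
            raise ValueError("merged mask values must be 0 or 1")


@dataclass
class SoftMask:
    """Predicted per-structure foreground probability in [0, 1]."""

    prob: np.ndarray

    def __post_init__(self):
        if self.prob.min() < 0 or self.prob.max() > 1:
            raise ValueError("soft mask probabilities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Dice objective
# ---------------------------------------------------------------------------

def dice_coefficient(m_gt: np.ndarray, m_prob: np.ndarray, smooth: float = DICE_SMOOTH) -> float:
    """Soft dice overlap ``(2 sum(gt*p) + s) / (sum(gt) + sum(p) + s)``.

    Accepts binary or soft masks in [0, 1]; the soft intersection is the
    elementwise product, so for binary inputs this is the classic
    ``2|A∩B| / (|A| + |B|)`` up to the smoothing term.
    """
    m_gt = np.asarray(m_gt, dtype=np.float64)
    m_prob = np.asarray(m_prob, dtype=np.float64)
    if m_gt.shape != m_prob.shape:
        raise ValueError(f"shape mismatch {m_gt.shape} vs {m_prob.shape}")
    for name, m in (("m_gt", m_gt), ("m_prob", m_prob)):
        if m.min() < 0 or m.max() > 1:
            raise ValueError(f"{name} values must lie in [0, 1]")
    inter = float((m_gt * m_prob).sum())
    total = float(m_gt.sum() + m_prob.sum())
    return (2.0 * inter + smooth) / (total + smooth)


def dice_loss(m_gt: np.ndarray, m_prob: np.ndarray, smooth: float = DICE_SMOOTH) -> float:
    """``1 - dice``; for stacked [S, H, W] inputs, the unweighted mean over S."""
    m_gt = np.asarray(m_gt)
    m_prob = np.asarray(m_prob)
    if m_gt.shape != m_prob.shape:
        raise ValueError(f"shape mismatch {m_gt.shape} vs {m_prob.shape}")
    if m_gt.ndim == 2:
        return 1.0 - dice_coefficient(m_gt, m_prob, smooth)
    return float(np.mean([1.0 - dice_coefficient(g, p, smooth) for g, p in zip(m_gt, m_prob)]))


def merge_masks(masks: StructureMaskSet) -> MergedMask:
    """Pixel-wise sum of the three structure masks clipped to {0,1} (logical OR)."""
    total = sum(m.astype(np.int64) for m in masks.arrays())
    return MergedMask(np.clip(total, 0, 1)[None].astype(np.uint8))


# ---------------------------------------------------------------------------
# U-Net
# ---------------------------------------------------------------------------

class _DoubleConv(nn.Module):
    """Conv-BN-ReLU twice; batch normalisation makes the dice objective
    converge within a handful of epochs at desk scale."""

    def __init__(self, cin, cout, rng):
        self.block = nn.Sequential(
            nn.Conv2d(cin, cout, 3, rng=rng), nn.BatchNorm2d(cout), nn.ReLU(),
            nn.Conv2d(cout, cout, 3, rng=rng), nn.BatchNorm2d(cout), nn.ReLU(),
        )

    def forward(self, x):
        return self.block.forward(x)

    def backward(self, dy):
        return self.block.backward(dy)


class UNet(nn.Module):
    """Encoder-decoder segmenter with skip connections and a 3-channel
    sigmoid output (one foreground probability map per structure).

    ``depth`` counts resolution levels (encoder stages below the input level);
    feature width doubles per level starting at ``base_width``.
    """

    def __init__(self, in_channels: int = 3, out_channels: int = 3,
                 base_width: int = 64, depth: int = 4, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.depth = depth
        widths = [base_width * (2 ** i) for i in range(depth + 1)]
        self.enc = [_DoubleConv(in_channels if i == 0 else widths[i - 1], widths[i], rng)
                    for i in range(depth)]
        self.pools = [nn.AvgPool2d() for _ in range(depth)]
        self.bottleneck = _DoubleConv(widths[depth - 1], widths[depth], rng)
        self.ups = [nn.Upsample2x() for _ in range(depth)]
        self.up_convs = [nn.Conv2d(widths[i + 1], widths[i], 3, rng=rng) for i in reversed(range(depth))]
        self.dec = [_DoubleConv(widths[i] * 2, widths[i], rng) for i in reversed(range(depth))]
        self.head = nn.Conv2d(base_width, out_channels, 1, rng=rng)
        self.out_act = nn.Sigmoid()

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[2] % (2 ** self.depth) or x.shape[3] % (2 ** self.depth):
            raise ValueError(f"spatial size must be divisible by {2 ** self.depth}")
        skips = []
        for enc, pool in zip(self.enc, self.pools):
            x = enc.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._skip_channels = []
        for up, conv, dec, skip in zip(self.ups, self.up_convs, self.dec, reversed(skips)):
            x = conv.forward(up.forward(x))
            self._skip_channels.append(skip.shape[1])
            x = dec.forward(np.concatenate([skip, x], axis=1))
        return self.out_act.forward(self.head.forward(x))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.head.backward(self.out_act.backward(dy))
        dskips = []
        for up, conv, dec, cs in zip(reversed(self.ups), reversed(self.up_convs),
                                     reversed(self.dec), reversed(self._skip_channels)):
            dcat = dec.backward(dy)
            dskips.append(dcat[:, :cs])
            dy = up.backward(conv.backward(dcat[:, cs:]))
        dy = self.bottleneck.backward(dy)
        for enc, pool, dskip in zip(reversed(self.enc), reversed(self.pools), reversed(dskips)):
            dy = enc.backward(pool.backward(dy) + dskip)
        return dy


@dataclass
class SegTrainConfig:
    epochs: int = 16
    batch_size: int = 4
    lr: float = 5e-3
    weight_decay: float = 1e-4
    base_width: int = 64
    depth: int = 4
    seed: int = 0
    smooth: float = DICE_SMOOTH


def _batched_dice_backward(gt: np.ndarray, prob: np.ndarray, smooth: float) -> tuple[float, np.ndarray]:
    """Mean dice loss over [N, S, H, W] and its gradient w.r.t. ``prob``."""
    n, s = gt.shape[:2]
    inter = (gt * prob).sum(axis=(2, 3))
    total = gt.sum(axis=(2, 3)) + prob.sum(axis=(2, 3))
    dice = (2.0 * inter + smooth) / (total + smooth)
    loss = float((1.0 - dice).mean())
    # d dice / d p = (2*gt*(total+s) - (2*inter+s)) / (total+s)^2
    denom = (total + smooth)[:, :, None, None]
    ddice = (2.0 * gt * denom - (2.0 * inter + smooth)[:, :, None, None]) / (denom ** 2)
    dprob = -ddice / (n * s)
    return loss, dprob.astype(prob.dtype)


def train_segmenter(train_samples, val_samples, config: SegTrainConfig | None = None,
                    preprocess=None):
    """Train a U-Net on (image, StructureMaskSet) samples under dice loss.

    Returns ``(unet, log)`` where the network carries the parameters of the
    epoch with the smallest validation dice loss and ``log`` is a list of
    per-epoch ``{"epoch", "train_loss", "val_loss"}`` records.
    """
    if config is None:
        config = SegTrainConfig()
    if len(train_samples) == 0:
        raise ValueError("empty training set")
    from .classifier import preprocess_image  # shared normalisation pipeline
    prep = preprocess or preprocess_image

    x_tr = np.stack([prep(s.image) for s in train_samples])
    y_tr = np.stack([s.masks.stack() for s in train_samples])
    x_va = np.stack([prep(s.image) for s in val_samples]) if len(val_samples) else None
    y_va = np.stack([s.masks.stack() for s in val_samples]) if len(val_samples) else None

    net = UNet(base_width=config.base_width, depth=config.depth, seed=config.seed)
    opt = nn.Adam(net.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed + 1)

    def val_loss() -> float:
        if x_va is None:
            return np.nan
        net.eval()
        losses = []
        for i in range(0, len(x_va), config.batch_size):
            p = net.forward(x_va[i:i + config.batch_size])
            g = y_va[i:i + config.batch_size]
            losses.append(_batched_dice_backward(g, p, config.smooth)[0] * len(g))
        net.train()
        return float(np.sum(losses) / len(x_va))

    log = []
    best = (np.inf, copy.deepcopy(net.get_state()))
    v0 = val_loss()
    if v0 <= best[0]:
        best = (v0, net.get_state())
    for epoch in range(config.epochs):
        order = rng.permutation(len(x_tr))
        ep_losses = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            prob = net.forward(x_tr[idx])
            loss, dprob = _batched_dice_backward(y_tr[idx], prob, config.smooth)
            net.zero_grad()
            net.backward(dprob)
            opt.step()
            ep_losses.append(loss * len(idx))
        vl = val_loss()
        log.append({"epoch": epoch, "train_loss": float(np.sum(ep_losses) / len(x_tr)),
                    "val_loss": vl})
        if vl <= best[0]:
            best = (vl, net.get_state())
    net.set_state(best[1])
    net.eval()
    return net, log


def predict_soft(image: np.ndarray, segmenter: UNet, preprocess=None) -> np.ndarray:
    """[3, H, W] per-structure foreground probabilities for one image."""
    from .classifier import preprocess_image
    prep = preprocess or preprocess_image
    segmenter.eval()
    out = segmenter.forward(prep(np.asarray(image))[None])[0]
    return out


def predict_masks(image: np.ndarray, segmenter: UNet, threshold: float = MASK_THRESHOLD,
                  preprocess=None) -> StructureMaskSet:
    """Run the segmenter and binarise each structure probability at ``threshold``."""
    prob = predict_soft(image, segmenter, preprocess)
    binary = (prob > threshold).astype(np.uint8)
    return StructureMaskSet(left_lung=binary[0], right_lung=binary[1], heart=binary[2])
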