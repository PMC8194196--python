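"""Multi-scale spatial attention gate applied to the input radiograph.

The gate builds a three-branch feature hierarchy — the image itself plus one
3->3 convolution per scale kernel (defaults 5 and 9) — pools each branch to
its per-pixel channel maximum and mean, fuses the six pooled planes with a
single 6->1 convolution (kernel 7), and squashes through a sigmoid.  The
resulting ``[1, H, W]`` gate, with every value strictly inside (0, 1), is
multiplied element-wise into the image before the backbone, spatially
re-weighting the input at full resolution.  All convolutions use stride 1
with zero same-padding so the gate matches the image size exactly.
"""

from __future__ import annotations

import numpy as np

from . import nn

DEFAULT_SCALE_KERNELS = (5, 9)
DEFAULT_FUSION_KERNEL = 7


def channel_pool(feature: np.ndarray) -> np.ndarray:
    """Per-pixel channel maximum (plane 0) and mean (plane 1): [C,H,W] -> [2,H,W]."""
    feature = np.asarray(feature)
    if feature.ndim != 3 or feature.shape[0] < 1:
        raise ValueError("channel_pool expects a non-empty [C, H, W] array")
    return np.stack([feature.max(axis=0), feature.mean(axis=0)])


def apply_attention(image: np.ndarray, gate: np.ndarray) -> np.ndarray:
    """Element-wise product ``image[c] * gate[0]``, gate broadcast over channels."""
    image = np.asarray(image)
    gate = np.asarray(gate)
    if gate.ndim != 3 or gate.shape[0] != 1:
        raise ValueError("gate must have shape [1, H, W]")
    if image.shape[-2:] != gate.shape[-2:]:
        raise ValueError(f"spatial size mismatch: image {image.shape[-2:]} vs gate {gate.shape[-2:]}")
    return image * gate


class MultiScaleAttention(nn.Module):
    """Trainable attention gate; ``forward`` returns the gated image and
    caches everything the manual backward pass needs."""

    def __init__(self, scale_kernels=DEFAULT_SCALE_KERNELS,
                 fusion_kernel: int = DEFAULT_FUSION_KERNEL,
                 in_channels: int = 3, rng: np.random.Generator | None = None):
        for k in tuple(scale_kernels) + (fusion_kernel,):
            if k % 2 == 0:
                raise ValueError(f"attention kernels must be odd, got {k}")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.scale_kernels = tuple(scale_kernels)
        self.in_channels = in_channels
        self.scale_convs = [nn.Conv2d(in_channels, in_channels, k, rng=rng, pad_mode="reflect")
                            for k in self.scale_kernels]
        self.fuse = nn.Conv2d(2 * (len(self.scale_kernels) + 1), 1, fusion_kernel, rng=rng,
                              pad_mode="reflect")
        # start the gate near pass-through (sigmoid(2) ~ 0.88) so early
        # training is not disrupted by a random multiplicative gate
        self.fuse.bias.value[...] = 2.0
        self._cache = None

    @staticmethod
    def _as_batch(image: np.ndarray) -> np.ndarray:
        image = np.asarray(image)
        return image[None] if image.ndim == 3 else image

    def multiscale_features(self, image: np.ndarray) -> list[np.ndarray]:
        """Identity branch plus one learned convolution per scale kernel,
        each preserving the input shape."""
        x = self._as_batch(image)
        if min(x.shape[2:]) < max(self.scale_kernels):
            raise ValueError("image smaller than the largest scale kernel")
        branches = [x] + [conv.forward(x) for conv in self.scale_convs]
        if image.ndim == 3:
            return [b[0] for b in branches]
        return branches

    def attention_gate(self, image: np.ndarray) -> np.ndarray:
        """Gate for a single [3, H, W] image (or batch): sigmoid-fused pooled
        multi-scale hierarchy, shape [1, H, W] (batched: [N, 1, H, W])."""
        single = image.ndim == 3
        _, gate = self.forward(self._as_batch(image))
        return gate[0] if single else gate

    # -- training path ---------------------------------------------------
    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Returns ``(gated_image, gate)`` for a [N, 3, H, W] batch."""
        branches = [x] + [conv.forward(x) for conv in self.scale_convs]
        pooled = []
        argmaxes = []
        for b in branches:
            amax = b.argmax(axis=1)
            argmaxes.append(amax)
            pooled.append(np.take_along_axis(b, amax[:, None], axis=1)[:, 0])
            pooled.append(b.mean(axis=1))
        stack = np.stack(pooled, axis=1)
        z = self.fuse.forward(stack)
        gate = nn.sigmoid(z)
        out = x * gate
        self._cache = (x, branches, argmaxes, gate)
        return out, gate

    def backward(self, dout: np.ndarray, dgate_direct: np.ndarray | None = None,
                 need_input_grad: bool = False) -> np.ndarray | None:
        """Backprop through ``gated = x * gate``; ``dgate_direct`` allows an
        extra loss term on the gate itself.  The module sits directly on the
        input image, so the image gradient is only computed on request."""
        x, branches, argmaxes, gate = self._cache
        dgate = (dout * x).sum(axis=1, keepdims=True)
        if dgate_direct is not None:
            dgate = dgate + dgate_direct
        dx = dout * gate if need_input_grad else None
        dz = dgate * gate * (1.0 - gate)
        dstack = self.fuse.backward(dz)
        c = x.shape[1]
        for i, amax in enumerate(argmaxes):
            dmax, dmean = dstack[:, 2 * i], dstack[:, 2 * i + 1]
            dbranch = np.repeat(dmean[:, None] / c, c, axis=1)
            np.put_along_axis(dbranch, amax[:, None], np.take_along_axis(dbranch, amax[:, None], axis=1) + dmax[:, None], axis=1)
            if i == 0:
                if need_input_grad:
                    dx = dx + dbranch
            else:
                dconv = self.scale_convs[i - 1].backward(dbranch, need_input_grad=need_input_grad)
                if need_input_grad:
                    dx = dx + dconv
        return dx
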