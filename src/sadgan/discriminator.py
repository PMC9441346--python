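"""Realness discriminator: dilated-inception stages with dual attention.

Scores whether a segmentation map is an expert ground truth or a generator
output.  Pipeline: Conv3x3-BN-ReLU stem, then per stage a dilated-inception
block (three parallel 1x1-reduce -> 3x3 branches at dilation rates 1, 2, 4,
concatenated, fused by 1x1 conv and residual-added), a 1x1 Conv-BN-ReLU
channel adjustment and 2x2 average pooling; after the last stage a CBAM
attention module (channel attention, then spatial attention), global average
pooling, and a fully connected 2-way softmax head returning p(real).

Average pooling is used throughout the down-sampling path (it preserves
high-level semantic content better than max pooling for this real/fake
classification).  An optional fully convolutional spatial head replaces the
FC head with a 1x1 convolution producing a per-cell realness grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["DiscConfig", "DilatedInceptionBlock", "ChannelAttention",
           "SpatialAttention", "CBAM", "Discriminator"]


@dataclass
class DiscConfig:
    """Discriminator hyperparameters.

    stages: number of inception + downsampling stages (each halves H and W).
    dilation_rates is fixed at (1, 2, 4).  attn_reduction is the channel-
    attention MLP bottleneck ratio; spatial_kernel the (odd) spatial-attention
    convolution size.  spatial_head switches the scalar FC head to a fully
    convolutional per-cell realness grid.
    """

    stages: int = 4
    base_channels: int = 32
    dilation_rates: tuple[int, int, int] = (1, 2, 4)
    attn_reduction: int = 8
    spatial_kernel: int = 7
    spatial_head: bool = False
    seed: int = 0

    def validate(self) -> "DiscConfig":
        if self.dilation_rates != (1, 2, 4):
            raise ValueError("dilation_rates are fixed at (1, 2, 4)")
        if self.spatial_kernel % 2 == 0:
            raise ValueError("spatial_kernel must be odd")
        if self.stages < 1 or self.base_channels < 4:
            raise ValueError("need stages >= 1 and base_channels >= 4")
        top = self.base_channels * 2 ** (self.stages - 1)
        if top % self.attn_reduction:
            raise ValueError(f"attn_reduction {self.attn_reduction} must divide "
                             f"final width {top}")
        return self

    @property
    def widths(self) -> list[int]:
        return [self.base_channels * 2 ** i for i in range(self.stages)]


class DilatedInceptionBlock(nn.Module):
    """Multi-scale residual block: parallel dilated 3x3 branches.

    Each branch reduces channels C -> C/4 with a 1x1 conv then applies a 3x3
    conv at dilation 1, 2 or 4 with same-padding; branch outputs are
    concatenated, fused back to C by a 1x1 conv, added to the input and
    passed through ReLU (Inception-ResNet style, so gradients always have an
    identity path).
    """

    def __init__(self, channels: int, rates: tuple[int, int, int],
                 rng: np.random.Generator):
        super().__init__()
        mid = max(1, channels // 4)
        self.branches = nn.ModuleList([
            nn.Sequential(
                nn.Conv2d(channels, mid, 1, rng), nn.BatchNorm2d(mid), nn.ReLU(),
                nn.Conv2d(mid, mid, 3, rng, dilation=r), nn.BatchNorm2d(mid), nn.ReLU(),
            )
            for r in rates
        ])
        self.fuse = nn.Conv2d(3 * mid, channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        outs = [b(x) for b in self.branches]
        fused = self.fuse(nn.concat(outs, axis=1))
        return (x + fused).relu()


class ChannelAttention(nn.Module):
    """Channel gate: sigmoid( MLP(avgpool) + MLP(maxpool) ), shared MLP C->C/r->C."""

    def __init__(self, channels: int, r: int, rng: np.random.Generator):
        super().__init__()
        if channels % r:
            raise ValueError(f"attention reduction {r} must divide channel count {channels}")
        self.fc1 = nn.Linear(channels, channels // r, rng)
        self.fc2 = nn.Linear(channels // r, channels, rng)

    def _mlp(self, z: Tensor) -> Tensor:
        return self.fc2(self.fc1(z).relu())

    def channel_weights(self, x: Tensor) -> Tensor:
        avg = self._mlp(nn.global_avg_pool(x))
        mx = self._mlp(nn.global_max_pool(x))
        return (avg + mx).sigmoid()               # (N,C) in (0,1)

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[:2]
        return x * self.channel_weights(x).reshape((n, c, 1, 1))


class SpatialAttention(nn.Module):
    """Spatial gate: conv over stacked per-pixel channel mean and max, sigmoid."""

    def __init__(self, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("spatial attention kernel must be odd")
        self.conv = nn.Conv2d(2, 1, kernel, rng)

    def weight_map(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1)                      # (N,H,W)
        mx = x.max(axis=1)                        # (N,H,W)
        stacked = nn.stack_channels(avg, mx)      # (N,2,H,W)
        return self.conv(stacked).sigmoid()       # (N,1,H,W) in (0,1)

    def forward(self, x: Tensor) -> Tensor:
        return x * self.weight_map(x)


class CBAM(nn.Module):
    """Sequential channel-then-spatial attention; the order is fixed."""

    def __init__(self, channels: int, r: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.channel = ChannelAttention(channels, r, rng)
        self.spatial = SpatialAttention(kernel, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.spatial(self.channel(x))


class Discriminator(nn.Module):
    """Scores a segmentation map; returns p(real) in [0,1]."""

    def __init__(self, cfg: DiscConfig | None = None):
        super().__init__()
        self.cfg = (cfg or DiscConfig()).validate()
        rng = np.random.default_rng(self.cfg.seed)
        w = self.cfg.widths

        self.stem = nn.Sequential(nn.Conv2d(1, w[0], 3, rng),
                                  nn.BatchNorm2d(w[0]), nn.ReLU())
        self.inception = nn.ModuleList()
        self.adjust = nn.ModuleList()
        for i in range(self.cfg.stages):
            self.inception.append(DilatedInceptionBlock(w[i], self.cfg.dilation_rates, rng))
            nxt = w[i + 1] if i + 1 < len(w) else w[-1]
            self.adjust.append(nn.Sequential(nn.Conv2d(w[i], nxt, 1, rng),
                                             nn.BatchNorm2d(nxt), nn.ReLU()))
        self.cbam = CBAM(w[-1], self.cfg.attn_reduction, self.cfg.spatial_kernel, rng)
        if self.cfg.spatial_head:
            self.head = nn.Conv2d(w[-1], 2, 1, rng)
        else:
            self.head = nn.Linear(w[-1], 2, rng)

    def features(self, x: Tensor) -> Tensor:
        x = self.stem(x)
        for blk, adj in zip(self.inception, self.adjust):
            x = blk(x)
            x = adj(x)
            x = nn.avgpool2x2(x)
        return self.cbam(x)

    def forward(self, mask: Tensor) -> Tensor:
        """(N,1,H,W) map in [0,1] -> p(real).

        Scalar head: (N,) probabilities.  Spatial head: (N,h',w') per-cell
        probability grid.
        """
        n, c, h, w = mask.shape
        m = 2 ** self.cfg.stages
        if h % m or w % m:
            raise ValueError(f"input {h}x{w} not divisible by {m}; pad upstream")
        feats = self.features(mask)
        if self.cfg.spatial_head:
            probs = nn.softmax(self.head(feats), axis=1)   # (N,2,h',w')
            return probs[:, 1, :, :]
        z = nn.global_avg_pool(feats)                      # (N,C)
        probs = nn.softmax(self.head(z), axis=1)           # (N,2)
        return probs[:, 1]

    def score(self, mask: np.ndarray) -> float:
        """Inference-mode p(real) for a single H×W map in [0,1]."""
        was_training = self.training
        self.eval()
        try:
            with nn.no_grad():
                out = self.forward(Tensor(mask.astype(nn.DTYPE)[None, None]))
        finally:
            self.train(was_training)
        return float(out.data.mean())
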