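"""U-shaped segmentation generator with SE-ResNet blocks.

Encoder/decoder with four max-pooling and four upsampling levels, skip
connections concatenating each encoder level onto the matching decoder
level, and a final 1x1 convolution producing a 2-class per-pixel softmax.
Of the nine convolution blocks along the U-path, two are plain
Conv-BN-ReLU x2 blocks and seven are SE-ResNet blocks: a residual block
whose branch is reweighted per channel by a squeeze-and-excitation gate
(global average pool -> FC C->C/r -> ReLU -> FC C/r->C -> sigmoid), with
reduction ratio r = 2.  Which two slots are plain is configurable; the
default puts them at the first encoder block and the bottleneck.

Upsampling is bilinear 2x followed by a 3x3 convolution (avoids the
checkerboard artifacts of transposed convolution).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["GenConfig", "SEBlock", "SEResNetBlock", "PlainBlock", "Generator"]

_SLOTS = ("enc1", "enc2", "enc3", "enc4", "bottleneck", "dec4", "dec3", "dec2", "dec1")


@dataclass
class GenConfig:
    """Generator hyperparameters.

    base_channels: width of the first level; levels double up to the
    bottleneck (16-32-64-128-256 by default).  se_reduction is the SE
    bottleneck ratio r (r = 2); it must divide every level width.
    plain_blocks: which two of the nine U-path slots are plain Conv-BN-ReLU
    blocks instead of SE-ResNet blocks.
    """

    base_channels: int = 16
    depth: int = 4
    se_reduction: int = 2
    num_classes: int = 2
    plain_blocks: tuple[str, str] = ("enc1", "bottleneck")
    seed: int = 0

    def validate(self) -> "GenConfig":
        if self.depth != 4:
            raise ValueError("depth is fixed at 4 pooling levels")
        if self.num_classes != 2:
            raise ValueError("num_classes is fixed at 2 (vessel / background)")
        for name in self.plain_blocks:
            if name not in _SLOTS:
                raise ValueError(f"unknown block slot {name!r}; valid: {_SLOTS}")
        if len(set(self.plain_blocks)) != 2:
            raise ValueError("exactly two plain block slots required")
        widths = [self.base_channels * 2 ** i for i in range(self.depth + 1)]
        for w in widths:
            if w % self.se_reduction:
                raise ValueError(f"se_reduction {self.se_reduction} must divide width {w}")
        return self

    @property
    def widths(self) -> list[int]:
        return [self.base_channels * 2 ** i for i in range(self.depth + 1)]


class SEBlock(nn.Module):
    """Squeeze-and-excitation channel gate.

    GAP -> FC(C -> C/r) -> ReLU -> FC(C/r -> C) -> sigmoid, then each channel
    is scaled by its weight in (0,1).
    """

    def __init__(self, channels: int, r: int, rng: np.random.Generator):
        super().__init__()
        if channels % r:
            raise ValueError(f"SE reduction {r} must divide channel count {channels}")
        self.fc1 = nn.Linear(channels, channels // r, rng)
        self.fc2 = nn.Linear(channels // r, channels, rng)

    def channel_weights(self, x: Tensor) -> Tensor:
        z = nn.global_avg_pool(x)              # (N,C)
        z = self.fc1(z).relu()
        return self.fc2(z).sigmoid()           # (N,C) in (0,1)

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[:2]
        w = self.channel_weights(x).reshape((n, c, 1, 1))
        return x * w


class PlainBlock(nn.Module):
    """Two Conv3x3-BN-ReLU layers (the classic U-Net convolution block)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.body = nn.Sequential(
            nn.Conv2d(in_ch, out_ch, 3, rng), nn.BatchNorm2d(out_ch), nn.ReLU(),
            nn.Conv2d(out_ch, out_ch, 3, rng), nn.BatchNorm2d(out_ch), nn.ReLU(),
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.body(x)


class SEResNetBlock(nn.Module):
    """Residual block with an SE gate on the residual branch.

    out = ReLU( shortcut(x) + SE( BN(Conv3x3( ReLU(BN(Conv3x3 x)) )) ) );
    the shortcut is a 1x1 conv + BN when input and output widths differ.
    """

    def __init__(self, in_ch: int, out_ch: int, r: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, rng)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, rng)
        self.bn2 = nn.BatchNorm2d(out_ch)
        self.se = SEBlock(out_ch, r, rng)
        if in_ch != out_ch:
            self.proj = nn.Sequential(nn.Conv2d(in_ch, out_ch, 1, rng, bias=False),
                                      nn.BatchNorm2d(out_ch))
        else:
            self.proj = None

    def forward(self, x: Tensor) -> Tensor:
        branch = self.bn1(self.conv1(x)).relu()
        branch = self.se(self.bn2(self.conv2(branch)))
        shortcut = self.proj(x) if self.proj is not None else x
        return (shortcut + branch).relu()


class _UpBlock(nn.Module):
    """Bilinear 2x upsampling followed by a width-halving 3x3 conv."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch, 3, rng)
        self.bn = nn.BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(nn.upsample2x_bilinear(x))).relu()


def _make_block(slot: str, in_ch: int, out_ch: int, cfg: GenConfig,
                rng: np.random.Generator) -> nn.Module:
    if slot in cfg.plain_blocks:
        return PlainBlock(in_ch, out_ch, rng)
    return SEResNetBlock(in_ch, out_ch, cfg.se_reduction, rng)


class Generator(nn.Module):
    """Maps a preprocessed grayscale image to a 2-class probability map."""

    def __init__(self, cfg: GenConfig | None = None):
        super().__init__()
        self.cfg = (cfg or GenConfig()).validate()
        rng = np.random.default_rng(self.cfg.seed)
        w = self.cfg.widths                       # e.g. [16,32,64,128,256]

        self.enc = nn.ModuleList([
            _make_block(f"enc{i + 1}", 1 if i == 0 else w[i - 1], w[i], self.cfg, rng)
            for i in range(4)
        ])
        self.bottleneck = _make_block("bottleneck", w[3], w[4], self.cfg, rng)
        self.up = nn.ModuleList([_UpBlock(w[i + 1], w[i], rng) for i in (3, 2, 1, 0)])
        self.dec = nn.ModuleList([
            _make_block(f"dec{lvl + 1}", 2 * w[lvl], w[lvl], self.cfg, rng)
            for lvl in (3, 2, 1, 0)
        ])
        self.head = nn.Conv2d(w[0], self.cfg.num_classes, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        """(N,1,H,W) -> per-pixel class probabilities (N,2,H,W).

        H and W must be divisible by 2**depth (pad upstream with
        ``pad_to_multiple``).
        """
        n, c, h, wd = x.shape
        m = 2 ** self.cfg.depth
        if h % m or wd % m:
            raise ValueError(f"input {h}x{wd} not divisible by {m}; pad upstream")
        skips = []
        for block in self.enc:
            x = block(x)
            skips.append(x)
            x = nn.maxpool2x2(x)
        x = self.bottleneck(x)
        for up, dec, skip in zip(self.up, self.dec, reversed(skips)):
            x = up(x)
            x = dec(nn.concat([x, skip], axis=1))
        logits = self.head(x)
        return nn.softmax(logits, axis=1)

    # -------------------------------------------------------------- inference
    def predict_proba(self, img: np.ndarray) -> np.ndarray:
        """[0,1] H×W image -> H×W×2 probability map (inference mode)."""
        from .preprocess import pad_to_multiple, crop_back

        if img.ndim != 2:
            raise ValueError("predict_proba expects a single H×W image")
        padded, crop = pad_to_multiple(img.astype(nn.DTYPE), 2 ** self.cfg.depth)
        was_training = self.training
        self.eval()
        try:
            with nn.no_grad():
                out = self.forward(Tensor(padded[None, None]))
        finally:
            self.train(was_training)
        prob = out.data[0].transpose(1, 2, 0)     # H×W×2
        return crop_back(prob, crop)
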