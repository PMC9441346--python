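"""Fundus preprocessing: green channel, normalization, CLAHE, gamma,
augmentation and the train/validation split.

The enhancement chain reflects standard practice for DRIVE-style vessel
segmentation: vessels have their highest contrast in the green channel; the
channel is standardized and rescaled to [0,1]; contrast-limited adaptive
histogram equalization sharpens the vessel/background separation; a gamma
transform brightens the dark periphery.  Augmentation applies one random
rotation and/or mirror flip jointly to image and masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import exposure, transform

from .data import RetinalSample

__all__ = ["PreprocConfig", "extract_green_channel", "normalize", "apply_clahe",
           "gamma_transform", "preprocess_image", "augment", "split_train_val",
           "pad_to_multiple", "crop_back"]


@dataclass
class PreprocConfig:
    """Parameters of the preprocessing chain.

    clahe_clip_limit follows scikit-image's normalized convention (fraction
    in (0,1]; higher = more contrast).  gamma < 1 brightens dark regions.
    """

    clahe_clip_limit: float = 0.01
    clahe_tile_grid: tuple[int, int] = (8, 8)
    gamma: float = 1.2
    rotation_degrees_max: float = 180.0
    flip_probability: float = 0.5
    val_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> "PreprocConfig":
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must lie in (0,1)")
        if not 0 <= self.rotation_degrees_max <= 180:
            raise ValueError("rotation_degrees_max must lie in [0,180]")
        if self.clahe_clip_limit <= 0:
            raise ValueError("clahe_clip_limit must be positive")
        return self


def extract_green_channel(sample: RetinalSample) -> np.ndarray:
    """Green channel scaled to [0,1] — the highest vessel/background contrast
    of the three RGB channels."""
    if sample.image.ndim != 3 or sample.image.shape[2] != 3:
        raise ValueError(f"expected a 3-channel image, got shape {sample.image.shape}")
    return sample.image[..., 1].astype(np.float64) / 255.0


def normalize(img: np.ndarray) -> np.ndarray:
    """Per-image standardization followed by min-max rescale into [0,1].

    A constant image (zero variance) maps to all zeros.
    """
    if img.size == 0:
        raise ValueError("empty image")
    std = img.std()
    if std == 0:
        return np.zeros_like(img, dtype=np.float64)
    z = (img - img.mean()) / std
    return (z - z.min()) / (z.max() - z.min())


def apply_clahe(img: np.ndarray, cfg: PreprocConfig) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on a [0,1] image."""
    th, tw = cfg.clahe_tile_grid
    h, w = img.shape
    if th > h or tw > w:
        raise ValueError(f"CLAHE tile grid {cfg.clahe_tile_grid} exceeds image {h}x{w}")
    if img.max() == img.min():
        return img.copy()
    kernel = (max(1, h // th), max(1, w // tw))
    out = exposure.equalize_adapthist(np.clip(img, 0, 1), kernel_size=kernel,
                                      clip_limit=cfg.clahe_clip_limit)
    return np.clip(out, 0.0, 1.0)


def gamma_transform(img: np.ndarray, gamma: float) -> np.ndarray:
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return np.clip(img, 0.0, 1.0) ** gamma


def preprocess_image(sample: RetinalSample, cfg: PreprocConfig | None = None) -> np.ndarray:
    """Full chain: green channel -> normalize -> CLAHE -> gamma. Returns [0,1] H×W."""
    cfg = (cfg or PreprocConfig()).validate()
    g = extract_green_channel(sample)
    g = normalize(g)
    g = apply_clahe(g, cfg)
    return gamma_transform(g, cfg.gamma)


def _rebinarize(mask: np.ndarray) -> np.ndarray:
    return (mask > 0.5).astype(np.uint8)


def augment(sample: RetinalSample, cfg: PreprocConfig, rng: np.random.Generator
            ) -> RetinalSample:
    """One random rotation and mirror flip applied jointly to image and masks.

    The image is warped bilinearly; masks use nearest-neighbor warping and
    are re-binarized, so ground truth stays exactly binary.  Deterministic
    given the generator state.
    """
    angle = float(rng.uniform(-cfg.rotation_degrees_max, cfg.rotation_degrees_max))
    do_flip = bool(rng.random() < cfg.flip_probability)

    img = sample.image.astype(np.float64) / 255.0
    vm = sample.vessel_mask.astype(np.float64)
    fm = sample.fov_mask.astype(np.float64)
    if angle != 0.0:
        img = transform.rotate(img, angle, order=1, mode="constant", cval=0.0)
        vm = transform.rotate(vm, angle, order=0, mode="constant", cval=0.0)
        fm = transform.rotate(fm, angle, order=0, mode="constant", cval=0.0)
    if do_flip:
        img, vm, fm = img[:, ::-1], vm[:, ::-1], fm[:, ::-1]
    return RetinalSample(
        image=np.clip(np.rint(img * 255), 0, 255).astype(np.uint8),
        vessel_mask=_rebinarize(vm),
        fov_mask=_rebinarize(fm),
        sample_id=sample.sample_id,
    )


def split_train_val(samples: list[RetinalSample], cfg: PreprocConfig
                    ) -> tuple[list[RetinalSample], list[RetinalSample]]:
    """Random whole-image partition; |val| = round(val_fraction * N).

    Deterministic under cfg.seed; train and val are disjoint and cover the
    input.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to split")
    cfg.validate()
    n = len(samples)
    n_val = int(np.floor(cfg.val_fraction * n + 0.5))  # round-half-up
    n_val = min(n_val, n - 1)
    order = np.random.default_rng(cfg.seed).permutation(n)
    val_idx = set(order[:n_val].tolist())
    train = [samples[i] for i in range(n) if i not in val_idx]
    val = [samples[i] for i in range(n) if i in val_idx]
    return train, val


def pad_to_multiple(img: np.ndarray, m: int) -> tuple[np.ndarray, tuple[slice, slice]]:
    """Reflect-pad H and W up to the next multiple of ``m``.

    Returns the padded image and the slice pair that exactly recovers the
    original region (``crop_back``).  Padding is split evenly between the two
    sides, the odd pixel going to the bottom/right.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    h, w = img.shape[:2]
    ph = (-h) % m
    pw = (-w) % m
    top, left = ph // 2, pw // 2
    pad = [(top, ph - top), (left, pw - left)] + [(0, 0)] * (img.ndim - 2)
    out = np.pad(img, pad, mode="reflect") if (ph or pw) else img.copy()
    return out, (slice(top, top + h), slice(left, left + w))


def crop_back(img: np.ndarray, crop: tuple[slice, slice]) -> np.ndarray:
    return img[crop[0], crop[1]]
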