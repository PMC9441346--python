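"""Synthetic fundus phantoms: branching dark vessels on a textured disc.

Each phantom mimics the structure the segmentation task assumes: a bright
circular field of view (FOV) on a dark border, recursive bifurcating vessel
trees whose caliber shrinks with branching depth, vessels darker than the
background in the green channel, a smooth radial illumination gradient and
Gaussian pixel noise.  The vessel mask is rasterized hard (no anti-aliasing)
so ground truth is exactly binary; the rendered image uses a slightly blurred
vessel profile so edges look photographic.

Phantoms exercise every code path of the pipeline without the public retinal
datasets; they make no claim of physiological realism (no calibrated
tortuosity or caliber statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .data import RetinalSample, save_dataset

__all__ = ["PhantomSpec", "generate_phantom", "generate_dataset"]


@dataclass
class PhantomSpec:
    """Parameters of the procedural phantom generator."""

    height: int = 128
    width: int = 128
    n_trees: int = 3
    branch_depth: int = 4
    root_width_px: float = 3.0
    width_decay: float = 0.8
    branch_angle_sigma_deg: float = 10.0
    vessel_contrast: float = 0.35
    background_level: float = 0.55
    noise_sigma: float = 0.03
    fov_margin_frac: float = 0.05
    seed: int = 0

    def validate(self) -> "PhantomSpec":
        if self.height <= 0 or self.width <= 0:
            raise ValueError("height and width must be positive")
        if self.n_trees < 0 or self.branch_depth <= 0:
            raise ValueError("n_trees must be >= 0 and branch_depth >= 1")
        if not 0 < self.width_decay < 1:
            raise ValueError("width_decay must lie in (0,1)")
        if not 0 < self.vessel_contrast < 1 or not 0 < self.background_level < 1:
            raise ValueError("vessel_contrast and background_level must lie in (0,1)")
        if not 0 <= self.fov_margin_frac < 0.3:
            raise ValueError("fov_margin_frac must lie in [0,0.3)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        return self


def _fov_disc(spec: PhantomSpec) -> tuple[np.ndarray, tuple[float, float], float]:
    h, w = spec.height, spec.width
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    radius = min(h, w) / 2.0 * (1.0 - spec.fov_margin_frac)
    yy, xx = np.mgrid[0:h, 0:w]
    fov = ((yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2).astype(np.uint8)
    return fov, (cy, cx), radius


def _stamp_segment(mask: np.ndarray, fov: np.ndarray, p0: np.ndarray, p1: np.ndarray,
                   width: float) -> np.ndarray | None:
    """Rasterize a thick segment by stamping discs along it, stopping at the
    FOV boundary.  Returns the last point inside the FOV, or None if the
    segment immediately left it (the branch is then pruned, which keeps every
    tree's raster 8-connected)."""
    h, w = mask.shape
    length = float(np.hypot(*(p1 - p0)))
    n_steps = max(2, int(np.ceil(length * 2)))
    r = max(0.5, width / 2.0)
    ri = int(np.ceil(r))
    last_inside = None
    for t in np.linspace(0.0, 1.0, n_steps):
        p = p0 + t * (p1 - p0)
        y, x = int(round(p[0])), int(round(p[1]))
        if y < 0 or y >= h or x < 0 or x >= w or not fov[y, x]:
            break
        y0, y1 = max(0, y - ri), min(h, y + ri + 1)
        x0, x1 = max(0, x - ri), min(w, x + ri + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        disc = (yy - p[0]) ** 2 + (xx - p[1]) ** 2 <= r ** 2
        mask[y0:y1, x0:x1] |= disc.astype(np.uint8)
        last_inside = p
    return last_inside


def _grow_tree(mask: np.ndarray, fov: np.ndarray, origin: np.ndarray,
               direction: float, spec: PhantomSpec, rng: np.random.Generator,
               level: int = 0):
    if level >= spec.branch_depth:
        return
    seg_len = 0.30 * min(spec.height, spec.width) * (0.72 ** level)
    width = spec.root_width_px * (spec.width_decay ** level)
    end = origin + seg_len * np.array([np.sin(direction), np.cos(direction)])
    tip = _stamp_segment(mask, fov, origin, end, width)
    if tip is None:
        return
    # bifurcate: children deviate by roughly +/-25 degrees around the parent
    for sign in (-1.0, 1.0):
        dtheta = np.deg2rad(sign * 25.0 + rng.normal(0.0, spec.branch_angle_sigma_deg))
        _grow_tree(mask, fov, tip, direction + dtheta, spec, rng, level + 1)


def generate_phantom(spec: PhantomSpec) -> RetinalSample:
    """One synthetic sample, bit-deterministic under spec.seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    fov, (cy, cx), radius = _fov_disc(spec)

    vessel = np.zeros((h, w), dtype=np.uint8)
    for _ in range(spec.n_trees):
        # root near the disc edge, heading inward
        theta = rng.uniform(0, 2 * np.pi)
        origin = np.array([cy + 0.8 * radius * np.sin(theta),
                           cx + 0.8 * radius * np.cos(theta)])
        inward = np.arctan2(cy - origin[0], cx - origin[1])
        direction = inward + rng.normal(0.0, np.deg2rad(20.0))
        _grow_tree(vessel, fov, origin, direction, spec, rng)
    vessel &= fov

    # render: radial illumination falloff, soft vessel profile, noise
    yy, xx = np.mgrid[0:h, 0:w]
    rr = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2) / max(radius, 1.0)
    illum = 1.0 - 0.15 * rr ** 2
    soft = np.clip(gaussian_filter(vessel.astype(np.float64), 0.7) * 1.4, 0, 1)
    g = spec.background_level * illum - spec.vessel_contrast * soft
    g = g + rng.normal(0.0, spec.noise_sigma, size=(h, w))
    g = np.clip(g, 0.0, 1.0) * fov

    # red/blue channels: dimmer copies, as in fundus photographs
    img = np.stack([np.clip(g * 1.25, 0, 1), g, g * 0.45], axis=-1)
    img = np.clip(np.rint(img * 255), 0, 255).astype(np.uint8)

    return RetinalSample(image=img, vessel_mask=vessel, fov_mask=fov,
                         sample_id=f"phantom_{spec.seed:06d}").validate()


def generate_dataset(spec: PhantomSpec, n: int, seed: int,
                     out_dir: str | Path | None = None) -> list[RetinalSample]:
    """n phantoms with per-sample seeds derived from ``seed``.

    When ``out_dir`` is given the samples are also written in the on-disk
    layout the dataset loader reads (images/, labels/, masks/ PNG files).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]
    samples = [generate_phantom(replace(spec, seed=s)) for s in child_seeds]
    for i, s in enumerate(samples):
        s.sample_id = f"phantom_{i:03d}"
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        for sub in ("images", "labels", "masks"):
            (Path(out_dir) / sub).mkdir(exist_ok=True)
        save_dataset(samples, out_dir)
    return samples
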