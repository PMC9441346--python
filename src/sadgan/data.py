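"""Retinal sample container and on-disk dataset I/O.

A dataset directory holds three parallel folders::

    <root>/images/   fundus photographs (TIFF/PNG/JPEG, RGB)
    <root>/labels/   expert vessel ground truth (GIF/PNG, binary)
    <root>/masks/    field-of-view masks (GIF/PNG, binary)

paired by shared filename stem — the layout of the public DRIVE and
CHASE_DB1 releases.  When the root instead contains ``train/`` and ``test/``
subdirectories with that structure, each split is loaded separately and the
official split is honored instead of a random one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["RetinalSample", "load_dataset", "load_split_dataset", "save_dataset"]

IMAGE_EXTS = (".png", ".tif", ".tiff", ".jpg", ".jpeg", ".gif", ".ppm", ".bmp")


@dataclass
class RetinalSample:
    """One fundus image with its vessel ground truth and FOV mask.

    image: (H,W,3) uint8; vessel_mask / fov_mask: (H,W) in {0,1}.
    """

    image: np.ndarray
    vessel_mask: np.ndarray
    fov_mask: np.ndarray
    sample_id: str

    def validate(self) -> "RetinalSample":
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError(f"{self.sample_id}: image must be HxWx3, got {self.image.shape}")
        h, w = self.image.shape[:2]
        for name, m in (("vessel_mask", self.vessel_mask), ("fov_mask", self.fov_mask)):
            if m.shape != (h, w):
                raise ValueError(f"{self.sample_id}: {name} shape {m.shape} != image {h}x{w}")
            vals = np.unique(m)
            if not np.all(np.isin(vals, [0, 1])):
                raise ValueError(f"{self.sample_id}: {name} must be binary, found values {vals[:5]}")
        return self


def _read_binary(path: Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr > (arr.max() / 2 if arr.max() > 1 else 0)).astype(np.uint8)


def _read_rgb(path: Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[..., :3]
    return arr.astype(np.uint8)


def _index_by_stem(folder: Path) -> dict[str, Path]:
    out: dict[str, Path] = {}
    for p in sorted(folder.iterdir()):
        if p.suffix.lower() in IMAGE_EXTS:
            out[p.stem] = p
    return out


def load_dataset(root: str | Path, label_suffix: str | None = None) -> list[RetinalSample]:
    """Load all samples under ``root``.

    ``label_suffix`` selects among multiple annotation files per image (e.g.
    the two CHASE_DB1 observers, stems like ``Image_01L_1stHO``): a label is
    paired with an image when its stem starts with the image stem, and among
    candidates the one ending in ``label_suffix`` is preferred.
    """
    root = Path(root)
    img_dir, lbl_dir, msk_dir = root / "images", root / "labels", root / "masks"
    for d in (img_dir, lbl_dir, msk_dir):
        if not d.is_dir():
            raise FileNotFoundError(f"expected directory {d}")
    images = _index_by_stem(img_dir)
    labels = _index_by_stem(lbl_dir)
    masks = _index_by_stem(msk_dir)
    if not images:
        raise ValueError(f"no images found under {img_dir}")

    def match(stem: str, pool: dict[str, Path], what: str) -> Path:
        if stem in pool:
            return pool[stem]
        cands = [s for s in pool if s.startswith(stem) or stem.startswith(s)]
        if label_suffix:
            pref = [s for s in cands if s.endswith(label_suffix)]
            cands = pref or cands
        if not cands:
            raise FileNotFoundError(f"no {what} file pairs with image {stem!r}")
        return pool[sorted(cands)[0]]

    samples = []
    for stem, ipath in images.items():
        samples.append(RetinalSample(
            image=_read_rgb(ipath),
            vessel_mask=_read_binary(match(stem, labels, "label")),
            fov_mask=_read_binary(match(stem, masks, "FOV mask")),
            sample_id=stem,
        ).validate())
    return samples


def load_split_dataset(root: str | Path, label_suffix: str | None = None
                       ) -> tuple[list[RetinalSample], list[RetinalSample] | None]:
    """Return (train, test) honoring an explicit train/test layout if present."""
    root = Path(root)
    if (root / "train").is_dir():
        train = load_dataset(root / "train", label_suffix)
        test = load_dataset(root / "test", label_suffix) if (root / "test").is_dir() else None
        return train, test
    return load_dataset(root, label_suffix), None


def save_dataset(samples: list[RetinalSample], root: str | Path) -> Path:
    """Write samples in the loader layout (PNG throughout)."""
    root = Path(root)
    for sub in ("images", "labels", "masks"):
        (root / sub).mkdir(parents=True, exist_ok=True)
    for s in samples:
        iio.imwrite(root / "images" / f"{s.sample_id}.png", s.image)
        iio.imwrite(root / "labels" / f"{s.sample_id}.png",
                    (s.vessel_mask * 255).astype(np.uint8))
        iio.imwrite(root / "masks" / f"{s.sample_id}.png",
                    (s.fov_mask * 255).astype(np.uint8))
    return root
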