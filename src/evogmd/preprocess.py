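"""Dermoscopic image loading and ROI preprocessing.

Every downstream computation consumes the grayscale region-of-interest crop
of a lesion: the RGB dermoscopy image is converted to luminance, the image and
its binary segmentation mask are rescaled to a common working resolution
(720x480 by default, matching the PH2 protocol), pixels outside the mask are
zeroed, and the result is cropped to the tight bounding box of the mask.  The
bounding-box dimensions become the M x N extent over which the Gabor response
statistics are averaged — the zeroed background pixels inside the box
participate in those averages.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize

__all__ = [
    "BT601_WEIGHTS",
    "DEFAULT_TARGET_SIZE",
    "MASK_THRESHOLD",
    "LabeledSample",
    "to_grayscale",
    "rescale_image",
    "rescale_mask",
    "apply_mask_and_crop",
    "preprocess_pair",
    "load_dataset",
]

#: ITU-R BT.601 luminance weights for R, G, B
BT601_WEIGHTS = (0.299, 0.587, 0.114)

#: working resolution (width, height) used by the PH2 protocol
DEFAULT_TARGET_SIZE = (720, 480)

#: binarisation threshold applied to interpolated masks
MASK_THRESHOLD = 0.5


@dataclass(frozen=True)
class LabeledSample:
    """A preprocessed ROI crop paired with its class label.

    label 0 is the benign class (common nevus), 1 is melanoma.
    """

    id: str
    image: np.ndarray
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


def to_grayscale(img: np.ndarray, weights: tuple[float, float, float] = BT601_WEIGHTS) -> np.ndarray:
    """Convert an H x W x 3 RGB array to luminance; 2-D input passes through."""
    img = np.asarray(img, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if img.ndim == 2:
        return img
    if img.ndim != 3 or img.shape[2] not in (3, 4):
        raise ValueError(f"expected H x W x 3 RGB array, got shape {img.shape}")
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    wr, wg, wb = weights
    return wr * r + wg * g + wb * b


def rescale_image(img: np.ndarray, target_size: tuple[int, int] = DEFAULT_TARGET_SIZE) -> np.ndarray:
    """Bilinear resize of a grayscale image to (width, height) ``target_size``."""
    img = np.asarray(img, dtype=float)
    width, height = target_size
    if width < 1 or height < 1:
        raise ValueError(f"target size must be positive, got {target_size}")
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a nonempty 2-D grayscale array")
    if img.shape == (height, width):
        return img.copy()
    return resize(
        img,
        (height, width),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )


def rescale_mask(mask: np.ndarray, target_size: tuple[int, int] = DEFAULT_TARGET_SIZE,
                 threshold: float = MASK_THRESHOLD) -> np.ndarray:
    """Resize a binary mask; re-threshold after interpolation so it stays 0/1."""
    mask = np.asarray(mask, dtype=float)
    interp = rescale_image(mask, target_size)
    return (interp >= threshold).astype(np.uint8)


def apply_mask_and_crop(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero pixels outside the mask, then crop to the mask's bounding box."""
    img = np.asarray(img, dtype=float)
    mask = np.asarray(mask)
    if img.shape != mask.shape:
        raise ValueError(f"image {img.shape} and mask {mask.shape} dimensions differ")
    support = mask != 0
    if not support.any():
        raise ValueError("no lesion region: mask is all zero")
    rows = np.flatnonzero(support.any(axis=1))
    cols = np.flatnonzero(support.any(axis=0))
    masked = np.where(support, img, 0.0)
    return masked[rows[0]: rows[-1] + 1, cols[0]: cols[-1] + 1]


def preprocess_pair(img: np.ndarray, mask: np.ndarray,
                    target_size: tuple[int, int] | None = DEFAULT_TARGET_SIZE) -> np.ndarray:
    """Full pipeline for one image/mask pair: grayscale -> rescale -> mask+crop.

    ``target_size=None`` skips rescaling (useful when images are generated at
    the working resolution already).
    """
    gray = to_grayscale(img)
    mask = np.asarray(mask)
    if mask.ndim == 3:
        mask = to_grayscale(mask)
    # mask files may be stored as 0/1 or 0/255; any nonzero pixel is lesion
    mask = (np.asarray(mask, dtype=float) != 0).astype(np.uint8)
    if target_size is not None:
        gray = rescale_image(gray, target_size)
        mask = rescale_mask(mask, target_size)
    elif gray.shape != mask.shape:
        raise ValueError(f"image {gray.shape} and mask {mask.shape} dimensions differ")
    return apply_mask_and_crop(gray, mask)


def _read_image(path: Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im)


def load_dataset(root: str | Path, labels_csv: str | Path,
                 target_size: tuple[int, int] | None = DEFAULT_TARGET_SIZE) -> list[LabeledSample]:
    """Load a labelled image/mask directory into preprocessed samples.

    ``labels_csv`` has columns id, image_path, mask_path, label with paths
    relative to ``root``.  Samples are returned sorted by id so two loads of
    the same directory are bit-identical.
    """
    root = Path(root)
    table = pd.read_csv(labels_csv, dtype={"id": str})
    required = {"id", "image_path", "mask_path", "label"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"labels table missing columns: {sorted(missing)}")
    samples: list[LabeledSample] = []
    for row in table.sort_values("id").itertuples(index=False):
        label = int(row.label)
        if label not in (0, 1):
            raise ValueError(f"sample {row.id}: label must be 0 or 1, got {row.label}")
        img_path = root / row.image_path
        mask_path = root / row.mask_path
        for p in (img_path, mask_path):
            if not p.exists():
                raise FileNotFoundError(f"sample {row.id}: missing file {p}")
        img = _read_image(img_path)
        mask = _read_image(mask_path)
        if img.shape[:2] != mask.shape[:2] and target_size is None:
            raise ValueError(
                f"sample {row.id}: image {img.shape[:2]} and mask {mask.shape[:2]} differ"
            )
        crop = preprocess_pair(img, mask, target_size=target_size)
        samples.append(LabeledSample(id=str(row.id), image=crop, label=label))
    return samples
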