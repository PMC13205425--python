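"""Two-class directional-texture benchmark with elliptical lesion masks.

The generator emulates the premise behind directional lesion-texture
descriptors: malignant lesions show directionally organised, heterogeneous
texture while benign lesions are more uniform and isotropic.  Class 0 images
carry a sinusoidal grating at one dominant orientation; class 1 images carry a
grating at a second orientation plus, scaled by ``heterogeneity``, a third
superposed orientation emulating directional disorganisation.  Both classes
share the same base intensity and amplitude, so class separation lives in
orientation and heterogeneity, never in the mean intensity — a classifier has
to use genuinely directional features to succeed.

Each sample gets an elliptical "lesion" mask with randomised centre and
semi-axes, pixel values are quantised to 8-bit (so a written PNG round-trips
exactly), and the dataset is split 80/20 with per-class stratification.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .preprocess import LabeledSample, apply_mask_and_crop

__all__ = [
    "SyntheticConfig",
    "SyntheticSample",
    "generate_sample",
    "generate_dataset",
    "write_dataset",
    "to_labeled",
]


@dataclass(frozen=True)
class SyntheticConfig:
    n_per_class: int = 20
    image_size: tuple[int, int] = (64, 64)     # (H, W)
    class0_orientation: float = 0.0            # radians, in [0, pi)
    class1_orientation: float = math.pi / 2
    wavelength: float = 6.0                    # pixels per cycle
    heterogeneity: float = 0.5                 # weight of class-1 second grating
    noise_sd: float = 5.0                      # additive Gaussian noise, 8-bit units
    base_intensity: float = 128.0
    amplitude: float = 50.0                    # grating amplitude, 8-bit units
    mask_semi_axis_range: tuple[float, float] = (0.55, 0.85)  # fraction of H/2, W/2
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        for name in ("class0_orientation", "class1_orientation"):
            v = getattr(self, name)
            if not 0.0 <= v < math.pi:
                raise ValueError(f"{name} must lie in [0, pi), got {v}")
        lo, hi = self.mask_semi_axis_range
        if not (0 < lo <= hi < 1):
            raise ValueError("mask_semi_axis_range fractions must satisfy 0 < lo <= hi < 1")


@dataclass(frozen=True)
class SyntheticSample:
    id: str
    image: np.ndarray   # H x W uint8 grayscale
    mask: np.ndarray    # H x W uint8 in {0, 1}
    label: int
    provenance: dict


def _grating(shape: tuple[int, int], theta: float, wavelength: float, phase: float) -> np.ndarray:
    rows = np.arange(shape[0], dtype=float)[:, None]
    cols = np.arange(shape[1], dtype=float)[None, :]
    # wave vector along (cos theta, sin theta) in (row, col) coordinates,
    # matching the Gabor kernel's rotated x' axis
    coord = rows * math.cos(theta) + cols * math.sin(theta)
    return np.sin(2.0 * math.pi * coord / wavelength + phase)


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  semi_axes: tuple[float, float]) -> np.ndarray:
    rows = np.arange(shape[0], dtype=float)[:, None]
    cols = np.arange(shape[1], dtype=float)[None, :]
    r0, c0 = center
    ar, ac = semi_axes
    inside = ((rows - r0) / ar) ** 2 + ((cols - c0) / ac) ** 2 <= 1.0
    return inside.astype(np.uint8)


def generate_sample(cfg: SyntheticConfig, label: int, rng: np.random.Generator,
                    sample_id: str = "s0") -> SyntheticSample:
    """One grating image with additive noise and a random elliptical mask."""
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label}")
    h, w = cfg.image_size
    theta = cfg.class0_orientation if label == 0 else cfg.class1_orientation
    phase = float(rng.uniform(0.0, 2.0 * math.pi))
    image = cfg.base_intensity + cfg.amplitude * _grating((h, w), theta, cfg.wavelength, phase)
    if label == 1 and cfg.heterogeneity > 0:
        theta2 = (cfg.class1_orientation + math.pi / 3.0) % math.pi
        phase2 = float(rng.uniform(0.0, 2.0 * math.pi))
        image = image + cfg.heterogeneity * cfg.amplitude * _grating(
            (h, w), theta2, cfg.wavelength, phase2
        )
    if cfg.noise_sd > 0:
        image = image + rng.normal(0.0, cfg.noise_sd, size=(h, w))
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    lo, hi = cfg.mask_semi_axis_range
    ar = float(rng.uniform(lo, hi)) * (h / 2.0 - 1.0)
    ac = float(rng.uniform(lo, hi)) * (w / 2.0 - 1.0)
    if ar < 1.0 or ac < 1.0:
        raise ValueError("image too small for an elliptical lesion mask")
    # jitter the centre while keeping the ellipse fully inside the frame
    r0 = float(rng.uniform(ar, h - 1 - ar))
    c0 = float(rng.uniform(ac, w - 1 - ac))
    mask = _ellipse_mask((h, w), (r0, c0), (ar, ac))

    provenance = {
        "label": label,
        "orientation": theta,
        "phase": phase,
        "ellipse_center": (r0, c0),
        "ellipse_semi_axes": (ar, ac),
    }
    return SyntheticSample(id=sample_id, image=image, mask=mask, label=label,
                           provenance=provenance)


def generate_dataset(cfg: SyntheticConfig) -> tuple[list[SyntheticSample], list[SyntheticSample]]:
    """(train, test) samples: 2*n_per_class gratings, stratified 80/20 split.

    Deterministic under ``cfg.seed``: sample draws and the within-class split
    shuffle come from a single seeded generator.
    """
    rng = np.random.default_rng(cfg.seed)
    samples: dict[int, list[SyntheticSample]] = {0: [], 1: []}
    for label in (0, 1):
        for i in range(cfg.n_per_class):
            sid = f"c{label}_{i:03d}"
            samples[label].append(generate_sample(cfg, label, rng, sample_id=sid))
    train: list[SyntheticSample] = []
    test: list[SyntheticSample] = []
    for label in (0, 1):
        order = rng.permutation(cfg.n_per_class)
        n_train = int(round(cfg.train_fraction * cfg.n_per_class))
        for rank, idx in enumerate(order):
            (train if rank < n_train else test).append(samples[label][idx])
    train.sort(key=lambda s: s.id)
    test.sort(key=lambda s: s.id)
    return train, test


def write_dataset(cfg: SyntheticConfig, out_dir: str | Path) -> tuple[Path, Path]:
    """Write images/, masks/, labels CSVs and a provenance JSON to ``out_dir``.

    Returns the paths of the train and test labels CSVs; the layout matches
    what :func:`evogmd.preprocess.load_dataset` reads.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    train, test = generate_dataset(cfg)

    def _write_split(split: list[SyntheticSample], name: str) -> Path:
        rows = []
        for s in split:
            img_rel = f"images/{s.id}.png"
            mask_rel = f"masks/{s.id}.png"
            Image.fromarray(s.image).save(out_dir / img_rel)
            Image.fromarray(s.mask * np.uint8(255)).save(out_dir / mask_rel)
            rows.append({"id": s.id, "image_path": img_rel, "mask_path": mask_rel,
                         "label": s.label})
        path = out_dir / f"labels_{name}.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        return path

    train_csv = _write_split(train, "train")
    test_csv = _write_split(test, "test")
    provenance = {"config": asdict(cfg),
                  "n_train": len(train), "n_test": len(test)}
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return train_csv, test_csv


def to_labeled(samples: list[SyntheticSample]) -> list[LabeledSample]:
    """Apply the mask-and-crop preprocessing to in-memory synthetic samples
    (images are already grayscale at the working resolution, so no rescaling)."""
    return [
        LabeledSample(id=s.id,
                      image=apply_mask_and_crop(s.image.astype(float), s.mask),
                      label=s.label)
        for s in samples
    ]
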