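"""Procedural lesion-like image benchmark.

Renders multi-class datasets of elliptical, irregular "lesions" on a
skin-tone background. Each class owns a parameter vector (eccentricity,
boundary irregularity, lobe count, darkness, texture contrast, size); an
``ambiguity`` knob linearly interpolates every class's parameters toward
the global mean — at ambiguity 1 the classes share one generating
distribution and no classifier can beat chance in expectation — and widens
boundary blur. This produces the heterogeneous per-sample prediction
confidence that confidence-guided noise injection exploits, with a
controllable Bayes difficulty.

Images are written as PNG with a CSV manifest (image_path, label, split;
stratified 80/20), and loaded back through the standard pipeline: resize,
center-crop, optional train-time augmentation (rotations within +/-30
degrees, horizontal/vertical flips), and per-channel normalization with
means [0.485, 0.456, 0.406] and stds [0.229, 0.224, 0.225].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

__all__ = ["SynthSpec", "Dataset", "generate_dataset", "load_dataset",
           "NORM_MEAN", "NORM_STD"]

NORM_MEAN = np.array([0.485, 0.456, 0.406])
NORM_STD = np.array([0.229, 0.224, 0.225])

_SKIN = np.array([0.80, 0.62, 0.52])
_LESION = np.array([0.45, 0.28, 0.22])


@dataclass
class SynthSpec:
    """Generation conditions; same spec + seed reproduce byte-identical images."""

    n_per_class: int = 100
    K: int = 4
    image_size: int = 64
    ambiguity: float = 0.3
    texture_noise: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.K < 2:
            raise ValueError("need at least 2 classes")
        if not (0.0 <= self.ambiguity <= 1.0):
            raise ValueError("ambiguity must lie in [0, 1]")
        if self.texture_noise < 0:
            raise ValueError("texture_noise must be nonnegative")


@dataclass
class Dataset:
    """In-memory image set: images (N, 3, H, W) float64, integer labels (N,)."""

    images: np.ndarray
    labels: np.ndarray

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(zip(self.images, self.labels))

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1


def _class_params(K: int, ambiguity: float) -> np.ndarray:
    """Deterministic per-class shape/texture parameters, shrunk toward the mean."""
    ecc = np.linspace(0.10, 0.70, K)          # ellipse eccentricity
    amp = np.linspace(0.04, 0.22, K)          # boundary irregularity amplitude
    lobes = np.round(np.linspace(3, 3 + 2 * (K - 1), K))
    dark = np.linspace(0.35, 0.85, K)         # lesion darkness mix
    tex = np.linspace(0.02, 0.14, K)          # fill texture contrast
    size = np.linspace(0.26, 0.34, K)         # radius as a fraction of the side
    params = np.stack([ecc, amp, lobes, dark, tex, size], axis=1)
    return (1.0 - ambiguity) * params + ambiguity * params.mean(axis=0, keepdims=True)


def _render_lesion(params: np.ndarray, size: int, blur: float, texture_noise: float,
                   rng: np.random.Generator) -> np.ndarray:
    ecc, amp, lobes, dark, tex, rfrac = params
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    cy = size / 2 + rng.uniform(-0.08, 0.08) * size
    cx = size / 2 + rng.uniform(-0.08, 0.08) * size
    theta = rng.uniform(0, np.pi)
    dy, dx = yy - cy, xx - cx
    u = np.cos(theta) * dx + np.sin(theta) * dy
    v = -np.sin(theta) * dx + np.cos(theta) * dy
    # eccentricity e: minor axis shrinks by sqrt(1 - e^2)
    b_over_a = np.sqrt(max(1.0 - ecc**2, 1e-3))
    r = np.sqrt((u / 1.0) ** 2 + (v / b_over_a) ** 2)
    phi = np.arctan2(v, u)
    phase1, phase2 = rng.uniform(0, 2 * np.pi, size=2)
    radius = rfrac * size * (
        1.0
        + amp * np.sin(lobes * phi + phase1)
        + 0.5 * amp * np.sin((lobes + 2) * phi + phase2)
    )
    mask = (r < radius).astype(np.float64)
    alpha = ndimage.gaussian_filter(mask, sigma=blur)

    img = np.empty((size, size, 3))
    bg_noise = ndimage.gaussian_filter(rng.standard_normal((size, size)), 2.0)
    for ch in range(3):
        img[:, :, ch] = _SKIN[ch] + texture_noise * bg_noise
    lesion_color = (1.0 - dark) * _SKIN + dark * _LESION
    fill_tex = ndimage.gaussian_filter(rng.standard_normal((size, size)), 1.0) * tex
    for ch in range(3):
        lesion_ch = lesion_color[ch] + fill_tex
        img[:, :, ch] = (1.0 - alpha) * img[:, :, ch] + alpha * lesion_ch
    img += texture_noise * 0.5 * rng.standard_normal((size, size, 3))
    return np.clip(img, 0.0, 1.0)


def generate_dataset(spec: SynthSpec, out_dir) -> pd.DataFrame:
    """Render the dataset to ``out_dir`` and return (and write) the manifest.

    Per-sample parameters jitter around the (ambiguity-shrunk) class
    parameters; boundary blur grows with ambiguity. The manifest has
    columns image_path (relative), label, split (stratified 80/20).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    params = _class_params(spec.K, spec.ambiguity)
    spread = _class_params(spec.K, 0.0)
    jitter_scale = 0.10 * (spread.max(axis=0) - spread.min(axis=0) + 1e-9)
    blur = 0.8 + 2.5 * spec.ambiguity

    rows = []
    for k in range(spec.K):
        n_test = max(int(round(spec.n_per_class * 0.2)), 1)
        split_flags = np.array(["train"] * (spec.n_per_class - n_test) + ["test"] * n_test)
        rng.shuffle(split_flags)
        for i in range(spec.n_per_class):
            p = params[k] + rng.normal(0, jitter_scale)
            p[0] = np.clip(p[0], 0.0, 0.9)        # eccentricity
            p[1] = max(p[1], 0.0)                 # irregularity
            p[2] = max(round(p[2]), 2)            # lobes
            p[3] = np.clip(p[3], 0.05, 1.0)       # darkness
            p[4] = max(p[4], 0.0)                 # texture
            p[5] = np.clip(p[5], 0.15, 0.42)      # size
            img = _render_lesion(p, spec.image_size, blur, spec.texture_noise, rng)
            name = f"class{k}_{i:04d}.png"
            Image.fromarray((img * 255).round().astype(np.uint8)).save(out / name)
            rows.append({"image_path": name, "label": k, "split": split_flags[i]})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def draw_augment_params(rng: np.random.Generator) -> tuple[float, bool, bool]:
    """Draw one augmentation triple: rotation angle in [-30, +30] degrees,
    horizontal flip, vertical flip."""
    return float(rng.uniform(-30.0, 30.0)), bool(rng.random() < 0.5), bool(rng.random() < 0.5)


def _resize(img: np.ndarray, size: int) -> np.ndarray:
    if img.shape[0] == size and img.shape[1] == size:
        return img
    zoom = (size / img.shape[0], size / img.shape[1], 1.0)
    return ndimage.zoom(img, zoom, order=1, grid_mode=True, mode="nearest")


def _center_crop(img: np.ndarray, size: int) -> np.ndarray:
    h, w = img.shape[:2]
    r0, c0 = (h - size) // 2, (w - size) // 2
    return img[r0 : r0 + size, c0 : c0 + size]


def load_dataset(
    manifest_path,
    split: str = "train",
    augment: bool = False,
    image_size: int | None = None,
    seed: int = 0,
) -> Dataset:
    """Load a split: resize -> center-crop -> (train-only) augment -> normalize.

    Augmentation draws a rotation uniform in [-30, +30] degrees and
    independent horizontal/vertical flips per image; order and draws are
    deterministic under ``seed``.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent if manifest_path.is_file() else manifest_path
    mf = manifest_path if manifest_path.is_file() else manifest_path / "manifest.csv"
    manifest = pd.read_csv(mf)
    sel = manifest[manifest["split"] == split]
    if len(sel) == 0:
        raise ValueError(f"no rows with split={split!r} in {mf}")
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for _, row in sel.iterrows():
        path = base / row["image_path"]
        if not path.exists():
            raise IOError(f"missing image file: {path}")
        img = np.asarray(Image.open(path).convert("RGB"), dtype=np.float64) / 255.0
        target = image_size or min(img.shape[:2])
        resize_to = max(int(round(target * 1.125)), target)
        img = _center_crop(_resize(img, resize_to), target)
        if augment:
            angle, hflip, vflip = draw_augment_params(rng)
            img = ndimage.rotate(img, angle, reshape=False, order=1, mode="nearest")
            if hflip:
                img = img[:, ::-1]
            if vflip:
                img = img[::-1, :]
        img = (img - NORM_MEAN) / NORM_STD
        images.append(np.ascontiguousarray(img.transpose(2, 0, 1)))
        labels.append(int(row["label"]))
    return Dataset(images=np.stack(images), labels=np.asarray(labels, dtype=np.int64))
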