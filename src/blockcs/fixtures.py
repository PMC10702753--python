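"""Synthetic labeled image generator and sparse-signal oracles.

Stands in for a downloaded vegetable photo corpus: four parametric styles
(broccoli / carrot / potato / radish) that are separable by construction —
each style owns a base hue, a shape mask and a texture frequency — while a
randomized pose (rotation, translation, scale) and additive Gaussian pixel
noise keep individual images varied.  Everything is bit-reproducible from
a seed.

Style table (the separability parameters in one place):

=========  ================  ==================  ==============
style      base RGB (hue)    shape mask          texture freq
=========  ================  ==================  ==============
broccoli   (50, 135, 60)     cluster of discs    7.0
carrot     (235, 100, 25)    elongated taper     3.5
potato     (170, 150, 60)    ellipse             1.5
radish     (245, 190, 215)   capsule (cylinder)  0.8
=========  ================  ==================  ==============

The minimum pairwise circular distance between the base hues is ~0.077
(carrot vs potato); :data:`MIN_HUE_MARGIN` = 0.05 is the margin the
generator guarantees for mean foreground hue.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .classifier import DEFAULT_CLASSES, LabeledDataset

__all__ = [
    "STYLES",
    "MIN_HUE_MARGIN",
    "FixtureSpec",
    "generate_class_image",
    "generate_dataset",
    "write_dataset",
    "generate_sparse_vector",
    "mean_foreground_hue",
]

#: Parameters per style: base color, shape id, texture frequency.
STYLES = {
    "broccoli": {"rgb": (50, 135, 60), "shape": "discs", "freq": 7.0},
    "carrot": {"rgb": (235, 100, 25), "shape": "taper", "freq": 3.5},
    "potato": {"rgb": (170, 150, 60), "shape": "ellipse", "freq": 1.5},
    "radish": {"rgb": (245, 190, 215), "shape": "capsule", "freq": 0.8},
}

#: Guaranteed lower bound on pairwise mean-foreground-hue separation.
MIN_HUE_MARGIN = 0.05

_BACKGROUND = 205.0
_TEXTURE_AMP = 0.22


@dataclass
class FixtureSpec:
    """Generation parameters for a synthetic labeled dataset."""

    images_per_class: int
    image_size: int = 64
    seed: int = 0
    noise_sd: float = 8.0
    classes: tuple[str, ...] = DEFAULT_CLASSES

    def __post_init__(self) -> None:
        if self.images_per_class < 1:
            raise ValueError("images_per_class must be >= 1")
        if self.image_size % 8 != 0:
            raise ValueError(
                f"image size {self.image_size} must be divisible by 8"
            )
        unknown = set(self.classes) - STYLES.keys()
        if unknown:
            raise ValueError(f"unknown styles: {sorted(unknown)}")


def _shape_mask(shape: str, u: np.ndarray, v: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    if shape == "discs":
        mask = np.zeros(u.shape, dtype=bool)
        for _ in range(8):
            cu, cv = rng.uniform(-0.3, 0.3, size=2)
            r = rng.uniform(0.16, 0.28)
            mask |= (u - cu) ** 2 + (v - cv) ** 2 <= r * r
        return mask
    if shape == "taper":
        # halfwidth shrinks linearly toward the tip at v = +0.65
        inside = (v >= -0.65) & (v <= 0.65)
        halfwidth = 0.02 + 0.26 * (0.65 - v) / 1.3
        return inside & (np.abs(u) <= halfwidth)
    if shape == "ellipse":
        return (u / 0.55) ** 2 + (v / 0.38) ** 2 <= 1.0
    if shape == "capsule":
        body = (np.abs(u) <= 0.28) & (np.abs(v) <= 0.42)
        caps = u**2 + (np.abs(v) - 0.42) ** 2 <= 0.28**2
        return body | caps
    raise ValueError(f"unknown shape {shape!r}")


def generate_class_image(style: str, size: int = 64, seed=0,
                         noise_sd: float = 8.0) -> np.ndarray:
    """One synthetic image of a style, deterministic given the seed.

    Returns an (size, size, 3) uint8 array.  Pose (rotation, translation,
    scale), disc layout, texture phase, brightness and pixel noise are all
    drawn from the seeded generator; hue is fixed by the style table.
    """
    if style not in STYLES:
        raise ValueError(f"unknown style {style!r}; choose from {sorted(STYLES)}")
    params = STYLES[style]
    rng = np.random.default_rng(seed)

    coords = (np.arange(size) + 0.5) / size * 2.0 - 1.0
    x, y = np.meshgrid(coords, coords)

    theta = rng.uniform(0.0, 2.0 * np.pi)
    scale = rng.uniform(0.8, 1.15)
    tx, ty = rng.uniform(-0.15, 0.15, size=2)
    ct, st = np.cos(theta), np.sin(theta)
    u = (ct * (x - tx) + st * (y - ty)) / scale
    v = (-st * (x - tx) + ct * (y - ty)) / scale

    mask = _shape_mask(params["shape"], u, v, rng)

    phase_u, phase_v = rng.uniform(0.0, 2.0 * np.pi, size=2)
    freq = params["freq"]
    texture = 1.0 + _TEXTURE_AMP * np.sin(2 * np.pi * freq * u + phase_u) * np.sin(
        2 * np.pi * freq * v + phase_v
    )
    brightness = rng.uniform(0.9, 1.1)

    base = np.array(params["rgb"], dtype=float)
    img = np.full((size, size, 3), _BACKGROUND)
    img[mask] = base * brightness * texture[mask, None]
    img += rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_dataset(spec: FixtureSpec) -> LabeledDataset:
    """A balanced labeled dataset: images_per_class items per style."""
    images, labels = [], []
    for ci, cls in enumerate(spec.classes):
        for j in range(spec.images_per_class):
            seed = np.random.SeedSequence((spec.seed, ci, j))
            images.append(
                generate_class_image(cls, spec.image_size, seed, spec.noise_sd)
            )
            labels.append(cls)
    return LabeledDataset(images, labels, spec.classes)


def write_dataset(ds: LabeledDataset, root) -> list[Path]:
    """Write `<root>/<class>/<index>.png` (the layout the loader reads)."""
    root = Path(root)
    written = []
    counters = {c: 0 for c in ds.classes}
    for img, label in zip(ds.images, ds.labels):
        d = root / label
        d.mkdir(parents=True, exist_ok=True)
        path = d / f"{counters[label]:04d}.png"
        Image.fromarray(img).save(path)
        counters[label] += 1
        written.append(path)
    return written


def generate_sparse_vector(length: int, k: int,
                           amplitude_range: tuple[float, float] = (1.0, 2.0),
                           seed=0) -> np.ndarray:
    """Exactly K nonzeros at uniform random positions, magnitudes in range.

    Magnitudes are bounded away from zero (lower end of the range) with
    random signs — the standard test signal for sparse-recovery oracles.
    """
    if not 0 <= k <= length:
        raise ValueError(f"sparsity {k} outside [0, {length}]")
    lo, hi = amplitude_range
    if lo <= 0 or hi < lo:
        raise ValueError(f"amplitude range must satisfy 0 < lo <= hi, got {amplitude_range}")
    rng = np.random.default_rng(seed)
    v = np.zeros(length)
    support = rng.choice(length, size=k, replace=False)
    v[support] = rng.uniform(lo, hi, size=k) * rng.choice([-1.0, 1.0], size=k)
    return v


def mean_foreground_hue(image: np.ndarray, sat_threshold: float = 0.12) -> float:
    """Hue (in [0, 1)) of the mean color over saturated (foreground) pixels.

    The gray background has near-zero saturation, so thresholding on
    saturation isolates the object; the style's base hue survives the
    brightness/texture modulation because both scale all channels equally.
    """
    arr = np.asarray(image, dtype=float) / 255.0
    mx = arr.max(axis=-1)
    mn = arr.min(axis=-1)
    sat = np.where(mx > 0, (mx - mn) / np.maximum(mx, 1e-12), 0.0)
    mask = sat > sat_threshold
    if not mask.any():
        raise ValueError("no saturated pixels found; cannot estimate hue")
    r, g, b = np.mean(arr[mask], axis=0)
    mx, mn = max(r, g, b), min(r, g, b)
    if mx == mn:
        return 0.0
    d = mx - mn
    if mx == r:
        h = ((g - b) / d) % 6.0
    elif mx == g:
        h = (b - r) / d + 2.0
    else:
        h = (r - g) / d + 4.0
    return h / 6.0
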