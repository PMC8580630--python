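"""Synthetic dermoscopy-like images with exact ground-truth masks.

Each image is a skin-toned background under a smooth multiplicative
illumination gradient, carrying a single darker pigmented lesion.  The
lesion boundary is a radial harmonic curve

    r(theta) = r0 * (1 + irregularity * sum_{k=2..6} a_k cos(k theta + phi_k)
                       + asymmetry * cos(theta + phi_1))

with random harmonic weights ``a_k`` normalised to sum to one, so
``irregularity`` directly sets the relative amplitude of the border waves
and ``asymmetry`` adds a first-harmonic distortion plus an off-center
shift.  Pigment density varies inside the lesion as a smooth multiplicative
field with standard deviation ``color_variance``; optional dark hair arcs
and white Gaussian pixel noise complete the image.  The mask is the exact
rasterisation of the boundary curve — star-shaped by construction, hence a
single connected component.

Class-separating defaults: melanoma-labelled lesions get larger border
irregularity, asymmetry and color variance than benign ones, so the
geometric and statistical features of the extraction stage separate the
classes.

Tones are chosen so that the lesion is darker than skin in luminance and
lower in both normalised-red and normalised-X chromaticity, matching the
assumptions of the segmentation stage.  Images default to 256x256 — a
desk-scale stand-in for full-resolution dermoscopy frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import ConfigError
from .features import FEATURE_NAMES, FeatureConfig, extract_table, luminance

__all__ = [
    "LesionSpec",
    "SyntheticDataset",
    "benign_spec",
    "melanoma_spec",
    "generate_image",
    "generate_dataset",
    "dice",
]


@dataclass(frozen=True)
class LesionSpec:
    """All generator knobs for one lesion image."""

    image_size: int = 256
    skin_tone: tuple[float, float, float] = (0.80, 0.60, 0.50)
    lesion_tone: tuple[float, float, float] = (0.30, 0.26, 0.24)
    radius_frac: float = 0.18
    irregularity: float = 0.10
    asymmetry: float = 0.08
    color_variance: float = 0.03
    hair_count: int = 0
    noise_sigma: float = 0.02
    label: str = "benign"

    def __post_init__(self) -> None:
        if not 0.0 < self.radius_frac < 0.45:
            raise ConfigError("radius_frac must lie in (0, 0.45)")
        if self.irregularity < 0 or self.asymmetry < 0 or self.color_variance < 0:
            raise ConfigError("shape and color parameters must be non-negative")
        if self.noise_sigma < 0 or self.hair_count < 0:
            raise ConfigError("noise_sigma and hair_count must be non-negative")
        if self.label not in ("benign", "melanoma"):
            raise ConfigError(f"label must be 'benign' or 'melanoma', got {self.label!r}")
        lum = lambda t: 0.2126 * t[0] + 0.7152 * t[1] + 0.0722 * t[2]
        if lum(self.lesion_tone) >= lum(self.skin_tone):
            raise ConfigError("lesion tone must be darker than skin tone")


def benign_spec(**overrides) -> LesionSpec:
    """Default benign lesion: nearly round, homogeneous pigment."""
    return replace(
        LesionSpec(irregularity=0.06, asymmetry=0.05, color_variance=0.02), **overrides
    )


def melanoma_spec(**overrides) -> LesionSpec:
    """Default melanoma lesion: wavy border, asymmetric, variegated."""
    return replace(
        LesionSpec(
            irregularity=0.35,
            asymmetry=0.30,
            color_variance=0.08,
            radius_frac=0.20,
            label="melanoma",
        ),
        **overrides,
    )


def _smooth_field(shape, sigma_px: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-std smooth random field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_px)
    sd = f.std()
    return f / sd if sd > 0 else f


def _hair_arc(size: int, rng: np.random.Generator) -> np.ndarray:
    """Boolean stamp of one thin dark arc crossing the frame."""
    t = np.linspace(0.0, 1.0, 4 * size)
    p0 = rng.uniform(0, size, 2)
    p2 = rng.uniform(0, size, 2)
    p1 = 0.5 * (p0 + p2) + rng.uniform(-0.4 * size, 0.4 * size, 2)
    pts = (
        np.outer((1 - t) ** 2, p0) + np.outer(2 * (1 - t) * t, p1) + np.outer(t**2, p2)
    )
    rows = np.clip(pts[:, 0].astype(int), 0, size - 1)
    cols = np.clip(pts[:, 1].astype(int), 0, size - 1)
    stamp = np.zeros((size, size), dtype=bool)
    stamp[rows, cols] = True
    return ndimage.binary_dilation(stamp, iterations=1)


def generate_image(
    spec: LesionSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, str]:
    """Render one (RGB image, boolean mask, label) triple."""
    n = spec.image_size
    r0 = spec.radius_frac * n

    # radial harmonic boundary, normalised so the wave amplitude equals
    # `irregularity` exactly; total relative distortion stays below ~0.6
    ks = np.arange(2, 7)
    a = rng.uniform(0.3, 1.0, ks.size)
    a /= a.sum()
    phases = rng.uniform(0, 2 * np.pi, ks.size)
    phi1 = rng.uniform(0, 2 * np.pi)
    center = n / 2 + spec.asymmetry * r0 * 0.5 * np.array(
        [np.cos(phi1), np.sin(phi1)]
    )

    ys, xs = np.indices((n, n))
    dy, dx = ys - center[0], xs - center[1]
    theta = np.arctan2(dx, dy)
    rad = np.hypot(dy, dx)
    wave = spec.irregularity * np.sum(
        a[:, None, None] * np.cos(ks[:, None, None] * theta + phases[:, None, None]),
        axis=0,
    )
    wave = wave + spec.asymmetry * 0.5 * np.cos(theta + phi1)
    boundary = r0 * np.clip(1.0 + wave, 0.35, 1.8)
    mask = rad <= boundary

    skin = np.array(spec.skin_tone)
    lesion = np.array(spec.lesion_tone)
    illum = 1.0 + 0.03 * _smooth_field((n, n), n / 4, rng)
    pigment = 1.0 + spec.color_variance * _smooth_field((n, n), n / 16, rng)
    img = np.where(mask[..., None], lesion[None, None, :] * pigment[..., None], skin[None, None, :])
    img = img * illum[..., None]

    for _ in range(spec.hair_count):
        arc = _hair_arc(n, rng)
        img[arc] = img[arc] * 0.25

    if spec.noise_sigma > 0:
        img = img + spec.noise_sigma * rng.standard_normal(img.shape)
    return np.clip(img, 0.0, 1.0), mask, spec.label


@dataclass
class SyntheticDataset:
    """Images, exact masks, integer labels and the extracted feature table."""

    images: list[np.ndarray]
    masks: list[np.ndarray]
    labels: np.ndarray  # 0 = benign, 1 = melanoma
    features: pd.DataFrame
    specs: list[LesionSpec] = field(default_factory=list)


def generate_dataset(
    n: int,
    benign: LesionSpec | None = None,
    melanoma: LesionSpec | None = None,
    rng: np.random.Generator | None = None,
    feature_config: FeatureConfig | None = None,
) -> SyntheticDataset:
    """Balanced labelled dataset with per-image ground-truth features.

    Half the images (rounding up) are benign, half melanoma; the feature
    table is extracted with the ground-truth masks so it reflects the
    generator, not the segmentation stage.
    """
    if n < 2:
        raise ConfigError("n must be >= 2")
    if rng is None:
        rng = np.random.default_rng()
    benign = benign if benign is not None else benign_spec()
    melanoma = melanoma if melanoma is not None else melanoma_spec()

    n_benign = (n + 1) // 2
    specs = [benign] * n_benign + [melanoma] * (n - n_benign)
    images, masks, labels = [], [], []
    for spec in specs:
        img, msk, label = generate_image(spec, rng)
        images.append(img)
        masks.append(msk)
        labels.append(0 if label == "benign" else 1)
    table = extract_table(images, masks, feature_config)
    table["label"] = labels
    return SyntheticDataset(
        images=images,
        masks=masks,
        labels=np.array(labels),
        features=table,
        specs=specs,
    )


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap ``2|A ∩ B| / (|A| + |B|)`` of two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    return 2.0 * float((a & b).sum()) / denom if denom else 1.0
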