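"""Region features for lesion classification.

Given an image and a binary lesion mask, computes a fixed, named vector of
statistical, texture, geometric and moment-invariant features:

* statistical — mean, variance, standard deviation and histogram entropy
  of the masked gray intensities;
* texture — contrast, energy, homogeneity and correlation of a symmetric,
  normalised gray-level co-occurrence matrix (GLCM) restricted to masked
  pixel pairs;
* geometric — area, perimeter (count of region pixels 4-adjacent to
  background), rectangularity, irregularity index ``4*pi*A/P^2``, form
  factor, eccentricity, elongation and solidity, with the major/minor axis
  lengths ``a``, ``b`` of the second-moment ellipse;
* moment invariants — the first three combinations ``phi1..phi3`` of the
  scale-normalised central moments (translation- and scale-invariant).

Two texture modes exist.  ``standard`` uses the canonical GLCM
definitions.  ``literal`` reproduces a published variant in which contrast
and energy share the formula ``sum p^2`` and correlation is
``(sum p - mu_r * mu_c) / (sigma_r * sigma_c)``; it is retained so the
duplication is documented and testable, not because it is recommended.

The printed eccentricity ``(2/a) * sqrt(a^2 - b^2)`` can exceed 1 for
elongated shapes; it is computed as written.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from skimage import measure

from .exceptions import ConfigError, DataError

__all__ = [
    "FEATURE_NAMES",
    "GLCM",
    "FeatureConfig",
    "FeatureVector",
    "glcm",
    "hu_invariants",
    "luminance",
    "extract",
    "extract_table",
]

FEATURE_NAMES = (
    "mean",
    "variance",
    "std",
    "area",
    "rectangularity",
    "irregularity_index",
    "form_factor",
    "eccentricity",
    "elongation",
    "contrast",
    "perimeter",
    "entropy",
    "solidity",
    "correlation",
    "energy",
    "homogeneity",
    "phi1",
    "phi2",
    "phi3",
)

#: Rec. 709 luma weights used to collapse RGB to gray.
_LUMA = np.array([0.2126, 0.7152, 0.0722])


def luminance(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return image
    return image @ _LUMA


@dataclass
class GLCM:
    """Symmetric normalised co-occurrence matrix over masked pixel pairs."""

    levels: int
    offset: tuple[int, int]
    matrix: np.ndarray


@dataclass
class FeatureConfig:
    levels: int = 32
    offsets: tuple[tuple[int, int], ...] = ((0, 1), (1, 0))
    mode: str = "standard"
    entropy_bins: int = 64

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ConfigError("levels must be >= 2")
        if self.mode not in ("standard", "literal"):
            raise ConfigError(f"unknown texture mode {self.mode!r}")


@dataclass
class FeatureVector:
    """Named feature values for one (image, mask) pair."""

    values: dict[str, float] = field(default_factory=dict)

    def __getattr__(self, name: str) -> float:
        if name.startswith("__") or name == "values":
            raise AttributeError(name)
        try:
            return self.__dict__["values"][name]
        except KeyError as exc:
            raise AttributeError(name) from exc

    def as_series(self) -> pd.Series:
        return pd.Series({k: self.values[k] for k in FEATURE_NAMES})

    def as_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in FEATURE_NAMES])


def glcm(
    gray: np.ndarray,
    mask: np.ndarray,
    levels: int = 32,
    offset: tuple[int, int] = (0, 1),
) -> GLCM:
    """Co-occurrence counts of quantised gray levels at one offset.

    Intensities of masked pixels are quantised to ``levels`` equal-width
    bins over the masked range (a constant region occupies a single
    level).  Only pairs with both pixels inside the mask count; the matrix
    is symmetrised and normalised to sum to one.
    """
    gray = np.asarray(gray, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if levels < 2:
        raise ConfigError("levels must be >= 2")
    if not mask.any():
        raise DataError("empty mask")
    vals = gray[mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi > lo:
        q = np.floor((gray - lo) / (hi - lo) * levels).astype(int)
        np.clip(q, 0, levels - 1, out=q)
    else:
        q = np.zeros_like(gray, dtype=int)

    dy, dx = offset
    h, w = gray.shape
    src = np.zeros((h, w), dtype=bool)
    src[max(0, -dy) : h - max(0, dy), max(0, -dx) : w - max(0, dx)] = True
    pair = src & mask & np.roll(np.roll(mask, -dy, axis=0), -dx, axis=1)
    i = q[pair]
    j = np.roll(np.roll(q, -dy, axis=0), -dx, axis=1)[pair]
    if i.size < 1:
        raise DataError("mask has no co-occurring pixel pairs at this offset")
    counts = np.zeros((levels, levels))
    np.add.at(counts, (i, j), 1.0)
    counts = counts + counts.T
    return GLCM(levels=levels, offset=offset, matrix=counts / counts.sum())


def hu_invariants(region: np.ndarray) -> tuple[float, float, float]:
    """First three moment invariants of a binary or gray-weighted region.

    Central moments ``mu_pq`` are scale-normalised to
    ``eta_pq = mu_pq / mu_00^(1 + (p+q)/2)`` and combined into
    ``phi1 = eta20 + eta02``,
    ``phi2 = (eta20 - eta02)^2 + 4*eta11^2``,
    ``phi3 = (eta30 - 3*eta12)^2 + (3*eta21 - eta03)^2``.
    """
    region = np.asarray(region, dtype=float)
    m00 = region.sum()
    if m00 <= 0:
        raise DataError("zero-mass region has no moment invariants")
    ys, xs = np.indices(region.shape)
    cy = (ys * region).sum() / m00
    cx = (xs * region).sum() / m00
    dy, dx = ys - cy, xs - cx

    def mu(p: int, q: int) -> float:
        return float((dy**p * dx**q * region).sum())

    def eta(p: int, q: int) -> float:
        return mu(p, q) / m00 ** (1 + (p + q) / 2)

    e20, e02, e11 = eta(2, 0), eta(0, 2), eta(1, 1)
    e30, e03, e21, e12 = eta(3, 0), eta(0, 3), eta(2, 1), eta(1, 2)
    phi1 = e20 + e02
    phi2 = (e20 - e02) ** 2 + 4 * e11**2
    phi3 = (e30 - 3 * e12) ** 2 + (3 * e21 - e03) ** 2
    return phi1, phi2, phi3


def _perimeter_4adjacent(mask: np.ndarray) -> int:
    """Count region pixels with at least one 4-neighbour outside the region.

    Pixels on the image border count as boundary (outside is background).
    """
    padded = np.pad(mask, 1, mode="constant", constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return int((mask & ~interior).sum())


def _glcm_stats(p: np.ndarray, mode: str) -> dict[str, float]:
    levels = p.shape[0]
    i = np.arange(levels)[:, None]
    j = np.arange(levels)[None, :]
    energy = float((p**2).sum())
    homogeneity = float((p / (1.0 + np.abs(i - j))).sum())
    if mode == "literal":
        mu_r = float((i * p).sum())
        mu_c = float((j * p).sum())
        sd_r = math.sqrt(max(float(((i - mu_r) ** 2 * p).sum()), 0.0))
        sd_c = math.sqrt(max(float(((j - mu_c) ** 2 * p).sum()), 0.0))
        corr = (float(p.sum()) - mu_r * mu_c) / (sd_r * sd_c) if sd_r * sd_c > 0 else 0.0
        return {"contrast": energy, "energy": energy, "homogeneity": homogeneity, "correlation": corr}
    contrast = float(((i - j) ** 2 * p).sum())
    mu_r = float((i * p).sum())
    mu_c = float((j * p).sum())
    sd_r = math.sqrt(max(float(((i - mu_r) ** 2 * p).sum()), 0.0))
    sd_c = math.sqrt(max(float(((j - mu_c) ** 2 * p).sum()), 0.0))
    if sd_r * sd_c > 0:
        corr = float((((i - mu_r) * (j - mu_c) * p).sum()) / (sd_r * sd_c))
    else:
        corr = 0.0
    return {"contrast": contrast, "energy": energy, "homogeneity": homogeneity, "correlation": corr}


def extract(
    image: np.ndarray, mask: np.ndarray, config: FeatureConfig | None = None
) -> FeatureVector:
    """Compute the full named feature vector for one (image, mask) pair."""
    if config is None:
        config = FeatureConfig()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DataError("empty mask")
    gray = luminance(image)
    vals = gray[mask]

    out: dict[str, float] = {}
    out["mean"] = float(vals.mean())
    out["variance"] = float(vals.var(ddof=0))
    out["std"] = math.sqrt(out["variance"])
    hist, _ = np.histogram(vals, bins=config.entropy_bins, range=(0.0, 1.0))
    p_hat = hist[hist > 0] / hist.sum()
    out["entropy"] = float(-(p_hat * np.log(p_hat)).sum())

    area = int(mask.sum())
    perimeter = _perimeter_4adjacent(mask)
    props = measure.regionprops(mask.astype(int))[0]
    a = float(props.axis_major_length)
    b = float(props.axis_minor_length)
    if a <= 0:
        raise DataError("degenerate region: zero major axis length")
    out["area"] = float(area)
    out["perimeter"] = float(perimeter)
    out["rectangularity"] = area / (a * b) if b > 0 else float("inf")
    out["irregularity_index"] = 4.0 * math.pi * area / perimeter**2
    out["form_factor"] = area / a**2
    out["eccentricity"] = (2.0 / a) * math.sqrt(max(a**2 - b**2, 0.0))
    out["elongation"] = 2.0 * math.sqrt(area / math.pi) / a
    out["solidity"] = float(props.solidity)
    if not np.isfinite(out["rectangularity"]):
        raise DataError("degenerate region: zero minor axis length")

    mats = [glcm(gray, mask, config.levels, off).matrix for off in config.offsets]
    p = np.mean(mats, axis=0)
    out.update(_glcm_stats(p, config.mode))

    phi1, phi2, phi3 = hu_invariants(mask.astype(float))
    out["phi1"], out["phi2"], out["phi3"] = phi1, phi2, phi3
    return FeatureVector(values=out)


def extract_table(
    images: Iterable[np.ndarray],
    masks: Iterable[np.ndarray],
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Feature table with one named-column row per (image, mask) pair."""
    rows = [extract(img, msk, config).as_series() for img, msk in zip(images, masks)]
    return pd.DataFrame(rows).reset_index(drop=True)
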