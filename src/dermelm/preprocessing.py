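"""Dermoscopy preprocessing: fuzzy-rule denoising and contrast stretching.

Two independent operations:

* **Denoising** with a Wang–Mendel style fuzzy rulebase learned from
  (noisy 3x3 neighborhood, clean center) training pairs.  Three antecedent
  variables summarise the neighborhood — center value, median and mean —
  each fuzzified over triangular partitions of [0, 1].  Every training
  pair proposes one rule whose degree is the product of its antecedent
  memberships; within each occupied antecedent cell only the highest-degree
  rule survives.  Inference fires all rules with product conjunction and
  defuzzifies by the degree-weighted average of the crisp consequents;
  pixels firing no rule fall back to the neighborhood median.  Without a
  trained rulebase a plain 3x3 median filter is used.

* **Contrast stretching** to the full [0, 1] range through an 8-bit lookup
  table: inputs are quantised to 256 levels between the observed minimum
  and maximum and mapped linearly.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import ConfigError, DataError

__all__ = [
    "FuzzyRulebase",
    "contrast_stretch",
    "stretch_image",
    "train_wm_rulebase",
    "denoise",
]

logger = logging.getLogger(__name__)


def contrast_stretch(channel: np.ndarray) -> np.ndarray:
    """Stretch a 2-D channel to [0, 1] through a 256-entry lookup table.

    ``out = (in - min) / (max - min)``, quantised: inputs are floored onto
    256 equal-width levels spanning the observed range, and each level is
    mapped through the linear table.  A constant channel degenerates to all
    zeros with a warning.
    """
    channel = np.asarray(channel, dtype=float)
    if not np.all(np.isfinite(channel)):
        raise DataError("contrast_stretch requires finite input")
    lo, hi = float(channel.min()), float(channel.max())
    if hi == lo:
        warnings.warn("degenerate contrast: constant channel maps to zeros")
        return np.zeros_like(channel)
    levels = np.floor((channel - lo) / (hi - lo) * 255.0).astype(int)
    np.clip(levels, 0, 255, out=levels)
    lut = np.linspace(0.0, 1.0, 256)
    return lut[levels]


def stretch_image(image: np.ndarray) -> np.ndarray:
    """Contrast-stretch an RGB image with one shared lookup table.

    The table spans the global min/max over all channels, so the channels
    undergo the same affine map and their ratios — which the segmentation
    stage relies on — are distorted as little as possible.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return contrast_stretch(image)
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        warnings.warn("degenerate contrast: constant image maps to zeros")
        return np.zeros_like(image)
    levels = np.floor((image - lo) / (hi - lo) * 255.0).astype(int)
    np.clip(levels, 0, 255, out=levels)
    return np.linspace(0.0, 1.0, 256)[levels]


@dataclass
class FuzzyRulebase:
    """Triangular-partition fuzzy rulebase over (center, median, mean).

    ``rules`` maps an antecedent cell (one partition index per input) to
    the crisp consequent value of the winning rule and its degree.
    """

    n_partitions: int = 7
    rules: dict[tuple[int, int, int], tuple[float, float]] = field(default_factory=dict)

    def centers(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_partitions)

    def memberships(self, values: np.ndarray) -> np.ndarray:
        """Triangular memberships of ``values`` (any shape) in each set.

        Returns an array of shape ``values.shape + (n_partitions,)``.
        Neighbouring set centers are one partition width apart, so each
        value has at most two nonzero memberships summing to one.
        """
        c = self.centers()
        width = c[1] - c[0]
        v = np.asarray(values, dtype=float)[..., None]
        return np.clip(1.0 - np.abs(v - c) / width, 0.0, 1.0)

    def to_json(self) -> str:
        payload = {
            "n_partitions": self.n_partitions,
            "rules": [
                {"cell": list(cell), "consequent": cons, "degree": deg}
                for cell, (cons, deg) in sorted(self.rules.items())
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FuzzyRulebase":
        payload = json.loads(text)
        rules = {
            tuple(r["cell"]): (float(r["consequent"]), float(r["degree"]))
            for r in payload["rules"]
        }
        return cls(n_partitions=int(payload["n_partitions"]), rules=rules)


def _antecedents(neighborhood: np.ndarray) -> tuple[float, float, float]:
    nb = np.asarray(neighborhood, dtype=float).ravel()
    center = float(nb[len(nb) // 2])
    return center, float(np.median(nb)), float(nb.mean())


def train_wm_rulebase(
    pairs: list[tuple[np.ndarray, float]], n_partitions: int = 7
) -> FuzzyRulebase:
    """Learn a rulebase from (noisy 3x3 neighborhood, clean center) pairs.

    Each pair contributes one candidate rule: its antecedent cell is the
    maximum-membership partition of (center, median, mean), its degree the
    product of those memberships, and its consequent the clean center
    value.  Cells keep only their highest-degree candidate.
    """
    if n_partitions < 3:
        raise ConfigError("n_partitions must be >= 3")
    if not pairs:
        raise DataError("cannot train a rulebase from zero pairs")
    rb = FuzzyRulebase(n_partitions=n_partitions)
    for neighborhood, clean in pairs:
        ants = np.array(_antecedents(neighborhood))
        if np.any(ants < 0) or np.any(ants > 1) or not 0 <= clean <= 1:
            raise DataError("training values must lie in [0, 1]")
        mem = rb.memberships(ants)  # (3, P)
        cell = tuple(int(i) for i in mem.argmax(axis=-1))
        degree = float(mem.max(axis=-1).prod())
        current = rb.rules.get(cell)
        if current is None or degree > current[1]:
            rb.rules[cell] = (float(clean), degree)
    return rb


def _median_filter(channel: np.ndarray) -> np.ndarray:
    return ndimage.median_filter(channel, size=3, mode="reflect")


def _denoise_channel(channel: np.ndarray, rulebase: FuzzyRulebase) -> np.ndarray:
    """Fire all rules per pixel (product inference, weighted-average output)."""
    pad = np.pad(channel, 1, mode="reflect")
    h, w = channel.shape
    windows = np.lib.stride_tricks.sliding_window_view(pad, (3, 3)).reshape(h, w, 9)
    center = windows[..., 4]
    med = np.median(windows, axis=-1)
    mean = windows.mean(axis=-1)

    mem_c = rulebase.memberships(center)
    mem_md = rulebase.memberships(med)
    mem_mn = rulebase.memberships(mean)

    num = np.zeros((h, w))
    den = np.zeros((h, w))
    for (ic, imd, imn), (cons, _deg) in rulebase.rules.items():
        fire = mem_c[..., ic] * mem_md[..., imd] * mem_mn[..., imn]
        num += fire * cons
        den += fire
    out = np.where(den > 1e-12, num / np.maximum(den, 1e-12), med)
    return out


def denoise(image: np.ndarray, rulebase: FuzzyRulebase | None = None) -> np.ndarray:
    """Denoise a gray or RGB image in [0, 1].

    With a rulebase, fuzzy inference as described in the module docstring;
    without one, a 3x3 median filter.  RGB channels are processed
    independently.
    """
    image = np.asarray(image, dtype=float)
    if image.min() < 0 or image.max() > 1:
        raise DataError("denoise expects intensities in [0, 1]")
    fn = _median_filter if rulebase is None else lambda ch: _denoise_channel(ch, rulebase)
    if image.ndim == 2:
        return np.clip(fn(image), 0.0, 1.0)
    out = np.empty_like(image)
    for c in range(image.shape[2]):
        out[..., c] = fn(image[..., c])
    return np.clip(out, 0.0, 1.0)
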