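"""Summary statistics of pooled response maps: mean, skewness, entropy.

Each orientation-pooled response map is reduced to three "generalizer"
values — the arithmetic mean, the histogram skewness (population
normalization, third central moment over s^3 with s = sqrt(m2)), and the
Shannon entropy in bits of the map's intensity histogram.  For the default
36-map stack this yields the 108-element feature vector describing one
cutout.  All three statistics are histogram functionals: permuting pixel
positions within a map leaves the features unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .gaborbank import FilterBank, ResponseStack

__all__ = [
    "FeatureVector",
    "map_mean",
    "map_skewness",
    "map_entropy",
    "feature_names",
    "extract_features",
]

STAT_NAMES = ("mean", "skew", "entropy")


def map_mean(values: np.ndarray) -> float:
    """Arithmetic mean of all map entries."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("map is empty")
    return float(values.mean())


def map_skewness(values: np.ndarray) -> float:
    """Population skewness: (1/N) sum (x - mean)^3 / s^3 with s = population std.

    A map with zero spread has undefined skewness; by convention 0.0 is
    returned with a warning so degenerate inputs don't abort batch runs.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("map is empty")
    centered = values - values.mean()
    s2 = np.mean(centered**2)
    if s2 == 0.0:
        warnings.warn("map has zero spread; skewness undefined, returning 0", stacklevel=2)
        return 0.0
    return float(np.mean(centered**3) / s2**1.5)


def map_entropy(values: np.ndarray, bins: int = 256) -> float:
    """Shannon entropy (bits) of the map's intensity histogram.

    The histogram uses ``bins`` equal-width bins spanning the map's own
    [min, max] — pooled response scales differ by orders of magnitude
    across filter triples, so a per-map range keeps the statistic
    comparable.  Empty bins contribute nothing; a constant map occupies a
    single bin and has entropy 0.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("map is empty")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(values, bins=bins, range=(lo, hi))
    p = counts[counts > 0] / values.size
    return float(-(p * np.log2(p)).sum())


@dataclass(frozen=True)
class FeatureVector:
    """The ordered per-cutout feature vector (triplets in bank order)."""

    values: np.ndarray
    names: tuple[str, ...]
    cutout_id: str = ""

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.names),):
            raise ValueError("values and names lengths differ")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def __len__(self) -> int:
        return self.values.size


def _fmt(v: float) -> str:
    return f"{v:g}"


def feature_names(index) -> tuple[str, ...]:
    """Feature names for a pooled-map index or a FilterBank.

    Layout: for each (b, lambda, gamma) triple in canonical bank order, a
    ``(mean, skew, entropy)`` triplet named ``b{b}_lam{lam}_gam{gam}_{stat}``.
    """
    if isinstance(index, FilterBank):
        index = index.pooled_index
    return tuple(
        f"b{_fmt(b)}_lam{_fmt(lam)}_gam{_fmt(gam)}_{stat}"
        for (b, lam, gam) in index
        for stat in STAT_NAMES
    )


def extract_features(
    stack: ResponseStack, bins: int = 256, cutout_id: str = ""
) -> FeatureVector:
    """Reduce a pooled response stack to its mean/skew/entropy triplets."""
    if stack.maps.shape[0] != len(stack.index):
        raise ValueError("response stack index does not match map count")
    values = np.empty(3 * len(stack), dtype=float)
    for i in range(len(stack)):
        m = stack.maps[i]
        values[3 * i : 3 * i + 3] = (map_mean(m), map_skewness(m), map_entropy(m, bins=bins))
    return FeatureVector(values=values, names=feature_names(stack.index), cutout_id=cutout_id)
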