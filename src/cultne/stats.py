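"""Effective-size estimators, influence moments, and diversity indices.

The estimators are driven entirely by the first two moments of the
per-parent cultural offspring counts. With parental pool size ``N_{t-1}``,
mean offspring number ``k_bar`` and population-convention variance
``sigma2``:

* inbreeding effective size
  ``Nei = (N_{t-1} * k_bar - 1) / (k_bar - 1 + sigma2 / k_bar)``
* variance effective size
  ``Nev = (N_{t-1} - 1) * k_bar**2 / sigma2``
* constant-size simplification (``k_bar = 1``): ``Ne = (N - 1) / sigma2``

For a population whose census size changed over time, the multi-generation
effective size is the harmonic mean of the per-generation sizes, which is
dominated by the smallest (bottleneck) sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .population import OffspringCounts, VariantCounts

__all__ = [
    "InfluenceMoments",
    "SummaryStats",
    "influence_moments",
    "inbreeding_ne",
    "variance_ne",
    "simple_ne",
    "harmonic_mean_ne",
    "simpson_index",
    "unique_count",
    "summarize",
]


@dataclass
class InfluenceMoments:
    """First two moments of cultural influence in one generational step."""

    k_bar: float
    sigma2: float
    pool_size: int
    offspring_size: int


@dataclass
class SummaryStats:
    """Across-replicate mean with a 90% prediction interval (5th/95th pct)."""

    mean: float
    lower: float
    upper: float


def influence_moments(oc: OffspringCounts) -> InfluenceMoments:
    """Mean and population-convention variance of per-parent offspring counts.

    The divisor is the pool size (not pool - 1): this is the convention
    under which the simulated one-to-many variance matches its closed form
    ``(N - 1) / R`` exactly in expectation.
    """
    c = oc.counts
    if c.size == 0:
        raise ValueError("offspring counts must cover a non-empty parental pool")
    k_bar = float(c.mean())
    sigma2 = float(c.var())  # ddof=0, population convention
    return InfluenceMoments(k_bar, sigma2, oc.pool_size, oc.offspring_size)


def inbreeding_ne(m: InfluenceMoments) -> float:
    """Inbreeding effective size; NaN when the denominator is non-positive.

    Tied to the parental generation: the probability that two random
    offspring share the same cultural parent shrinks as the role-model
    pool grows, even when the number of learners does not.
    """
    if m.k_bar <= 0:
        return math.nan
    den = m.k_bar - 1.0 + m.sigma2 / m.k_bar
    if den <= 0:
        return math.nan
    return (m.pool_size * m.k_bar - 1.0) / den


def variance_ne(m: InfluenceMoments) -> float:
    """Variance effective size; NaN when sigma2 = 0 (drift-free generation)."""
    if m.sigma2 <= 0:
        return math.nan
    return (m.pool_size - 1.0) * m.k_bar**2 / m.sigma2


def simple_ne(N: int, sigma2: float) -> float:
    """Constant-size effective size (N - 1) / sigma2."""
    if N < 2:
        raise ValueError("simple_ne needs N >= 2")
    if sigma2 <= 0:
        raise ValueError("simple_ne is undefined for sigma2 <= 0")
    return (N - 1) / sigma2


def harmonic_mean_ne(sizes) -> float:
    """Multi-generation Ne: harmonic mean of per-generation census sizes."""
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size == 0:
        raise ValueError("need at least one generation size")
    if np.any(sizes < 1):
        raise ValueError("census sizes must be >= 1")
    return float(sps.hmean(sizes))


def _counts_array(counts) -> np.ndarray:
    if isinstance(counts, VariantCounts):
        return np.asarray(counts.counts, dtype=float)
    return np.asarray(counts, dtype=float)


def simpson_index(counts) -> float:
    """Simpson diversity D = 1 - sum((n_i / N)**2), in [0, 1 - 1/N].

    The probability that two randomly drawn individuals carry different
    variants; computed on the whole population, no finite-sample
    correction.
    """
    c = _counts_array(counts)
    if c.size == 0 or c.sum() <= 0:
        raise ValueError("need a non-empty population")
    f = c / c.sum()
    return float(1.0 - np.sum(f**2))


def unique_count(counts) -> int:
    """Number of distinct cultural variants present."""
    c = _counts_array(counts)
    if c.size == 0:
        raise ValueError("need a non-empty population")
    return int(np.count_nonzero(c))


def summarize(values) -> SummaryStats:
    """Across-replicate mean and empirical 90% prediction interval.

    Percentiles use linear interpolation; NaN entries (generations where an
    estimator was undefined) are excluded.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValueError("summarize needs at least two replicate values")
    lo, hi = np.percentile(v, [5.0, 95.0])
    return SummaryStats(float(v.mean()), float(lo), float(hi))
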