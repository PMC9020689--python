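"""Core cultural Wright-Fisher population with infinite-alleles innovation.

A population is a fixed-size collection of individuals, each carrying the
label of a single cultural variant. Generations are discrete and
non-overlapping: every generation, each naive learner either innovates
(adopting a brand-new variant label, probability ``mu``) or copies the
variant of a member of the parental role-model pool. The per-parent count of
learners who copied a given individual is that individual's *cultural
influence* (its number of cultural offspring); the moments of these counts
drive every effective-size estimator in :mod:`cultne.stats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Population",
    "VariantCounts",
    "OffspringCounts",
    "variant_counts",
    "unbiased_step",
    "drift_trajectory",
]


@dataclass
class Population:
    """One generation of ``N`` individuals and the global innovation counter.

    Parameters
    ----------
    variants
        Integer label of the cultural variant carried by each individual;
        length equals the census size ``N``.
    next_label
        Smallest label that has never been used. Labels are allocated
        sequentially so that no innovated label can collide with an existing
        one, even across coupled populations that share the counter.
    """

    variants: np.ndarray
    next_label: int

    def __post_init__(self) -> None:
        self.variants = np.asarray(self.variants, dtype=np.int64)
        if self.variants.ndim != 1 or self.variants.size < 1:
            raise ValueError("variants must be a non-empty 1-D sequence of labels")
        if self.variants.min() < 0:
            raise ValueError("variant labels must be non-negative integers")
        if int(self.variants.max()) >= self.next_label:
            raise ValueError("next_label must exceed every label currently in use")

    @property
    def N(self) -> int:
        """Census size (number of individuals)."""
        return self.variants.size

    @classmethod
    def all_distinct(cls, N: int) -> "Population":
        """Maximal-diversity start: every individual carries its own variant."""
        if N < 1:
            raise ValueError("N must be >= 1")
        return cls(np.arange(N, dtype=np.int64), N)

    @classmethod
    def monomorphic(cls, N: int, label: int = 0) -> "Population":
        """Single-variant population (useful for boundary cases)."""
        if N < 1:
            raise ValueError("N must be >= 1")
        return cls(np.full(N, label, dtype=np.int64), label + 1)


@dataclass
class VariantCounts:
    """Tally of variant frequencies ``n_i`` within one generation."""

    labels: np.ndarray
    counts: np.ndarray

    @property
    def M(self) -> int:
        """Number of distinct variants present."""
        return self.labels.size

    @property
    def total(self) -> int:
        """Sum of all counts; equals the census size."""
        return int(self.counts.sum())

    def as_dict(self) -> dict[int, int]:
        return {int(l): int(c) for l, c in zip(self.labels, self.counts)}


@dataclass
class OffspringCounts:
    """Per-parent cultural offspring counts for one generational step.

    ``counts`` has one entry per member of the eligible role-model pool
    (individuals outside the pool are not represented; eligible but uncopied
    individuals have count 0). Innovating learners have no cultural parent,
    so ``counts.sum() + n_innovators == offspring_size``.
    """

    counts: np.ndarray
    offspring_size: int
    n_innovators: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1 or self.counts.size < 1:
            raise ValueError("counts must be a non-empty 1-D array")
        if int(self.counts.sum()) + self.n_innovators != self.offspring_size:
            raise ValueError("counts + innovators must account for every learner")

    @property
    def pool_size(self) -> int:
        """Size of the eligible role-model pool (parental generation)."""
        return self.counts.size


def variant_counts(pop: Population) -> VariantCounts:
    """Tally the variant frequencies of a population."""
    labels, counts = np.unique(pop.variants, return_counts=True)
    return VariantCounts(labels, counts)


def _check_mu(mu: float) -> None:
    if not 0.0 <= mu <= 1.0:
        raise ValueError(f"innovation rate mu must lie in [0, 1], got {mu!r}")


def _innovate(child: np.ndarray, next_label: int, mu: float,
              rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, int]:
    """Overwrite a Bernoulli(mu) subset of learners with fresh labels.

    Returns the innovator mask, the updated child array and the advanced
    label counter.
    """
    n = child.size
    if mu == 0.0:
        return np.zeros(n, dtype=bool), child, next_label
    innovators = rng.random(n) < mu
    k = int(innovators.sum())
    if k:
        child[innovators] = next_label + np.arange(k, dtype=np.int64)
    return innovators, child, next_label + k


def unbiased_step(pop: Population, mu: float,
                  rng: np.random.Generator) -> tuple[Population, OffspringCounts]:
    """One generation of unbiased transmission.

    Each of the ``N`` learners independently innovates with probability
    ``mu`` or copies a uniformly random member of the parental generation;
    equivalently, it adopts variant ``i`` with probability
    ``(n_i / N) * (1 - mu)``.
    """
    _check_mu(mu)
    N = pop.N
    parents = rng.integers(0, N, size=N)
    child = pop.variants[parents].copy()
    innovators, child, next_label = _innovate(child, pop.next_label, mu, rng)
    counts = np.bincount(parents[~innovators], minlength=N)
    new = Population(child, next_label)
    return new, OffspringCounts(counts, N, int(innovators.sum()))


def drift_trajectory(N: int, p0: float, T: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Frequency of a focal variant under pure drift (two variants, mu = 0).

    The initial count is ``round(N * p0)``; each generation the count is
    binomially resampled. The frequencies 0 and 1 are absorbing. Returns the
    ``T + 1`` frequencies including the initial one.
    """
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("initial frequency p0 must lie in [0, 1]")
    if N < 1 or T < 0:
        raise ValueError("need N >= 1 and T >= 0")
    x = int(round(N * p0))
    freqs = np.empty(T + 1)
    freqs[0] = x / N
    for t in range(1, T + 1):
        if 0 < x < N:
            x = int(rng.binomial(N, x / N))
        freqs[t] = x / N
    return freqs
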