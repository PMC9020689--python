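"""Two-population connectedness: migration, cultural exchange, fixed influx.

Migration permanently swaps an equal random number of individuals between
two equal-size populations before each generation of unbiased learning.
Cultural exchange leaves everybody at home but lends a random subset of
each population to the other as *additional role models* for one
generation, enlarging the parental pool without changing census sizes.
The influx scenario grows a small focal population by a fixed number of
immigrants from a large source population every generation.

Both populations of a metapopulation share one innovation counter, so
variant labels remain globally unique and migrant variants are recognised
as new arrivals rather than coincidental re-inventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .population import OffspringCounts, Population, _check_mu, _innovate, unbiased_step

__all__ = ["Metapopulation", "swap_members", "migration_step", "exchange_step",
           "influx_step"]


@dataclass
class Metapopulation:
    """Two populations with a shared (synchronised) innovation counter."""

    pop_a: Population
    pop_b: Population

    def __post_init__(self) -> None:
        # keep the label counter global across both populations
        shared = max(self.pop_a.next_label, self.pop_b.next_label)
        self.pop_a.next_label = shared
        self.pop_b.next_label = shared

    @classmethod
    def independent(cls, N: int) -> "Metapopulation":
        """Two maximal-diversity populations with disjoint label ranges."""
        a = Population(np.arange(N, dtype=np.int64), 2 * N)
        b = Population(np.arange(N, 2 * N, dtype=np.int64), 2 * N)
        return cls(a, b)


def _paired_steps(pop_a: Population, pop_b: Population, mu: float,
                  rng: np.random.Generator):
    """Unbiased steps on both populations keeping labels globally unique."""
    new_a, oc_a = unbiased_step(pop_a, mu, rng)
    pop_b = Population(pop_b.variants, new_a.next_label)
    new_b, oc_b = unbiased_step(pop_b, mu, rng)
    new_a = Population(new_a.variants, new_b.next_label)
    return Metapopulation(new_a, new_b), (oc_a, oc_b)


def swap_members(meta: Metapopulation, m: float,
                 rng: np.random.Generator,
                 fixed_count: bool = False) -> Metapopulation:
    """Symmetric permanent migration between two equal-size populations.

    ``X`` individuals are chosen uniformly (disjoint sets) in each
    population and exchanged, keeping both census sizes exactly ``N``.
    ``X ~ Binomial(N, m)`` by default — an average of ``m * N`` migrants,
    each individual migrating independently; ``fixed_count=True`` uses the
    deterministic ``round(m * N)`` instead.
    """
    if not 0.0 <= m <= 1.0:
        raise ValueError(f"migration rate m must lie in [0, 1], got {m!r}")
    N = meta.pop_a.N
    if meta.pop_b.N != N:
        raise ValueError("migration requires equal-size populations")
    x = int(round(m * N)) if fixed_count else int(rng.binomial(N, m))
    va = meta.pop_a.variants.copy()
    vb = meta.pop_b.variants.copy()
    if x:
        ia = rng.choice(N, size=x, replace=False)
        ib = rng.choice(N, size=x, replace=False)
        va[ia], vb[ib] = meta.pop_b.variants[ib], meta.pop_a.variants[ia]
    label = meta.pop_a.next_label
    return Metapopulation(Population(va, label), Population(vb, label))


def migration_step(meta: Metapopulation, m: float, mu: float,
                   rng: np.random.Generator,
                   fixed_count: bool = False
                   ) -> tuple[Metapopulation, tuple[OffspringCounts, OffspringCounts]]:
    """Symmetric permanent migration followed by unbiased learning.

    Migrants (see :func:`swap_members`) carry their variants with them and
    serve as potential role models; each population then performs an
    independent unbiased step over its own post-migration parental
    generation.
    """
    _check_mu(mu)
    meta = swap_members(meta, m, rng, fixed_count=fixed_count)
    return _paired_steps(meta.pop_a, meta.pop_b, mu, rng)


def _exchange_one(home: Population, other: Population, e: float, mu: float,
                  rng: np.random.Generator) -> tuple[Population, OffspringCounts]:
    N = home.N
    x = int(rng.binomial(other.N, e))
    if x:
        borrowed = rng.choice(other.N, size=x, replace=False)
        pool = np.concatenate([home.variants, other.variants[borrowed]])
    else:
        pool = home.variants
    parents = rng.integers(0, pool.size, size=N)
    child = pool[parents].copy()
    innovators, child, next_label = _innovate(child, home.next_label, mu, rng)
    counts = np.bincount(parents[~innovators], minlength=pool.size)
    return Population(child, next_label), OffspringCounts(counts, N, int(innovators.sum()))


def exchange_step(meta: Metapopulation, e: float, mu: float,
                  rng: np.random.Generator) -> tuple[Metapopulation, tuple[OffspringCounts, OffspringCounts]]:
    """Cultural exchange: borrowed role models, no permanent movement.

    ``X ~ Binomial(N, e)`` members of the other population are appended to
    each population's role-model pool for this generation only, enlarging
    the parental generation to ``N + X`` while the offspring generation
    stays at ``N``. Offspring counts span the whole enlarged pool (home
    members first, borrowed members after), which is what drives the
    inbreeding effective size toward ``(N - 1)(1 + e)`` while the variance
    effective size stays near the census size.
    """
    if not 0.0 <= e <= 1.0:
        raise ValueError(f"cultural exchange rate e must lie in [0, 1], got {e!r}")
    _check_mu(mu)
    new_a, oc_a = _exchange_one(meta.pop_a, meta.pop_b, e, mu, rng)
    pop_b = Population(meta.pop_b.variants, new_a.next_label)
    new_b, oc_b = _exchange_one(pop_b, meta.pop_a, e, mu, rng)
    new_a = Population(new_a.variants, new_b.next_label)
    return Metapopulation(new_a, new_b), (oc_a, oc_b)


def influx_step(source: Population, focal: Population, influx_count: int,
                mu: float, rng: np.random.Generator,
                advance_source: bool = True
                ) -> tuple[Population, Population, OffspringCounts]:
    """Fixed per-generation immigration that grows the focal census size.

    ``influx_count`` individuals drawn uniformly from the source join the
    focal parental pool; the offspring generation then has
    ``N_t = N_{t-1} + influx_count`` learners, each copying uniformly from
    that pool (innovating with probability ``mu``). The source census is
    left unchanged (it is assumed large and at its own equilibrium); by
    default it also advances one unbiased generation so its variant
    spectrum keeps turning over. Returns the new source, the grown focal
    population, and the focal offspring counts (pool = previous focal
    members followed by the immigrants).
    """
    if influx_count < 0:
        raise ValueError("influx_count must be >= 0")
    if influx_count > source.N:
        raise ValueError("influx_count cannot exceed the source census size")
    _check_mu(mu)
    if influx_count:
        mig = rng.choice(source.N, size=influx_count, replace=False)
        pool = np.concatenate([focal.variants, source.variants[mig]])
    else:
        pool = focal.variants
    n_t = pool.size
    parents = rng.integers(0, n_t, size=n_t)
    child = pool[parents].copy()
    innovators, child, next_label = _innovate(child, focal.next_label, mu, rng)
    counts = np.bincount(parents[~innovators], minlength=n_t)
    new_focal = Population(child, next_label)
    oc = OffspringCounts(counts, n_t, int(innovators.sum()))
    new_source = Population(source.variants, next_label)
    if advance_source:
        new_source, _ = unbiased_step(new_source, mu, rng)
        new_focal = Population(new_focal.variants, new_source.next_label)
    return new_source, new_focal, oc
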