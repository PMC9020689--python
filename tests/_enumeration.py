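"""Brute-force one-step oracles shared by the oracle and acceptance tests.

For tiny populations the exact distribution of the next generation's
variant configuration can be enumerated directly from the adoption
probabilities, independently of the step operators under test.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats as sps


def compositions(total: int, parts: int):
    """All orderings of ``total`` into ``parts`` non-negative integers."""
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in compositions(total - first, parts - 1):
            yield (first,) + rest


def multinomial_distribution(probs: np.ndarray, n: int) -> dict[tuple, float]:
    """Exact distribution of next-generation variant counts.

    Each of ``n`` learners independently adopts variant ``i`` with
    probability ``probs[i]``; the outcome is the tuple of per-variant
    counts.
    """
    probs = np.asarray(probs, dtype=float)
    dist = {}
    for counts in compositions(n, probs.size):
        dist[counts] = float(sps.multinomial.pmf(counts, n, probs))
    return dist


def unbiased_distribution(variant_counts: np.ndarray) -> dict[tuple, float]:
    """Oracle for unbiased transmission with mu = 0."""
    c = np.asarray(variant_counts, dtype=float)
    return multinomial_distribution(c / c.sum(), int(c.sum()))


def frequency_dependent_distribution(variant_counts: np.ndarray,
                                     theta: float) -> dict[tuple, float]:
    """Oracle for frequency-dependent transmission with mu = 0."""
    c = np.asarray(variant_counts, dtype=float)
    w = c**theta
    return multinomial_distribution(w / w.sum(), int(c.sum()))


def one_to_many_distribution(variants: np.ndarray, labels: np.ndarray,
                             R: int) -> dict[tuple, float]:
    """Oracle for one-to-many transmission with mu = 0.

    Mixture over all equally likely role-model subsets of size ``R``; given
    a subset, learners copy variants with probabilities given by the
    subset's variant frequencies.
    """
    variants = np.asarray(variants)
    N = variants.size
    subsets = list(combinations(range(N), R))
    dist: dict[tuple, float] = {}
    for subset in subsets:
        sub = variants[list(subset)]
        probs = np.array([(sub == l).sum() for l in labels], dtype=float) / R
        for counts, p in multinomial_distribution(probs, N).items():
            dist[counts] = dist.get(counts, 0.0) + p / len(subsets)
    return dist


def chisquare_vs_oracle(observed: dict[tuple, int], oracle: dict[tuple, float],
                        draws: int, min_expected: float = 5.0) -> float:
    """Chi-square p-value of empirical outcome counts against the oracle.

    Outcomes with expected count below ``min_expected`` are pooled into a
    single tail category.
    """
    keys = sorted(oracle)
    exp = np.array([oracle[k] * draws for k in keys])
    obs = np.array([observed.get(k, 0) for k in keys], dtype=float)
    # anything the oracle assigns zero-ish mass must not have been observed
    unseen = sum(v for k, v in observed.items() if k not in oracle)
    assert unseen == 0, "step operator produced an outcome the oracle excludes"
    big = exp >= min_expected
    obs_pooled = np.append(obs[big], obs[~big].sum())
    exp_pooled = np.append(exp[big], exp[~big].sum())
    if exp_pooled[-1] == 0:
        obs_pooled, exp_pooled = obs_pooled[:-1], exp_pooled[:-1]
    exp_pooled *= obs_pooled.sum() / exp_pooled.sum()
    return float(sps.chisquare(obs_pooled, exp_pooled).pvalue)


def observe_counts(step, labels: np.ndarray, draws: int) -> dict[tuple, int]:
    """Empirical distribution of next-generation variant-count tuples."""
    observed: dict[tuple, int] = {}
    for _ in range(draws):
        pop = step()
        key = tuple(int((pop.variants == l).sum()) for l in labels)
        observed[key] = observed.get(key, 0) + 1
    return observed
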