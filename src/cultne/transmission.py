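"""Non-unbiased transmission modes and their closed-form expectations.

One-to-many transmission restricts the role-model pool to ``R`` randomly
designated individuals per generation; the variance of cultural influence is
then ``(N - 1) / R`` in expectation and the effective population size equals
``R``. Frequency-dependent transmission biases adoption toward common
(``theta > 1``, conformity) or rare (``theta < 1``, anti-conformity)
variants via adoption probabilities proportional to ``n_i ** theta``.
"""

from __future__ import annotations

import numpy as np

from .population import OffspringCounts, Population, _check_mu, _innovate

__all__ = [
    "one_to_many_step",
    "otm_sigma2",
    "otm_ne",
    "adoption_probabilities",
    "frequency_dependent_step",
]


def _check_R(N: int, R: int) -> None:
    if not 1 <= R <= N:
        raise ValueError(f"role-model count R must satisfy 1 <= R <= N, got R={R!r}")


def _check_theta(theta: float) -> None:
    if not theta > 0:
        raise ValueError(f"frequency-dependence exponent theta must be > 0, got {theta!r}")


def one_to_many_step(pop: Population, R: int, mu: float,
                     rng: np.random.Generator) -> tuple[Population, OffspringCounts]:
    """One generation in which only ``R`` random individuals may be copied.

    The ``R`` role models are redrawn uniformly without replacement each
    generation. Offspring counts cover all ``N`` parents: the ``N - R``
    non-role-models receive count 0, which is what makes the pooled variance
    of cultural influence equal ``(N - 1) / R`` in expectation.
    """
    _check_mu(mu)
    N = pop.N
    _check_R(N, R)
    models = rng.choice(N, size=R, replace=False)
    parents = models[rng.integers(0, R, size=N)]
    child = pop.variants[parents].copy()
    innovators, child, next_label = _innovate(child, pop.next_label, mu, rng)
    counts = np.bincount(parents[~innovators], minlength=N)
    return Population(child, next_label), OffspringCounts(counts, N, int(innovators.sum()))


def otm_sigma2(N: int, R: int) -> float:
    """Expected variance of cultural influence under one-to-many transmission."""
    _check_R(N, R)
    return (N - 1) / R


def otm_ne(N: int, R: int) -> float:
    """Effective size under one-to-many transmission: (N-1)/sigma2 = R."""
    return (N - 1) / otm_sigma2(N, R)


def adoption_probabilities(counts: np.ndarray, theta: float = 1.0,
                           mu: float = 0.0) -> np.ndarray:
    """Per-variant adoption probabilities ``n_i**theta / sum(n_m**theta) * (1-mu)``.

    With ``theta = 1`` this reduces exactly to unbiased transmission. The
    exponent is applied to absolute counts; normalisation makes this
    identical to applying it to relative frequencies.
    """
    _check_theta(theta)
    _check_mu(mu)
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0 or np.any(counts <= 0):
        raise ValueError("variant counts must be positive")
    w = counts ** theta
    return w / w.sum() * (1.0 - mu)


def frequency_dependent_step(pop: Population, theta: float, mu: float,
                             rng: np.random.Generator) -> tuple[Population, OffspringCounts]:
    """One generation of frequency-dependent transmission.

    Each learner innovates with probability ``mu`` or adopts variant ``i``
    with probability proportional to ``n_i ** theta``. A learner adopting
    variant ``i`` is credited as the cultural offspring of a uniformly
    random parent carrying that variant, which keeps influence per-parent
    and is the unique attribution symmetric among carriers.
    """
    _check_theta(theta)
    _check_mu(mu)
    N = pop.N
    labels, cnt = np.unique(pop.variants, return_counts=True)
    w = cnt.astype(float) ** theta
    probs = w / w.sum()
    vidx = rng.choice(labels.size, size=N, p=probs)
    # uniform carrier of the adopted variant: index into carriers sorted by label
    order = np.argsort(pop.variants, kind="stable")
    starts = np.concatenate(([0], np.cumsum(cnt)[:-1]))
    offset = (rng.random(N) * cnt[vidx]).astype(np.int64)
    parents = order[starts[vidx] + offset]
    child = labels[vidx].copy()
    innovators, child, next_label = _innovate(child, pop.next_label, mu, rng)
    counts = np.bincount(parents[~innovators], minlength=N)
    return Population(child, next_label), OffspringCounts(counts, N, int(innovators.sum()))
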