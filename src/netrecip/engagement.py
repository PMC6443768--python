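"""Abstention statistics of reciprocating cooperators.

A cooperator exploited by a neighbor abstains from playing that neighbor for
a random number of rounds.  After ``t - 1`` consecutive abstentions she
resumes play with the *engagement probability*

    p_t = 1 - (1 - delta_d)**t,   t >= 1,   p_0 = 1,

i.e. the probability that the exploiter has revised her strategy at least
once since the exploitation, computed at the reciprocity-biased update rate
``delta_d``.  The resulting distribution of the abstention-period length
``a`` (number of consecutive abstentions before the next play) is

    Prob(a) = delta_d                                        if a = 0,
    Prob(a) = (1-delta_d)**(a(a+1)/2) * (1 - (1-delta_d)**(a+1))  if a > 0.

There is no closed form for the mean ``<a>``; it is computed by series
summation with a controlled tail.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "engagement_probability",
    "abstention_pmf",
    "mean_abstention_length",
    "sample_abstention_length",
]


def engagement_probability(t, delta_d: float):
    """Probability p_t to play after t - 1 consecutive abstentions.

    ``t = 0`` is the fully-engaged state (p_0 = 1, reciprocating
    cooperation); for ``t >= 1``, p_t = 1 - (1 - delta_d)**t, strictly
    increasing in ``t`` with limit 1.  Accepts scalars or arrays.
    """
    if not 0.0 < delta_d <= 1.0:
        raise ValueError(f"delta_d must be in (0, 1], got {delta_d}")
    t = np.asarray(t)
    if np.any(t < 0):
        raise ValueError("abstention-state index t must be >= 0")
    p = 1.0 - (1.0 - delta_d) ** t
    p = np.where(t == 0, 1.0, p)
    return p if p.ndim else float(p)


def abstention_pmf(a, delta_d: float):
    """Probability of ``a`` consecutive abstentions followed by a play."""
    if not 0.0 < delta_d < 1.0:
        raise ValueError(f"delta_d must be in (0, 1), got {delta_d}")
    a = np.asarray(a)
    if np.any(a < 0):
        raise ValueError("abstention length a must be >= 0")
    q = 1.0 - delta_d
    p = q ** (a * (a + 1) / 2.0) * (1.0 - q ** (a + 1))
    p = np.where(a == 0, delta_d, p)
    return p if p.ndim else float(p)


def mean_abstention_length(delta_d: float, tail_tol: float = 1e-12) -> float:
    """Mean abstention-period length <a>, by truncated series summation.

    The series is cut when the residual tail mass of the length
    distribution drops below ``tail_tol``; the quadratic exponent in the
    pmf makes the tail collapse super-geometrically, so a few hundred terms
    suffice even for small ``delta_d``.  <a> is strictly decreasing in
    ``delta_d``.
    """
    if not 0.0 < delta_d < 1.0:
        raise ValueError(f"delta_d must be in (0, 1), got {delta_d}")
    mean = 0.0
    mass = abstention_pmf(0, delta_d)
    a = 0
    while 1.0 - mass >= tail_tol:
        a += 1
        p = abstention_pmf(a, delta_d)
        mean += a * p
        mass += p
        if a > 100_000:  # unreachable for delta_d in (0, 1); safety stop
            raise RuntimeError("abstention-length series failed to converge")
    return mean


def sample_abstention_length(delta_d: float, rng: np.random.Generator, size=None):
    """Draw abstention-period lengths by sequential engagement draws.

    Mirrors the in-game mechanism: after being exploited the cooperator
    abstains with probability 1 - p_1; after each further abstention she
    abstains again with probability 1 - p_{t+1}.  The empirical
    distribution converges to :func:`abstention_pmf`.
    """
    if not 0.0 < delta_d < 1.0:
        raise ValueError(f"delta_d must be in (0, 1), got {delta_d}")
    n = 1 if size is None else int(size)
    out = np.zeros(n, dtype=np.int64)
    active = np.arange(n)
    t = 1
    while active.size:
        p_t = engagement_probability(t, delta_d)
        abstain = rng.random(active.size) >= p_t
        out[active[abstain]] = t  # provisional: at least t abstentions
        active = active[abstain]
        t += 1
    return int(out[0]) if size is None else out
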