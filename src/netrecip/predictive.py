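"""Model-predictive strategy update and its analytic thresholds.

A revising agent classifies each neighbor from the pair of engagement
counters on the shared edge (perception), forecasts the probability of
actually playing that neighbor over each of the next ``h`` rounds under
both candidate strategies, and switches strategy iff the expected cumulated
payoff gain is strictly positive.

Forecast recursions (play probabilities over the horizon, seeded at the
current engagement p_t):

* against a defector who stays D, the agent's own future engagement is
  predicted by

      P_CD(1) = p_t,
      P_CD(s+1) = P_CD(s) * delta_d + (1 - P_CD(s)) * ((1-delta_d) * P_CD(s) + delta_d),

  which converges to the closed-form limit :func:`p_cd_limit` from any
  initialization;

* against a cooperator currently abstaining at state t (because the
  reviser exploited her), resumption is absorbing:

      P_CC(1) = p_t,   P_CC(s+1) = P_CC(s) + (1 - P_CC(s)) * p_{t+s}.

The expected gains are assembled from the horizon partial sums of these
sequences and are affine in the PD return r, which yields closed-form
remain-C and fixation thresholds in the infinite-horizon limit and a
numeric worst-case bound for finite horizons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dynamics import PopulationState, apply_strategy_change
from .engagement import engagement_probability
from .params import ModelParams

__all__ = [
    "NeighborPerception",
    "perceive_neighbors",
    "forecast_play_with_defector",
    "forecast_play_with_cooperator",
    "GainCalculator",
    "expected_gain_C",
    "expected_gain_D",
    "revise",
    "p_cd_limit",
    "remain_C_threshold",
    "fixation_threshold_infinite",
    "fixation_threshold_bound",
]


@dataclass(frozen=True)
class NeighborPerception:
    """What a revising agent can infer about one neighbor.

    ``perceived_c`` is the inferred strategy; ``state`` the abstention
    counter seeding the forecast recursions; ``from_own_counter`` marks
    whether the reviser's own counter (rather than the neighbor's) produced
    the perception.
    """

    neighbor: int
    perceived_c: bool
    state: int
    from_own_counter: bool = False


def perceive_neighbors(state: PopulationState, agent: int) -> list[NeighborPerception]:
    """Classify each neighbor of ``agent`` from the edge counters.

    For a revising cooperator i: her own counter t_ij > 0 means j exploited
    her at their last interaction, so j is perceived D (at D-state t_ij) —
    possibly stale if j has since switched, so a C can under-count her
    C-neighbors, never over-count.  t_ij = 0 with t_ji > 0 means j abstains
    because i exploited j, so j is correctly perceived C (at C-state t_ji);
    both zero means the last interaction was mutual cooperation (perceived
    C at state 0).

    For a revising defector i: t_ji > 0 identifies an abstaining cooperator
    (perceived C at state t_ji), otherwise the last interaction was mutual
    defection (perceived D).  Defectors thus have full information.
    """
    if not 0 <= agent < state.network.n_nodes:
        raise IndexError(f"unknown agent index {agent}")
    eidx, side = state.network.incidence()[agent]
    nbrs = state.network.edges[eidx, 1 - side]
    t_mine = state.t[eidx, side]
    t_theirs = state.t[eidx, 1 - side]
    out = []
    if state.is_c[agent]:
        for j, tij, tji in zip(nbrs, t_mine, t_theirs):
            if tij > 0:
                out.append(NeighborPerception(int(j), False, int(tij), True))
            else:
                out.append(NeighborPerception(int(j), True, int(tji), False))
    else:
        for j, tji in zip(nbrs, t_theirs):
            if tji > 0:
                out.append(NeighborPerception(int(j), True, int(tji), False))
            else:
                out.append(NeighborPerception(int(j), False, 0, False))
    return out


def forecast_play_with_defector(t_init: int, delta_d: float, h: int) -> np.ndarray:
    """Forecast play probabilities over ``h`` rounds against a steady D."""
    if h < 1:
        raise ValueError("horizon h must be >= 1")
    if t_init < 0:
        raise ValueError("state index must be >= 0")
    out = np.empty(h)
    p = engagement_probability(t_init, delta_d)
    out[0] = p
    for s in range(1, h):
        p = p * delta_d + (1.0 - p) * ((1.0 - delta_d) * p + delta_d)
        out[s] = p
    return out


def forecast_play_with_cooperator(t_ji: int, delta_d: float, h: int) -> np.ndarray:
    """Forecast play probabilities over ``h`` rounds against a steady C.

    The neighbor abstains at state ``t_ji``; once she resumes, mutual
    cooperation re-engages both sides for good, so the sequence is
    nondecreasing with limit 1.
    """
    if h < 1:
        raise ValueError("horizon h must be >= 1")
    if t_ji < 0:
        raise ValueError("state index must be >= 0")
    out = np.empty(h)
    p = engagement_probability(t_ji, delta_d)
    out[0] = p
    for s in range(1, h):
        p = p + (1.0 - p) * engagement_probability(t_ji + s, delta_d)
        out[s] = p
    return out


class GainCalculator:
    """Horizon partial sums of the forecasts, cached per abstention state.

    The expected-gain formulas only need S_CC(t) = sum_{s=1..h} P_CC^s(t)
    and S_CD(t) = sum_{s=1..h} P_CD^s(t); caching them by state keeps the
    per-revision cost at O(neighbors).

    With ``h = math.inf`` the calculator returns per-round payoff *rates*
    instead of horizon sums: S_CC/h -> 1 and S_CD/h -> the forecast limit,
    independently of the seeding state.  Gains built from these rates have
    the sign of the infinite-horizon closed-form conditions (a revision at
    an exact threshold has rate gain 0 and keeps the current strategy).
    """

    def __init__(self, delta_d: float, h):
        self.delta_d = delta_d
        self.h = h
        self.infinite = isinstance(h, float) and math.isinf(h)
        self._p_inf = p_cd_limit(delta_d) if self.infinite else None
        self._s_cc: dict[int, float] = {}
        self._s_cd: dict[int, float] = {}

    def s_cc(self, t: int) -> float:
        if self.infinite:
            return 1.0
        if t not in self._s_cc:
            self._s_cc[t] = float(
                forecast_play_with_cooperator(t, self.delta_d, self.h).sum()
            )
        return self._s_cc[t]

    def s_cd(self, t: int) -> float:
        if self.infinite:
            return self._p_inf
        if t not in self._s_cd:
            self._s_cd[t] = float(
                forecast_play_with_defector(t, self.delta_d, self.h).sum()
            )
        return self._s_cd[t]

    def gain_c(self, perceptions, r: float) -> float:
        """Expected gain of a cooperator for switching to D (> 0: switch).

        Per perceived-C neighbor at state t: as a C she earns (r-1) per
        played round (play prob P_CC), as a D she exploits the neighbor
        (earns r) with play prob P_CD seeded at the same state; per
        perceived-D neighbor at state t she loses 1 per played round as a C
        and earns 0 as a D.
        """
        gain = 0.0
        for p in perceptions:
            if p.perceived_c:
                s_cc = self.s_cc(p.state)
                gain += -r * (s_cc - self.s_cd(p.state)) + s_cc
            else:
                gain += self.s_cd(p.state)
        return gain

    def gain_d(self, perceptions, r: float) -> float:
        """Expected gain of a defector for switching to C (> 0: switch).

        Perceived-C neighbors (abstaining at state t >= 1) would be
        exploited further as a D (play prob P_CD) or reciprocated as a C
        (play prob P_CC); toward perceived-D neighbors a fresh C guards at
        counter 1 (p = delta_d) and only expects exploitation losses.
        """
        gain = 0.0
        for p in perceptions:
            if p.perceived_c:
                s_cc = self.s_cc(p.state)
                gain += r * (s_cc - self.s_cd(p.state)) - s_cc
            else:
                gain -= self.s_cd(1)
        return gain


def expected_gain_C(perceptions, r: float, h: int, delta_d: float) -> float:
    """Expected payoff gain of a revising C for switching to D."""
    return GainCalculator(delta_d, h).gain_c(perceptions, r)


def expected_gain_D(perceptions, r: float, h: int, delta_d: float) -> float:
    """Expected payoff gain of a revising D for switching to C."""
    return GainCalculator(delta_d, h).gain_d(perceptions, r)


def revise(
    state: PopulationState,
    agent: int,
    params: ModelParams,
    rng: np.random.Generator | None = None,
    calc: GainCalculator | None = None,
    apply: bool = True,
    perceptions: list[NeighborPerception] | None = None,
    perceived_t: np.ndarray | None = None,
) -> str:
    """Revise one agent's strategy; returns ``'keep'`` or ``'switch'``.

    The switch happens iff the expected gain is strictly positive (ties
    keep the current strategy).  ``params.perturbation`` adds gain noise
    and decision flips (consuming ``rng`` draws only when active).  When
    ``apply`` is False the decision is returned without side effects;
    ``perceptions``/``perceived_t`` allow batching several revisions off a
    common pre-revision snapshot.
    """
    if calc is None:
        calc = GainCalculator(params.delta_d, params.h)
    if perceptions is None:
        perceptions = perceive_neighbors(state, agent)
    was_c = bool(state.is_c[agent])
    gain = calc.gain_c(perceptions, params.r) if was_c else calc.gain_d(perceptions, params.r)

    pert = params.perturbation
    if pert is not None and pert.gain_noise_sd > 0:
        if rng is None:
            raise ValueError("perturbed revision requires an rng")
        gain *= 1.0 + pert.gain_noise_sd * rng.standard_normal()
    switch = gain > 0.0
    if pert is not None and pert.decision_flip_prob > 0:
        if rng is None:
            raise ValueError("perturbed revision requires an rng")
        if rng.random() < pert.decision_flip_prob:
            switch = not switch
    if switch and apply:
        apply_strategy_change(
            state, agent, "D" if was_c else "C", perceived_t=perceived_t
        )
    return "switch" if switch else "keep"


# -- analytic thresholds ---------------------------------------------------


def p_cd_limit(delta_d: float) -> float:
    """Infinite-horizon limit of the play-with-defector forecast.

    Closed form (1/2) (sqrt(4 delta_d - 3 delta_d^2) - delta_d) / (1 - delta_d),
    increasing from 0 to 1 with delta_d and ~ sqrt(delta_d) for small
    delta_d; it is the unique fixed point in (0, 1) of the P_CD recursion.
    """
    if delta_d <= 0:
        raise ValueError("delta_d must be > 0")
    if delta_d >= 1:
        return 1.0
    return 0.5 * (math.sqrt(4 * delta_d - 3 * delta_d**2) - delta_d) / (1 - delta_d)


def remain_C_threshold(k: int, k_c: int, delta_d: float) -> float:
    """Infinite-horizon PD return above which a C with (k, k_c) remains C.

    r > 1 + (k / k_c) * P / (1 - P) with P the forecast limit; the same
    condition makes a D with the identical neighborhood switch to C.  A
    cooperator with no perceived C-neighbor (k_c = 0) defects at any
    return: the threshold is infinite.
    """
    if k_c < 0 or k < k_c:
        raise ValueError("need k >= k_c >= 0")
    if k_c == 0:
        return math.inf
    p = p_cd_limit(delta_d)
    return 1.0 + (k / k_c) * p / (1.0 - p)


def fixation_threshold_infinite(k_max: int, delta_d: float) -> float:
    """Infinite-horizon fixation threshold, worst case over the network.

    Equals the remain-C threshold of the maximal-degree node with a single
    perceived C-neighbor: 1 + k_max * P / (1 - P).
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    return remain_C_threshold(k_max, 1, delta_d)


def fixation_threshold_bound(
    k_max: int, h: int, delta_d: float, state_tail_tol: float = 1e-6
) -> float:
    """Finite-horizon upper bound on the fixation threshold.

    Both expected gains are affine in r for a fixed neighborhood, so each
    neighborhood configuration has a single r-root.  The bound scans the
    worst case at the maximal-degree node with one perceived C-neighbor:
    C-neighbor states {0, 1} for a revising C, all reachable states for a
    revising D, and defector states up to the counter at which the
    engagement probability is within ``state_tail_tol`` of 1.  The returned
    value is the smallest r above which every C keeps C and every D with a
    C-neighbor switches to C; it decreases toward
    :func:`fixation_threshold_infinite` as h grows.
    """
    if h < 2:
        raise ValueError("the finite-horizon bound requires h >= 2")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    calc = GainCalculator(delta_d, h)
    t_max = max(1, math.ceil(math.log(state_tail_tol) / math.log(1.0 - delta_d)))
    s_cd_worst = max(calc.s_cd(t) for t in range(1, t_max + 1))

    # revising C at the k_max node: gain_c = -r*(scc - scd) + scc + (k-1)*S_D
    r_c = max(
        (calc.s_cc(tc) + (k_max - 1) * s_cd_worst)
        / (calc.s_cc(tc) - calc.s_cd(tc))
        for tc in (0, 1)
    )
    # revising D: gain_d = r*(scc - scd) - scc - (k-1)*s_cd(1);
    # an abstaining C-neighbor of a D has state >= 1
    r_d = max(
        (calc.s_cc(tc) + (k_max - 1) * calc.s_cd(1))
        / (calc.s_cc(tc) - calc.s_cd(tc))
        for tc in range(1, t_max + 1)
    )
    return max(r_c, r_d)
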