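"""One game round of the networked PD with selective abstention.

Every agent plays a one-shot PD with each neighbor at every round.
Cooperators additionally hold, per neighbor, an abstention counter ``t``
encoding their engagement probability ``p_t`` toward that neighbor
(:func:`netrecip.engagement.engagement_probability`): ``t = 0`` means full
engagement (p = 1), ``t >= 1`` means the cooperator was exploited by that
neighbor ``t - 1`` abstentions ago and plays the next round only with
probability ``p_t``.  Defectors always play (all their counters are 0), so
for every edge at least one side's counter is 0 and an interaction happens
iff both sides agree to play.

Stage payoffs (cost c = 1, benefit b = r): mutual cooperation gives r - 1
to both, a cooperator exploited by a defector gets -1 while the defector
pockets r, mutual defection gives 0, and any abstention voids the
interaction (0 for both).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .networks import Network, StrategyAssignment
from .params import ModelParams

__all__ = ["PopulationState", "stage_payoffs", "play_round", "apply_strategy_change"]


def stage_payoffs(action_i: str, action_j: str, r: float) -> tuple[float, float]:
    """Payoff pair for one pairwise stage; actions in {'C', 'D', 'A'}."""
    for a in (action_i, action_j):
        if a not in ("C", "D", "A"):
            raise ValueError(f"invalid action {a!r}")
    if "A" in (action_i, action_j):
        return (0.0, 0.0)
    table = {
        ("C", "C"): (r - 1.0, r - 1.0),
        ("C", "D"): (-1.0, r),
        ("D", "C"): (r, -1.0),
        ("D", "D"): (0.0, 0.0),
    }
    return table[(action_i, action_j)]


@dataclass
class PopulationState:
    """Strategies plus the dynamic engagement state of every directed edge.

    ``t[e, 0]`` is the abstention counter of node ``edges[e, 0]`` toward
    ``edges[e, 1]``; ``t[e, 1]`` the reverse.  Initially all counters are 0
    (everyone fully engaged).  ``payoffs`` holds the per-agent payoff of the
    last played round (payoffs are per round; no memory is kept).
    """

    network: Network
    is_c: np.ndarray
    t: np.ndarray = field(default=None)
    round: int = 0
    payoffs: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if isinstance(self.is_c, StrategyAssignment):
            self.is_c = self.is_c.is_c
        self.is_c = np.asarray(self.is_c, dtype=bool).copy()
        if self.is_c.shape != (self.network.n_nodes,):
            raise ValueError("strategy vector length must equal the node count")
        if self.t is None:
            self.t = np.zeros((self.network.n_edges, 2), dtype=np.int64)
        if self.payoffs is None:
            self.payoffs = np.zeros(self.network.n_nodes)

    @property
    def fraction_c(self) -> float:
        return float(self.is_c.mean())

    def n_inhibited_edges(self) -> int:
        """Number of directed edge sides with engagement p < 1."""
        return int((self.t > 0).sum())

    def check_invariants(self) -> None:
        """Raise if the engagement bookkeeping is inconsistent.

        For every edge at least one side is fully engaged, and defectors are
        fully engaged toward all neighbors.
        """
        if np.any((self.t[:, 0] > 0) & (self.t[:, 1] > 0)):
            raise AssertionError("both sides of an edge have p < 1")
        e = self.network.edges
        if np.any(self.t[~self.is_c[e[:, 0]], 0] > 0) or np.any(
            self.t[~self.is_c[e[:, 1]], 1] > 0
        ):
            raise AssertionError("a defector holds an abstention counter > 0")

    def copy(self) -> "PopulationState":
        return PopulationState(
            network=self.network,
            is_c=self.is_c.copy(),
            t=self.t.copy(),
            round=self.round,
            payoffs=self.payoffs.copy(),
        )


def play_round(
    state: PopulationState, params: ModelParams, rng: np.random.Generator
) -> np.ndarray:
    """Play one simultaneous round of pairwise interactions; mutate ``state``.

    All participation draws are made at the start of the round (one uniform
    per directed edge side; sides at counter 0 always participate).  The
    (i, j) PD is played iff both sides participate; payoffs follow
    :func:`stage_payoffs` with abstention replacing a cooperator's action
    when she does not participate.  After the round the counters update:
    a cooperator exploited by a playing defector moves to counter 1
    (p = delta_d); one who abstained increments her counter; one who played
    against a cooperating opponent resets to 0 (reciprocating cooperation);
    one who played while the opponent abstained learns nothing and keeps
    her counter.
    """
    net = state.network
    e = net.edges
    t = state.t
    dd = params.delta_d

    draws = rng.random((net.n_edges, 2))
    p = np.where(t == 0, 1.0, 1.0 - (1.0 - dd) ** t)
    participate = (t == 0) | (draws < p)
    played = participate[:, 0] & participate[:, 1]

    cu = state.is_c[e[:, 0]]
    cv = state.is_c[e[:, 1]]
    payoffs = np.zeros(net.n_nodes)
    both_c = played & cu & cv
    u_exploited = played & cu & ~cv
    v_exploited = played & ~cu & cv
    r = params.r
    np.add.at(payoffs, e[both_c, 0], r - 1.0)
    np.add.at(payoffs, e[both_c, 1], r - 1.0)
    np.add.at(payoffs, e[u_exploited, 0], -1.0)
    np.add.at(payoffs, e[u_exploited, 1], r)
    np.add.at(payoffs, e[v_exploited, 1], -1.0)
    np.add.at(payoffs, e[v_exploited, 0], r)

    for side, mine_c, opp_c in ((0, cu, cv), (1, cv, cu)):
        abstained = mine_c & ~participate[:, side]
        t[abstained, side] += 1
        played_c = mine_c & played
        t[played_c & ~opp_c, side] = 1
        t[played_c & opp_c, side] = 0
        # participating against an abstaining opponent: counter unchanged

    state.payoffs = payoffs
    state.round += 1
    return payoffs


def apply_strategy_change(
    state: PopulationState,
    agent: int,
    new_strategy: str,
    perceived_t: np.ndarray | None = None,
) -> None:
    """Switch ``agent`` to ``new_strategy`` and update her engagement row.

    A cooperator turning defector re-engages fully (all her counters reset
    to 0: defectors always play).  A defector turning cooperator guards
    against immediate exploitation: she sets counter 1 (p = delta_d) toward
    neighbors she perceives as defectors (their counter toward her is 0)
    and 0 toward perceived cooperators (their counter toward her is > 0,
    i.e. they are abstaining because she exploited them).

    ``perceived_t`` optionally supplies the opposite-side counters as
    perceived *before* a batch of simultaneous revisions, so that several
    agents can switch based on a common pre-revision state.  A no-op change
    (same strategy) leaves the state untouched.
    """
    if not 0 <= agent < state.network.n_nodes:
        raise IndexError(f"unknown agent index {agent}")
    if new_strategy not in ("C", "D"):
        raise ValueError(f"invalid strategy {new_strategy!r}")
    currently_c = bool(state.is_c[agent])
    if (new_strategy == "C") == currently_c:
        return
    eidx, side = state.network.incidence()[agent]
    if new_strategy == "D":
        state.is_c[agent] = False
        state.t[eidx, side] = 0
    else:
        state.is_c[agent] = True
        t_opp = (
            perceived_t
            if perceived_t is not None
            else state.t[eidx, 1 - side]
        )
        state.t[eidx, side] = np.where(t_opp > 0, 0, 1)
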