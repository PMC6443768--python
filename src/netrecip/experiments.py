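"""Evolutionary runs, return sweeps, and invasion experiments.

The evolutionary loop alternates one simultaneous game round with an
asynchronous revision step: after each round every agent is independently
flagged with probability ``delta``; flagged agents decide from the common
post-round state and all switches are applied simultaneously.  The all-D
state is always absorbing; all-C is declared absorbed only when every
counter is back to 0 and the remain-C condition holds at the run's horizon
(so that no revision can ever switch anyone again).

Return sweeps over an r-grid estimate the empirical invasion threshold
``r_inv`` (smallest grid return whose mean final cooperation exceeds the
initial fraction) and fixation threshold ``r_fix`` (smallest grid return at
which every replicate absorbs at all-C).  Single-seed experiments estimate
the first-mover race probability and the fixation probability from one
initial cooperator.  A pairwise-comparison imitation baseline (strong
selection) is included as the classical comparator.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import PopulationState, apply_strategy_change, play_round
from .networks import (
    Network,
    StrategyAssignment,
    assign_initial_strategies,
    build_lattice,
    build_random_network,
)
from .params import ModelParams, RationalityPerturbation
from .predictive import GainCalculator, perceive_neighbors, revise

__all__ = [
    "Trajectory",
    "SweepResult",
    "run",
    "sweep_return",
    "estimate_single_seed_fixation",
    "estimate_first_mover_race",
    "imitation_baseline_run",
    "perturb_rationality",
]

_SEED_MOD = 2**31


@dataclass
class Trajectory:
    """Cooperation level over rounds with absorption bookkeeping."""

    fraction_c: np.ndarray
    absorbed: str  # 'all_C' | 'all_D' | 'none'
    absorption_round: int | None
    rounds: int
    final_state: PopulationState | None = None
    stats: pd.DataFrame | None = None

    @property
    def final_fraction(self) -> float:
        return float(self.fraction_c[-1])


@dataclass
class SweepResult:
    """Outcome table of a return sweep with estimated thresholds."""

    table: pd.DataFrame  # columns: r, replicate, final_fraction, absorbed, absorption_round
    r_inv: float
    r_fix: float
    initial_fraction: float

    def summary(self) -> pd.DataFrame:
        """Per-return mean final fraction and outcome shares."""
        g = self.table.groupby("r")
        out = pd.DataFrame(
            {
                "mean_final_fraction": g["final_fraction"].mean(),
                "share_all_D": g.apply(
                    lambda d: (d["absorbed"] == "all_D").mean(), include_groups=False
                ),
                "share_all_C": g.apply(
                    lambda d: (d["absorbed"] == "all_C").mean(), include_groups=False
                ),
                "share_interior": g.apply(
                    lambda d: (d["absorbed"] == "none").mean(), include_groups=False
                ),
                "share_slow_fixation": g.apply(
                    lambda d: (
                        (d["absorbed"] == "none") & (d["final_fraction"] > 0.2)
                    ).mean(),
                    include_groups=False,
                ),
            }
        )
        return out.reset_index()


def _all_c_is_stable(params: ModelParams) -> bool:
    """Whether a fully cooperative, fully engaged population is absorbing.

    At all-C with zero counters every reviser sees only C-neighbors at
    state 0, so the gain for defecting is degree * (-r (h - S_CD(0)) + h);
    the sign does not depend on the degree.
    """
    calc = GainCalculator(params.delta_d, params.h)
    s_cc0 = calc.s_cc(0)
    return -params.r * (s_cc0 - calc.s_cd(0)) + s_cc0 <= 0.0


def _revision_step(
    state: PopulationState,
    params: ModelParams,
    rng: np.random.Generator,
    calc: GainCalculator,
) -> int:
    """Flag agents at rate delta, decide from the common state, apply.

    Returns the number of strategy switches.  All decisions (and the
    perceived opposite-side counters a fresh cooperator needs) are computed
    before any switch is applied, so simultaneous revisions cannot see each
    other.
    """
    flagged = np.flatnonzero(rng.random(state.network.n_nodes) < params.delta)
    if not flagged.size:
        return 0
    pending = []
    for agent in flagged:
        eidx, side = state.network.incidence()[agent]
        perceptions = perceive_neighbors(state, agent)
        decision = revise(
            state, agent, params, rng=rng, calc=calc, apply=False, perceptions=perceptions
        )
        if decision == "switch":
            new = "D" if state.is_c[agent] else "C"
            pending.append((int(agent), new, state.t[eidx, 1 - side].copy()))
    for agent, new, t_opp in pending:
        apply_strategy_change(state, agent, new, perceived_t=t_opp)
    return len(pending)


def run(
    network: Network,
    initial_strategies: StrategyAssignment | np.ndarray,
    params: ModelParams,
    max_rounds: int,
    seed: int | None = None,
    detect_absorption: bool = True,
    collect_stats: bool = False,
    stop_when=None,
) -> Trajectory:
    """Run the evolutionary dynamics for up to ``max_rounds`` game rounds.

    A single rng stream (from ``seed``) drives participation draws,
    revision flags and any rationality perturbation, in fixed edge/node
    order, so identical seeds give identical trajectories.  ``stop_when``
    is an optional ``f(state, round) -> bool`` early-stop predicate (used
    by the race experiments).
    """
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    if not network.is_connected():
        raise ValueError("the network must be connected")
    state = PopulationState(network=network, is_c=initial_strategies)
    rng = np.random.default_rng(seed)
    calc = GainCalculator(params.delta_d, params.h)
    all_c_stable = _all_c_is_stable(params)

    fractions = [state.fraction_c]
    stats_rows = [] if collect_stats else None
    absorbed, absorption_round = "none", None

    for rnd in range(1, max_rounds + 1):
        payoffs = play_round(state, params, rng)
        _revision_step(state, params, rng, calc)
        fractions.append(state.fraction_c)
        if collect_stats:
            c = state.is_c
            stats_rows.append(
                {
                    "round": rnd,
                    "fraction_C": state.fraction_c,
                    "mean_payoff_C": float(payoffs[c].mean()) if c.any() else math.nan,
                    "mean_payoff_D": float(payoffs[~c].mean()) if (~c).any() else math.nan,
                    "inhibited_edges": state.n_inhibited_edges(),
                }
            )
        if detect_absorption:
            if not state.is_c.any():
                absorbed, absorption_round = "all_D", rnd
                break
            if (
                state.is_c.all()
                and all_c_stable
                and not state.t.any()
            ):
                absorbed, absorption_round = "all_C", rnd
                break
        if stop_when is not None and stop_when(state, rnd):
            break

    return Trajectory(
        fraction_c=np.array(fractions),
        absorbed=absorbed,
        absorption_round=absorption_round,
        rounds=state.round,
        final_state=state,
        stats=pd.DataFrame(stats_rows) if collect_stats else None,
    )


def _materialize_network(network_spec, rep_seed: int | None) -> Network:
    """Turn a sweep network spec into a Network for one replicate."""
    if isinstance(network_spec, Network):
        return network_spec
    if callable(network_spec):
        return network_spec(rep_seed)
    spec = dict(network_spec)
    if "kind" in spec:
        return build_lattice(spec["kind"], spec["n"])
    return build_random_network(
        spec["model"],
        spec["n"],
        mean_degree=spec.get("mean_degree"),
        seed=rep_seed,
        transitivity=spec.get("transitivity"),
    )


def sweep_return(
    network_spec,
    r_grid,
    replicates: int,
    params: ModelParams,
    max_rounds: int,
    seed: int | None = None,
    scheme: str = "random",
    count_c: int | None = None,
    initial_fraction: float = 0.01,
) -> SweepResult:
    """Sweep the PD return over ``r_grid`` and estimate r_inv and r_fix.

    ``network_spec`` may be a fixed :class:`Network` (lattices), a dict
    spec, or a callable ``seed -> Network``; random networks are
    regenerated per replicate.  Initial cooperators (``count_c``, default
    ``initial_fraction`` of N) are placed per ``scheme`` with a fresh seed
    per replicate.  ``params.r`` is overridden by each grid value.
    """
    r_grid = list(r_grid)
    if not r_grid:
        raise ValueError("empty r grid")
    if sorted(r_grid) != r_grid:
        raise ValueError("r_grid must be increasing")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")

    master = np.random.default_rng(seed)
    rows = []
    init_fracs = []
    for rep in range(replicates):
        net_seed, place_seed = (int(s) for s in master.integers(_SEED_MOD, size=2))
        run_seeds = master.integers(_SEED_MOD, size=len(r_grid))
        net = _materialize_network(network_spec, net_seed)
        n_c = count_c if count_c is not None else max(1, round(initial_fraction * net.n_nodes))
        init = assign_initial_strategies(net, scheme, n_c, seed=place_seed)
        init_fracs.append(n_c / net.n_nodes)
        for r, run_seed in zip(r_grid, run_seeds):
            p = dataclasses.replace(params, r=float(r))
            traj = run(net, init, p, max_rounds, seed=int(run_seed))
            rows.append(
                {
                    "r": float(r),
                    "replicate": rep,
                    "final_fraction": traj.final_fraction,
                    "absorbed": traj.absorbed,
                    "absorption_round": traj.absorption_round,
                }
            )
    table = pd.DataFrame(rows)
    f0 = float(np.mean(init_fracs))

    mean_final = table.groupby("r")["final_fraction"].mean()
    above = mean_final[mean_final > f0]
    r_inv = float(above.index.min()) if len(above) else math.nan
    all_c = table.groupby("r").apply(
        lambda d: (d["absorbed"] == "all_C").all(), include_groups=False
    )
    fixed = all_c[all_c]
    r_fix = float(fixed.index.min()) if len(fixed) else math.nan
    return SweepResult(table=table, r_inv=r_inv, r_fix=r_fix, initial_fraction=f0)


def estimate_single_seed_fixation(
    network: Network,
    seed_node: int,
    params: ModelParams,
    replicates: int,
    seed: int | None = None,
    max_rounds: int = 20_000,
) -> dict:
    """Monte-Carlo fixation probability from a single initial cooperator.

    Returns the share of replicates absorbed at all-C with its binomial
    standard error; replicates not absorbed within ``max_rounds`` count as
    non-fixation (and are reported separately).
    """
    master = np.random.default_rng(seed)
    init = assign_initial_strategies(network, "single", 1, node=seed_node)
    n_fix = n_ext = n_open = 0
    for run_seed in master.integers(_SEED_MOD, size=replicates):
        traj = run(network, init, params, max_rounds, seed=int(run_seed))
        if traj.absorbed == "all_C":
            n_fix += 1
        elif traj.absorbed == "all_D":
            n_ext += 1
        else:
            n_open += 1
    p = n_fix / replicates
    return {
        "fixation_probability": p,
        "standard_error": math.sqrt(p * (1.0 - p) / replicates),
        "replicates": replicates,
        "n_fixed": n_fix,
        "n_extinct": n_ext,
        "n_unresolved": n_open,
    }


def estimate_first_mover_race(
    network: Network,
    seed_node: int,
    params: ModelParams,
    replicates: int,
    seed: int | None = None,
    max_rounds: int = 100_000,
) -> dict:
    """Who moves first: a D-neighbor turning C, or the lone C defecting?

    Starting from a single cooperator at ``seed_node`` (who, being isolated,
    defects as soon as she revises), each replicate runs until either the
    focal agent has switched to D or some neighbor has switched to C.  For
    small delta the D-first probability approaches 1 - 1/(k + 1) where k is
    the focal degree, provided r is above the neighbors' switch threshold.
    Simultaneous switches in the same round count as a focal-first outcome
    (conservative; they occur with probability O(delta)).
    """
    master = np.random.default_rng(seed)
    init = assign_initial_strategies(network, "single", 1, node=seed_node)
    nbrs = network.neighbors(seed_node)
    d_first = 0
    for run_seed in master.integers(_SEED_MOD, size=replicates):
        outcome = {}

        def decided(state, rnd):
            focal_defected = not state.is_c[seed_node]
            neighbor_cooperates = state.is_c[nbrs].any()
            if focal_defected or neighbor_cooperates:
                outcome["d_first"] = neighbor_cooperates and not focal_defected
                return True
            return False

        run(
            network,
            init,
            params,
            max_rounds,
            seed=int(run_seed),
            detect_absorption=False,
            stop_when=decided,
        )
        d_first += bool(outcome.get("d_first", False))
    p = d_first / replicates
    return {
        "d_first_probability": p,
        "standard_error": math.sqrt(p * (1.0 - p) / replicates),
        "replicates": replicates,
    }


def imitation_baseline_run(
    network: Network,
    initial_strategies: StrategyAssignment | np.ndarray,
    r: float,
    max_rounds: int,
    seed: int | None = None,
    delta: float = 0.05,
) -> Trajectory:
    """Unconditional C vs D under pairwise-comparison imitation.

    Each round every pair of neighbors plays the PD unconditionally (no
    abstention) and payoffs accumulate per round.  Revising agents (rate
    ``delta``) compare with one uniformly chosen neighbor and copy her
    strategy iff her round payoff is strictly higher — the strong-selection
    limit of the pairwise-comparison (Fermi) rule.  Both monomorphic states
    absorb.
    """
    if isinstance(initial_strategies, StrategyAssignment):
        is_c = initial_strategies.is_c.copy()
    else:
        is_c = np.asarray(initial_strategies, dtype=bool).copy()
    rng = np.random.default_rng(seed)
    e = network.edges
    n = network.n_nodes
    neighbor_lists = [network.neighbors(u) for u in range(n)]

    fractions = [float(is_c.mean())]
    absorbed, absorption_round = "none", None
    for rnd in range(1, max_rounds + 1):
        cu, cv = is_c[e[:, 0]], is_c[e[:, 1]]
        payoffs = np.zeros(n)
        both = cu & cv
        np.add.at(payoffs, e[both, 0], r - 1.0)
        np.add.at(payoffs, e[both, 1], r - 1.0)
        u_exp = cu & ~cv
        np.add.at(payoffs, e[u_exp, 0], -1.0)
        np.add.at(payoffs, e[u_exp, 1], r)
        v_exp = ~cu & cv
        np.add.at(payoffs, e[v_exp, 1], -1.0)
        np.add.at(payoffs, e[v_exp, 0], r)

        flagged = np.flatnonzero(rng.random(n) < delta)
        new_c = is_c.copy()
        for agent in flagged:
            nbrs = neighbor_lists[agent]
            model_agent = nbrs[rng.integers(len(nbrs))]
            if payoffs[model_agent] > payoffs[agent]:
                new_c[agent] = is_c[model_agent]
        is_c = new_c
        fractions.append(float(is_c.mean()))
        if not is_c.any():
            absorbed, absorption_round = "all_D", rnd
            break
        if is_c.all():
            absorbed, absorption_round = "all_C", rnd
            break

    return Trajectory(
        fraction_c=np.array(fractions),
        absorbed=absorbed,
        absorption_round=absorption_round,
        rounds=rnd,
        final_state=None,
    )


def perturb_rationality(
    params: ModelParams, gain_noise_sd: float, decision_flip_prob: float
) -> ModelParams:
    """Attach bounded-rationality knobs to a parameter set.

    Zero settings return parameters whose runs are bit-identical to the
    exact model at equal seeds (no extra random draws are consumed).
    """
    pert = RationalityPerturbation(gain_noise_sd, decision_flip_prob)
    return dataclasses.replace(params, perturbation=None if pert.is_identity else pert)
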