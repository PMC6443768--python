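# Methods

## Model

A population of N agents occupies the nodes of a static, connected,
undirected network. Time is discrete; at every round each pair of
neighbors faces a one-shot prisoner's dilemma parameterized by the return
r = b/c with the cost of cooperating c = 1 as the monetary unit.
Defectors always play and defect. Cooperators hold, per neighbor, an
abstention counter t ≥ 0 that encodes their engagement probability
p_t = 1 − (1 − δ_d)^t (p_0 = 1): the probability that a neighbor who
exploited them t − 1 abstentions ago has since revised her strategy,
evaluated at the reciprocity-biased update rate δ_d = (1 − d)δ. An
interaction is played iff both sides agree; an abstained interaction pays
nothing to either side but reveals the abstainer's cooperative mood to a
participating opponent. After a round, a cooperator exploited by a playing
defector guards at counter 1; one who abstained increments her counter;
one who played against a cooperating opponent re-engages at counter 0; one
who played while the opponent abstained keeps her counter (she learns the
opponent's mood, but no rule in the model re-engages her early).

By construction at most one side of an edge is disengaged, defectors are
always fully engaged, and the initial state is fully engaged everywhere.
These three invariants are enforced by `PopulationState.check_invariants`
and fuzz-tested over random trajectories.

Strategy update is asynchronous: after every round each agent is
independently flagged with probability δ. A flagged agent perceives each
neighbor from the counter pair on the shared edge (a cooperator may
under-count her cooperating neighbors when her own counter is stale, never
over-count; a defector has full information), forecasts the probability of
playing that neighbor over each of the next h rounds under both candidate
strategies, and switches iff the expected cumulated gain is strictly
positive. Ties keep the current strategy ("switch under a positive gain"
read strictly). All revisions flagged in a round are decided from the
common post-round state and applied simultaneously; a defector turning
cooperator guards at counter 1 toward perceived defectors.

## Forecasts and their numerical status

Against a steady defector the forecast obeys

    P¹ = p_t,   P^{s+1} = P^s δ_d + (1 − P^s)((1 − δ_d) P^s + δ_d),

whose fixed point is the closed form P∞ = ½(√(4δ_d − 3δ_d²) − δ_d)/(1 − δ_d).
Against a steady cooperator resumption is absorbing:
P¹ = p_t, P^{s+1} = P^s + (1 − P^s) p_{t+s}.

The defector-side recursion is the agents' belief-update rule, and it is a
first-order closure of the exact abstention-counter Markov chain: the
abstain branch advances the *marginal* play probability where the exact
chain would advance the path-conditional engagement. The two coincide for
the first two forecast steps (and from fresh states at the third), and
differ by O(10⁻⁴)–O(10⁻³) per step beyond that at the reference δ_d. The
package treats the recursion as the model definition — it is what revising
agents compute, it is internally consistent with the closed-form limit and
with all threshold formulas — while the test suite carries an independent
oracle that enumerates the exact play/abstain tree and checks equality on
the domain where it holds exactly. The cooperator-side recursion is exact.

Expected gains assemble from the horizon partial sums S_CC(t), S_CD(t) of
these sequences; both gains are affine in r for fixed neighborhood, with
Δπ_C decreasing and Δπ_D increasing in r whenever the agent perceives at
least one cooperator and h ≥ 2. At h = 1 defection dominates regardless of
the neighborhood — the multi-step horizon is essential.

An infinite-horizon decision mode (`h = math.inf`) replaces the horizon
sums by per-round rates (S_CC/h → 1, S_CD/h → P∞), so revisions reproduce
the closed-form remain-C condition exactly, with rate ties keeping the
current strategy. It exists for the analytic reference experiments (ring
and star); the finite-h model is the simulation default.

## Parameters

| parameter | meaning | default / reference | notes |
|---|---|---|---|
| r | PD return b/c (dimensionless) | swept over [1, 6] | c = 1 is the unit |
| δ | revision probability per round | 0.05 | 1/δ = inertia |
| d | reciprocity strength | 0 (normal) | admissible open interval (−(1/δ−1), 1) |
| δ_d | (1−d)δ, biased rate | 0.05 | drives p_t and all thresholds |
| h | predictive horizon (rounds) | 2–5 | δ·h > 0.3 triggers a warning: the forecast ignores neighbors' revisions |
| ⟨a⟩ | mean abstention length | 4.57 at δ_d = 0.05 | no closed form; series summed to a 10⁻¹² tail |

The mean abstention length is strictly decreasing in δ_d, so either d, δ_d
or ⟨a⟩ can serve as the reciprocity parameter.

## Thresholds

`remain_C_threshold(k, k_C, δ_d)` = 1 + (k/k_C)·P∞/(1−P∞) is the
infinite-horizon return above which a cooperator with k neighbors, k_C of
them perceived cooperators, keeps cooperating (and a defector with the
same neighborhood switches). Its worst case over a network,
`fixation_threshold_infinite(k_max, δ_d)`, takes k = k_max, k_C = 1. The
finite-horizon bound `fixation_threshold_bound` exploits the affinity of
both gains in r: it scans the r-roots over the worst-case neighborhood at
the maximal-degree node — one perceived cooperator at states {0, 1} for a
revising C (all reachable states for a revising D, which may itself face a
recently converted neighbor), defector states up to the counter where
engagement is within 10⁻⁶ of 1 — and returns the largest root. The bound
decreases with h toward the infinite-horizon value and is deliberately
conservative: empirical fixation thresholds from sweeps are far below it
(e.g. R̄_fix(k_max=4, h=2, δ_d=0.05) ≈ 70 vs an empirical r_fix ≈ 5),
because in practice defectors convert near a seed cluster long before the
worst-case configuration is ever visited.

## Experiments

`run` alternates play and revision and stops at absorption: all-D always;
all-C only when every counter is zero and the all-C remain-C condition
holds at the run's horizon (the sign of the degree-independent gain
−r(S_CC(0) − S_CD(0)) + S_CC(0)), so a declared absorption is provably
permanent. A single master seed drives one generator through participation
draws, revision flags and perturbation noise in fixed edge/node order;
trajectories are bit-reproducible.

`sweep_return` estimates, over an increasing return grid, r_inv (smallest
grid return whose mean final cooperation exceeds the initial fraction —
the operational reading of "on average, cooperation invades") and r_fix
(smallest grid return at which every replicate absorbs at all-C). It also
reports per-return outcome shares and flags unabsorbed runs above 20%
cooperation as slow-fixation candidates. Random networks and placements
are redrawn per replicate; lattices are fixed and only the placement
varies.

Desk-scale defaults are N = 1024 lattices (32² — the reference size 1000
is not a perfect square; periodic boundaries keep every degree exactly 4
or 8), 20 replicates, 10⁴ rounds, and the grid
[1.5, 2, 2.5, 3, 3.5, 4, 5, 6, 8]; `scripts/full_sweep.py` documents the
full 8-panel, 100-replicate protocol at N ≈ 1000.

Single-seed experiments: `estimate_first_mover_race` measures whether a
defecting neighbor converts before a lone cooperator (who, perceiving no
cooperators, defects at her first revision) gives up — for slow update the
race is a uniform draw among the k + 1 first revision times, giving
1 − 1/(k + 1). Simultaneous switches (probability O(δ)) are counted
conservatively as a focal-first outcome. `estimate_single_seed_fixation`
measures full fixation from one seed; the star reference case (N = 11,
central seed, r at the ring fixation threshold) runs in the
infinite-horizon mode because the predicted probability 1/2 + 1/(2N)
hinges on the knife-edge tie at exactly that return, which every finite
horizon resolves toward defection; r carries a +10⁻⁹ relative nudge so the
tie is not left to floating-point rounding. The measured probability sits
slightly below the asymptotic value because the central cooperator only
perceives a converted leaf after re-playing it (a lag of order the mean
abstention length).

`imitation_baseline_run` is the classical comparator: unconditional
strategies, no abstention, and copy-if-strictly-better against one random
neighbor — the strong-selection limit of the pairwise-comparison (Fermi)
rule. Sparse cooperation dies under it even at returns where the
predictive model fixates reliably.

`perturb_rationality` exposes two bounded-rationality knobs (multiplicative
Gaussian noise on computed gains; random decision flips). Zero settings
consume no random draws, so unperturbed runs are bit-identical to the
exact model.

## What the generators emulate — and what they do not

Networks are synthetic throughout: regular tori and rings, fully rewired
Watts–Strogatz (single-scale), Barabási–Albert (scale-free), Holme–Kim
(tunable transitivity), star and complete reference graphs. They reproduce
the degree-distribution contrasts the theory turns on (homogeneous vs
hub-dominated at equal mean degree) but none of the community structure,
degree correlations, or dynamics of real social networks; conclusions from
passing tests are about the model's internal claims, not about any
empirical network. Initial conditions are point seeds, random or
degree-ranked placements, or adjacent pairs — idealized invasion
scenarios.

## Known limitations

- The defector-side forecast is the model's own belief recursion, not the
  exact counter-chain marginal (see above); all analytic thresholds inherit
  this definition.
- r_inv is grid-resolution limited and, between r_inv and r_fix, single
  runs are bimodal so the mean curve is not representative (the outcome
  shares are the more informative diagnostic).
- Absorption within the round budget is not guaranteed near thresholds;
  unabsorbed runs are reported as such, never extrapolated.
- Payoffs are undiscounted and neighbors' strategy revisions are ignored
  within the forecast horizon; both are reasonable only for δ·h small,
  hence the 0.3 warning threshold.
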