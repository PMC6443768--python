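# netrecip

Agent-based and analytic tools for studying the evolution of cooperation in
a networked prisoner's dilemma where cooperators practice **direct
reciprocity by abstention** and revise strategies with **model-predictive
rationality**.

## The model in brief

Agents sit on a static connected network and play a one-shot prisoner's
dilemma with every neighbor at each round. With cost *c* = 1 as the unit,
a cooperator (C) grants benefit *b* = *r* to the opponent; a defector (D)
grants nothing. Instead of retaliating, a C exploited by a neighbor
temporarily *abstains* from playing that neighbor: after *t* − 1
consecutive abstentions she resumes with the engagement probability

    p_t = 1 − (1 − δ_d)^t ,    p_0 = 1 ,

the probability that the exploiter has revised her strategy at least once,
computed at the reciprocity-biased update rate δ_d = (1 − *d*) δ. Here δ is
the per-round revision probability and *d* ∈ (−(1/δ − 1), 1) modulates the
reciprocity strength (*d* = 0: normal; *d* > 0 / < 0: super/sub-normal,
longer/shorter abstention periods ⟨a⟩).

Strategy update is asynchronous and *innovative* rather than imitative:
a revising agent classifies each neighbor from the engagement state of the
shared link, forecasts her probability of playing each neighbor over the
next *h* rounds under both candidate strategies, and switches iff the
expected cumulated payoff gain is strictly positive. In the
infinite-horizon limit a C with degree *k* and *k*_C perceived cooperating
neighbors remains C iff

    r > 1 + (k / k_C) · P∞ / (1 − P∞) ,
    P∞ = ½ (√(4δ_d − 3δ_d²) − δ_d) / (1 − δ_d) ≈ √δ_d  (small δ_d),

and the worst case over the network (k = k_max, k_C = 1) gives the
fixation threshold R_fix^∞ = 1 + k_max · P∞/(1 − P∞). For finite horizons
the package computes a numeric worst-case bound R̄_fix. Empirically,
cooperation seeded at 1% invades and fixates above return thresholds
r_inv ≤ r_fix that grow with the network's mean degree and shrink with the
horizon — the classical *network reciprocity* rule, recovered without
imitation.

## Worked example

```python
import netrecip as nr

# abstention statistics at the reference update rate
nr.mean_abstention_length(0.05)        # 4.5695 rounds
nr.p_cd_limit(0.05)                    # 0.20460
nr.fixation_threshold_infinite(4, 0.05)  # 2.0289

# a 32x32 4-neighbor torus, 1% cooperators, r = 10, horizon 2
net = nr.build_lattice("square4", 1024)
init = nr.assign_initial_strategies(net, "random", 10, seed=3)
traj = nr.run(net, init, nr.ModelParams(r=10.0, delta=0.05, h=2),
              max_rounds=10_000, seed=5)
traj.absorbed, traj.rounds             # ('all_C', 263)
```

Ten isolated cooperators among 1014 defectors take over the lattice in 263
rounds: the return r = 10 is far above the empirical fixation threshold
(≈ 5 for this lattice and horizon), so every replicate ends at all-C.

The same experiments are available from the shell:

```
netrecip thresholds --kmax 4 --delta-d 0.05 --h 2
netrecip sweep config.yaml --seed 1 --out results/
netrecip simulate config.yaml
netrecip networks --kind scale_free --n 1000 --mean-degree 4 --out net/
```

where `config.yaml` is a flat key/value document (see
`examples/reference.yaml`).

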