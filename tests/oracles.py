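"""Independent brute-force oracles for the predictive-update gains.

The oracle enumerates the play/abstain outcome tree of one reviser-neighbor
pair exactly: the pair's state is the abstention counter, a play happens
with the engagement probability of that counter, playing against a
defector resets the counter to 1 while an abstention increments it, and
resumption against a cooperator is absorbing.  Expected payoffs are summed
over the exact counter distribution round by round; neighbors are frozen
and payoffs are additive across neighbors, so the gains assemble per pair.
"""

from collections import defaultdict

from netrecip.engagement import engagement_probability


def exact_play_probs_vs_defector(t_init: int, delta_d: float, h: int) -> list[float]:
    """Exact per-round play probabilities against a steady defector."""
    dist = {t_init: 1.0}
    probs = []
    for _ in range(h):
        probs.append(
            sum(w * engagement_probability(c, delta_d) for c, w in dist.items())
        )
        new = defaultdict(float)
        for c, w in dist.items():
            p = engagement_probability(c, delta_d)
            new[1] += w * p  # played, got exploited: guard at counter 1
            new[c + 1] += w * (1.0 - p)  # abstained: counter grows
        dist = dict(new)
    return probs


def exact_play_probs_vs_cooperator(t_init: int, delta_d: float, h: int) -> list[float]:
    """Exact per-round play probabilities against a steady cooperator.

    The neighbor abstains at counter ``t_init``; once she resumes, mutual
    cooperation locks both sides at full engagement.
    """
    probs = []
    not_resumed = 1.0
    p_play = 0.0
    for s in range(h):
        p_resume = engagement_probability(t_init + s, delta_d)
        p_play = p_play + not_resumed * p_resume
        not_resumed *= 1.0 - p_resume
        probs.append(p_play)
    return probs


def oracle_gain_c(perceptions, r: float, h: int, delta_d: float) -> float:
    """Expected gain of a C for switching to D, from the exact trees."""
    gain = 0.0
    for p in perceptions:
        if p.perceived_c:
            stay = (r - 1.0) * sum(exact_play_probs_vs_cooperator(p.state, delta_d, h))
            switch = r * sum(exact_play_probs_vs_defector(p.state, delta_d, h))
        else:
            stay = -sum(exact_play_probs_vs_defector(p.state, delta_d, h))
            switch = 0.0
        gain += switch - stay
    return gain


def oracle_gain_d(perceptions, r: float, h: int, delta_d: float) -> float:
    """Expected gain of a D for switching to C, from the exact trees."""
    gain = 0.0
    for p in perceptions:
        if p.perceived_c:
            stay = r * sum(exact_play_probs_vs_defector(p.state, delta_d, h))
            # a fresh C fully re-engages toward a perceived C, who resumes
            # from her current state
            switch = (r - 1.0) * sum(exact_play_probs_vs_cooperator(p.state, delta_d, h))
        else:
            stay = 0.0
            # a fresh C guards at counter 1 toward a perceived D
            switch = -sum(exact_play_probs_vs_defector(1, delta_d, h))
        gain += switch - stay
    return gain
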