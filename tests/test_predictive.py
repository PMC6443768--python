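"""Forecast recursions, expected gains, revision rule, analytic thresholds."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netrecip import (
    ModelParams,
    NeighborPerception,
    PopulationState,
    build_lattice,
    expected_gain_C,
    expected_gain_D,
    fixation_threshold_bound,
    fixation_threshold_infinite,
    forecast_play_with_cooperator,
    forecast_play_with_defector,
    p_cd_limit,
    perceive_neighbors,
    play_round,
    remain_C_threshold,
    revise,
)
from netrecip.predictive import GainCalculator

from oracles import (
    exact_play_probs_vs_cooperator,
    exact_play_probs_vs_defector,
    oracle_gain_c,
    oracle_gain_d,
)


def _pc(state):
    return NeighborPerception(0, True, state)


def _pd(state):
    return NeighborPerception(0, False, state)


def _random_perceptions(rng, k_min=1, k_max=8, force_c=False):
    k = rng.integers(k_min, k_max + 1)
    out = []
    for _ in range(k):
        if rng.random() < 0.5:
            out.append(_pc(int(rng.integers(0, 20))))
        else:
            out.append(_pd(int(rng.integers(1, 20))))
    if force_c and not any(p.perceived_c for p in out):
        out[0] = _pc(int(rng.integers(0, 20)))
    return out


class TestForecasts:
    def test_defector_forecast_seeds_and_steps(self):
        assert np.allclose(forecast_play_with_defector(0, 0.05, 2), [1.0, 0.05])
        seq = forecast_play_with_defector(1, 0.05, 3)
        assert seq[0] == pytest.approx(0.05)

    def test_defector_forecast_converges_to_closed_form(self):
        for dd in (0.025, 0.05, 0.1):
            for t0 in (0, 1, 7, 40):
                seq = forecast_play_with_defector(t0, dd, 1000)
                assert abs(seq[-1] - p_cd_limit(dd)) < 1e-6

    def test_closed_form_is_recursion_fixed_point(self):
        for dd in (0.01, 0.05, 0.3, 0.9):
            p = p_cd_limit(dd)
            step = p * dd + (1 - p) * ((1 - dd) * p + dd)
            assert step == pytest.approx(p, abs=1e-14)

    def test_cooperator_forecast_values(self):
        assert np.allclose(forecast_play_with_cooperator(0, 0.3, 4), [1, 1, 1, 1])
        seq = forecast_play_with_cooperator(1, 0.05, 2)
        assert np.allclose(seq, [0.05, 0.142625])

    @given(t=st.integers(0, 30), dd=st.floats(0.01, 0.9))
    @settings(max_examples=100, deadline=None)
    def test_cooperator_forecast_nondecreasing_to_one(self, t, dd):
        seq = forecast_play_with_cooperator(t, dd, 200)
        assert np.all(np.diff(seq) >= -1e-15)
        assert seq[-1] == pytest.approx(1.0, abs=1e-3)

    def test_forecasts_match_exact_trees_for_two_steps(self):
        """The belief recursions are exact for the first two forecast rounds."""
        for dd in (0.05, 0.3):
            for t0 in (0, 1, 5):
                assert np.allclose(
                    forecast_play_with_defector(t0, dd, 2),
                    exact_play_probs_vs_defector(t0, dd, 2),
                    atol=1e-15,
                )
                assert np.allclose(
                    forecast_play_with_cooperator(t0, dd, 6),
                    exact_play_probs_vs_cooperator(t0, dd, 6),
                    atol=1e-14,
                )


class TestLimitsAndThresholds:
    def test_p_cd_limit_values(self):
        assert p_cd_limit(1.0) == 1.0
        assert p_cd_limit(0.05) == pytest.approx(0.2046043, abs=1e-6)
        assert p_cd_limit(1e-4) == pytest.approx(math.sqrt(1e-4), rel=0.02)
        with pytest.raises(ValueError):
            p_cd_limit(0.0)

    def test_remain_c_threshold_structure(self):
        dd = 0.05
        p = p_cd_limit(dd)
        # full C-neighborhood is the mildest requirement
        assert remain_C_threshold(4, 4, dd) == pytest.approx(1 + p / (1 - p))
        # star center with one C-leaf is the harshest
        assert remain_C_threshold(10, 1, dd) == pytest.approx(1 + 10 * p / (1 - p))
        ratios = [remain_C_threshold(k, 1, dd) for k in (1, 2, 4, 8)]
        assert all(a < b for a, b in zip(ratios, ratios[1:]))
        assert remain_C_threshold(4, 0, dd) == math.inf

    def test_fixation_threshold_infinite(self):
        assert fixation_threshold_infinite(4, 0.05) == pytest.approx(2.0289, abs=1e-3)
        ks = [fixation_threshold_infinite(k, 0.05) for k in (1, 2, 4, 8, 16)]
        assert all(a < b for a, b in zip(ks, ks[1:]))

    def test_finite_horizon_bound_decreases_to_infinite_limit(self):
        dd = 0.05
        bounds = [fixation_threshold_bound(4, h, dd) for h in (2, 3, 4, 5, 8, 12)]
        assert all(a >= b for a, b in zip(bounds, bounds[1:]))
        r_inf = fixation_threshold_infinite(4, dd)
        assert all(b >= r_inf for b in bounds)
        assert fixation_threshold_bound(4, 400, dd) == pytest.approx(r_inf, rel=0.05)

    def test_bound_requires_multistep_horizon(self):
        with pytest.raises(ValueError):
            fixation_threshold_bound(4, 1, 0.05)


class TestGains:
    def test_single_c_neighbor_closed_form(self):
        """One perceived C at state 0, h=2: gain of defecting is 2 - 0.95 r."""
        for r in (1.0, 3.0, 5.0):
            g = expected_gain_C([_pc(0)], r, 2, 0.05)
            assert g == pytest.approx(2 - 0.95 * r, abs=1e-12)
        assert expected_gain_C([_pc(0)], 3.0, 2, 0.05) == pytest.approx(-0.85)

    def test_d_gain_closed_form_and_revision(self):
        """One perceived C at state 1, h=2: gain of cooperating is 0.0475 r - 0.192625."""
        for r in (2.0, 4.0, 5.0):
            g = expected_gain_D([_pc(1)], r, 2, 0.05)
            assert g == pytest.approx(0.0475 * r - 0.192625, abs=1e-12)
        # sign change near r ~ 4.06
        assert expected_gain_D([_pc(1)], 4.0, 2, 0.05) < 0
        assert expected_gain_D([_pc(1)], 4.1, 2, 0.05) > 0

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=300, deadline=None)
    def test_myopic_sign_laws(self, seed):
        """Best response (h=1): defecting always gains, cooperating never."""
        rng = np.random.default_rng(seed)
        perceptions = _random_perceptions(rng)
        r = float(rng.uniform(0.2, 50))
        dd = float(rng.uniform(0.01, 0.9))
        assert expected_gain_C(perceptions, r, 1, dd) > 0
        assert expected_gain_D(perceptions, r, 1, dd) < 0

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_affine_in_r_with_sign_pattern(self, seed):
        """For h >= 2 and k_C >= 1: gains are affine in r, decreasing for the
        C-gain and increasing for the D-gain, positive/negative at r = 1."""
        rng = np.random.default_rng(seed)
        perceptions = _random_perceptions(rng, force_c=True)
        h = int(rng.integers(2, 6))
        dd = float(rng.uniform(0.01, 0.5))
        g = [expected_gain_C(perceptions, r, h, dd) for r in (1.0, 2.0, 3.0)]
        assert g[1] - g[0] == pytest.approx(g[2] - g[1], rel=1e-9, abs=1e-12)
        assert g[1] < g[0]
        assert g[0] > 0
        g = [expected_gain_D(perceptions, r, h, dd) for r in (1.0, 2.0, 3.0)]
        assert g[1] - g[0] == pytest.approx(g[2] - g[1], rel=1e-9, abs=1e-12)
        assert g[1] > g[0]
        assert g[0] < 0

    def test_isolated_c_always_defects(self):
        """No perceived C-neighbors: the gain is positive at any return."""
        perceptions = [_pd(3), _pd(1)]
        for r in (0.5, 1.0, 10.0, 1000.0):
            assert expected_gain_C(perceptions, r, 4, 0.05) > 0
            assert expected_gain_D(perceptions, r, 4, 0.05) < 0

    def test_oracle_equivalence_short_horizons(self):
        """Gains match the exact play-tree expectation where the belief
        recursion is exact (h <= 2 anywhere; longer from fresh states)."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            perceptions = _random_perceptions(rng)
            r = float(rng.uniform(0.5, 10))
            dd = float(rng.uniform(0.01, 0.9))
            for h in (1, 2):
                assert expected_gain_C(perceptions, r, h, dd) == pytest.approx(
                    oracle_gain_c(perceptions, r, h, dd), abs=1e-12
                )
                assert expected_gain_D(perceptions, r, h, dd) == pytest.approx(
                    oracle_gain_d(perceptions, r, h, dd), abs=1e-12
                )

    def test_infinite_horizon_rate_gains(self):
        """h = inf compares per-round rates: signs follow the closed-form
        remain-C condition, with exact ties keeping the strategy."""
        dd = 0.05
        p = p_cd_limit(dd)
        k, kc = 4, 2
        perceptions = [_pc(0)] * kc + [_pd(3)] * (k - kc)
        thr = remain_C_threshold(k, kc, dd)
        calc = GainCalculator(dd, math.inf)
        assert calc.gain_c(perceptions, thr * 1.001) < 0
        assert calc.gain_c(perceptions, thr * 0.999) > 0
        assert calc.gain_d(perceptions, thr * 1.001) > 0


class TestPerception:
    def _state_after_exploitation(self):
        net = build_lattice("ring4", 10)
        is_c = np.zeros(10, bool)
        is_c[[0, 1]] = True
        state = PopulationState(net, is_c)
        play_round(state, ModelParams(r=3.0, delta=0.05, h=2), np.random.default_rng(2))
        return net, state

    def test_c_perceives_exploiters_as_d(self):
        net, state = self._state_after_exploitation()
        percs = {p.neighbor: p for p in perceive_neighbors(state, 0)}
        # neighbors 2, 8, 9 are defectors who exploited agent 0
        for j in (2, 8, 9):
            assert not percs[j].perceived_c
            assert percs[j].state >= 1
        # neighbor 1 cooperated: both counters 0, perceived C at state 0
        assert percs[1].perceived_c
        assert percs[1].state == 0

    def test_d_perceives_abstaining_c(self):
        net, state = self._state_after_exploitation()
        percs = {p.neighbor: p for p in perceive_neighbors(state, 2)}
        assert percs[0].perceived_c  # the exploited C abstains: identified
        eidx, side = net.incidence()[0]
        t_toward_2 = state.t[eidx, side][list(net.neighbors(0)).index(2)]
        assert percs[0].state == t_toward_2  # seeded at her counter
        for j in (3, 4):
            assert not percs[j].perceived_c

    def test_revision_tie_keeps_strategy(self):
        net, state = self._state_after_exploitation()

        class ZeroGain:
            def gain_c(self, perceptions, r):
                return 0.0

            def gain_d(self, perceptions, r):
                return 0.0

        params = ModelParams(r=3.0, delta=0.05, h=2)
        assert revise(state, 0, params, calc=ZeroGain()) == "keep"
        assert state.is_c[0]

    def test_revision_applies_switch(self):
        net, state = self._state_after_exploitation()
        # defector 8 perceives one abstaining C (agent 0) at state 1 plus
        # three D's; its switch point is (S_CC(1) + 3 S_CD(1)) / 0.0475 ~ 13.2
        params = ModelParams(r=15.0, delta=0.05, h=2)
        assert revise(state, 8, params) == "switch"
        assert state.is_c[8]
        state.check_invariants()
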