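"""Likelihood and simulation checks for the two generative task models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cogrel import synth
from cogrel.tasks import (BanditTrials, DataError, GambleTrials, PTParams,
                          RLParams, RLState, pt_gamble_prob, pt_loglik,
                          pt_simulate, pt_utility, rl_choice_probs, rl_loglik,
                          rl_simulate, rl_step)


def _rl_oracle_probs(choices, rewards, punishments, p):
    """Trial-by-trial reimplementation of the bandit likelihood.

    Deliberately written in plain Python, independent of the compiled
    kernel it checks.
    """
    q_rew, q_pun = [0.0] * 4, [0.0] * 4
    out = []
    for c, r, pu in zip(choices, rewards, punishments):
        q = [q_rew[a] + q_pun[a] for a in range(4)]
        es = [np.exp(v) for v in q]
        denom = sum(es)
        probs = [(1 - p.xi) * e / denom + p.xi / 4 for e in es]
        out.append(probs[c - 1])
        q_rew[c - 1] += p.a_rew * (p.r_sens * r - q_rew[c - 1])
        q_pun[c - 1] += p.a_pun * (p.p_sens * pu - q_pun[c - 1])
    return out


class TestBanditChoiceRule:
    def test_uniform_at_zero_q(self):
        p = rl_choice_probs(RLState(), RLParams(0.3, 0.3, 2, 2, 0.0))
        np.testing.assert_allclose(p, 0.25)

    def test_full_lapse_is_uniform_regardless_of_q(self):
        state = RLState(np.array([3.0, -1.0, 0.5, 0.0]), np.zeros(4))
        p = rl_choice_probs(state, RLParams(0.3, 0.3, 2, 2, 1.0))
        np.testing.assert_allclose(p, 0.25)

    def test_softmax_hand_value(self):
        state = RLState(np.array([1.0, 0, 0, 0]), np.zeros(4))
        p = rl_choice_probs(state, RLParams(0.3, 0.3, 2, 2, 0.0))
        assert p[0] == pytest.approx(np.e / (np.e + 3), abs=1e-12)

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=8, max_size=8),
           st.floats(0, 1), st.floats(-3, 3))
    def test_normalisation_lapse_floor_and_shift_invariance(self, qs, xi, shift):
        """Probabilities sum to 1, never drop below xi/4, and are invariant
        to adding a constant to all Q-values."""
        state = RLState(np.array(qs[:4]), np.array(qs[4:]))
        params = RLParams(0.5, 0.5, 1, 1, xi)
        p = rl_choice_probs(state, params)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert (p >= xi / 4 - 1e-12).all()
        shifted = RLState(state.q_rew + shift, state.q_pun)
        np.testing.assert_allclose(rl_choice_probs(shifted, params), p, atol=1e-10)

    def test_nonfinite_q_rejected(self):
        state = RLState(np.array([np.nan, 0, 0, 0]), np.zeros(4))
        with pytest.raises(ValueError):
            rl_choice_probs(state, RLParams(0.3, 0.3, 2, 2, 0.0))


class TestBanditUpdate:
    def test_reward_update_hand_value(self):
        s = rl_step(RLState(), 1, 1, 0, RLParams(0.4, 0.5, 2.0, 3.0, 0.0))
        assert s.q_rew[0] == pytest.approx(0.8)
        assert s.q_pun[0] == 0.0

    def test_punishment_update_hand_value(self):
        s = rl_step(RLState(), 2, 0, -1, RLParams(0.4, 0.5, 2.0, 3.0, 0.0))
        assert s.q_pun[1] == pytest.approx(-1.5)

    def test_zero_learning_rate_freezes_state(self):
        s0 = RLState(np.array([0.3, 0, 0, 0]), np.array([0, -0.2, 0, 0.0]))
        s1 = rl_step(s0, 1, 1, -1, RLParams(0.0, 0.0, 2.0, 3.0, 0.0))
        np.testing.assert_array_equal(s1.q_rew, s0.q_rew)
        np.testing.assert_array_equal(s1.q_pun, s0.q_pun)

    def test_unchosen_arms_unchanged_and_fixed_point(self):
        p = RLParams(1.0, 1.0, 2.0, 3.0, 0.0)
        s = rl_step(RLState(), 3, 1, -1, p)
        assert s.q_rew[2] == pytest.approx(2.0)   # r_sens * reward at a=1
        assert s.q_pun[2] == pytest.approx(-3.0)  # p_sens * punishment
        assert all(s.q_rew[a] == 0 for a in (0, 1, 3))

    def test_invalid_outcome_coding_rejected(self):
        with pytest.raises(DataError):
            rl_step(RLState(), 1, 2, 0, RLParams(0.3, 0.3, 1, 1, 0))
        with pytest.raises(DataError):
            rl_step(RLState(), 5, 1, 0, RLParams(0.3, 0.3, 1, 1, 0))


class TestBanditLikelihood:
    def test_full_lapse_closed_form(self):
        T = 200
        trials = BanditTrials(np.ones(T, int), np.zeros(T), np.zeros(T))
        ll, per = rl_loglik(RLParams(0.3, 0.3, 2, 2, 1.0), trials)
        assert ll == pytest.approx(T * np.log(0.25), rel=1e-12)
        np.testing.assert_allclose(per, 0.25)

    def test_first_trial_is_uniform_for_any_params(self):
        trials = BanditTrials([3], [1], [-1])
        ll, _ = rl_loglik(RLParams(0.9, 0.1, 5, 5, 0.2), trials)
        assert ll == pytest.approx(np.log(0.25))

    def test_matches_pure_python_oracle_on_random_sequences(self, rng):
        for _ in range(20):
            p = RLParams(rng.uniform(0, 1), rng.uniform(0, 1),
                         rng.uniform(0, 8), rng.uniform(0, 8), rng.uniform(0, 1))
            choices = rng.integers(1, 5, size=5)
            rewards = rng.integers(0, 2, size=5).astype(float)
            punish = -rng.integers(0, 2, size=5).astype(float)
            ll, per = rl_loglik(p, BanditTrials(choices, rewards, punish))
            oracle = _rl_oracle_probs(choices, rewards, punish, p)
            np.testing.assert_allclose(per, oracle, rtol=1e-10)
            assert ll == pytest.approx(np.sum(np.log(oracle)), rel=1e-10)

    def test_empty_trials_rejected(self):
        with pytest.raises(DataError):
            rl_loglik(RLParams(0.3, 0.3, 1, 1, 0), BanditTrials([], [], []))


class TestBanditSimulation:
    def test_full_lapse_choice_frequencies_uniform(self):
        env = synth.BanditEnvironment(np.full((10000, 4), 0.5), np.full((10000, 4), 0.5))
        tr = rl_simulate(RLParams(0.3, 0.3, 2, 2, 1.0), env, seed=1)
        freqs = np.bincount(tr.choice, minlength=5)[1:] / len(tr)
        np.testing.assert_allclose(freqs, 0.25, atol=0.02)

    def test_learner_exploits_dominant_arm(self):
        win = np.zeros((600, 4))
        win[:, 1] = 1.0
        env = synth.BanditEnvironment(win, np.zeros((600, 4)))
        tr = rl_simulate(RLParams(0.7, 0.7, 8, 8, 0.02), env, seed=2)
        assert np.mean(tr.choice[200:] == 2) > 0.9

    def test_degenerate_environment_yields_no_outcomes(self):
        env = synth.BanditEnvironment(np.zeros((50, 4)), np.zeros((50, 4)))
        tr = rl_simulate(RLParams(0.5, 0.5, 2, 2, 0.1), env, seed=3)
        assert tr.reward.sum() == 0 and tr.punishment.sum() == 0

    def test_seed_reproducibility(self):
        env = synth.generate_bandit_environment(seed=5)
        a = rl_simulate(RLParams(0.4, 0.3, 5, 5, 0.05), env, seed=9)
        b = rl_simulate(RLParams(0.4, 0.3, 5, 5, 0.05), env, seed=9)
        np.testing.assert_array_equal(a.choice, b.choice)
        np.testing.assert_array_equal(a.reward, b.reward)

    def test_win_stay_ordering_win_neither_loss(self, small_bandit_study):
        """Simulated reward-sensitive agents repeat choices most after wins,
        least after losses."""
        from cogrel.agnostic import stay_table

        tab = stay_table(small_bandit_study.bandit)
        means = tab[["p_stay_win", "p_stay_neither", "p_stay_loss"]].mean()
        assert means["p_stay_win"] > means["p_stay_neither"] > means["p_stay_loss"]


class TestProspectTheory:
    def test_utility_identities(self):
        assert pt_utility(0, 0.8, 2.0) == 0
        assert pt_utility(30, 1.0, 3.0) == pytest.approx(30)
        assert pt_utility(-10, 0.8, 2.0) == pytest.approx(-2 * 10**0.8)

    def test_utility_sign_matches_outcome_sign(self, rng):
        x = rng.uniform(-50, 50, 100)
        u = pt_utility(x, 0.7, 2.5)
        np.testing.assert_array_equal(np.sign(u), np.sign(x))

    def test_symmetric_mixed_gamble_is_indifferent(self):
        p = pt_gamble_prob(PTParams(1.0, 1.0, 0.3), 0.0, 30.0, -30.0)
        assert p == pytest.approx(0.5)

    def test_gamble_prob_hand_value(self):
        p = pt_gamble_prob(PTParams(1.0, 2.0, 0.1), 0.0, 30.0, -30.0)
        assert p == pytest.approx(1 / (1 + np.exp(1.5)), abs=1e-12)

    def test_zero_temperature_is_indifferent(self):
        p = pt_gamble_prob(PTParams(0.7, 3.0, 0.0), 10.0, 50.0, 0.0)
        assert p == pytest.approx(0.5)

    @settings(max_examples=60, derandomize=True)
    @given(st.floats(0.3, 1.8), st.floats(0.2, 4.5), st.floats(0.01, 2),
           st.floats(10, 60), st.floats(5, 55))
    def test_monotonicity_in_loss_aversion_and_gain(self, rho, lam, tau, gain, loss_mag):
        """More loss-averse agents gamble less on mixed offers; larger gains
        make gambling more attractive."""
        p_lo = pt_gamble_prob(PTParams(rho, lam, tau), 0.0, gain, -loss_mag)
        p_hi = pt_gamble_prob(PTParams(rho, min(lam + 0.5, 5), tau), 0.0, gain, -loss_mag)
        assert p_hi <= p_lo + 1e-12
        p_gain = pt_gamble_prob(PTParams(rho, lam, tau), 0.0, gain + 5, -loss_mag)
        assert p_gain >= p_lo - 1e-12

    def test_loglik_limits_and_oracle(self):
        offers = GambleTrials(["mixed", "gain"], [0.0, 20.0], [30.0, 40.0],
                              [-25.0, 0.0], [1, 0])
        ll0, _ = pt_loglik(PTParams(0.9, 1.5, 0.0), offers)
        assert ll0 == pytest.approx(2 * np.log(0.5))
        p = PTParams(0.8, 2.0, 0.4)
        ll, per = pt_loglik(p, offers)
        p1 = pt_gamble_prob(p, 0.0, 30.0, -25.0)
        p2 = 1 - pt_gamble_prob(p, 20.0, 40.0, 0.0)
        assert ll == pytest.approx(np.log(p1) + np.log(p2), rel=1e-10)
        np.testing.assert_allclose(per, [p1, p2], rtol=1e-10)

    def test_deterministic_consistent_chooser_has_loglik_near_zero(self):
        offers = GambleTrials(["mixed"] * 2, [0.0] * 2, [60.0, 10.0],
                              [-10.0, -60.0], [1, 0])
        ll, _ = pt_loglik(PTParams(1.0, 1.0, 50.0), offers)
        assert ll == pytest.approx(0.0, abs=1e-6)

    def test_simulation_properties(self):
        offers = synth.training_offers()
        mixed = offers.trial_type == "mixed"
        # indifferent agent gambles about half the time
        sim = pt_simulate(PTParams(1.0, 1.0, 0.0), offers, seed=4)
        assert abs(sim.gambled.mean() - 0.5) < 0.15
        # extreme loss aversion suppresses mixed gambling
        sim_la = pt_simulate(PTParams(1.0, 5.0, 1.0), offers, seed=4)
        assert sim_la.gambled[mixed].mean() < 0.5
        # determinism
        a = pt_simulate(PTParams(0.9, 1.5, 0.3), offers, seed=11)
        b = pt_simulate(PTParams(0.9, 1.5, 0.3), offers, seed=11)
        np.testing.assert_array_equal(a.gambled, b.gambled)


class TestContainers:
    def test_bandit_coding_validated(self):
        with pytest.raises(DataError):
            BanditTrials([1, 2], [0, 2], [0, 0])
        with pytest.raises(DataError):
            BanditTrials([0, 1], [0, 0], [0, 0])

    def test_gamble_structure_validated(self):
        with pytest.raises(DataError):
            GambleTrials(["mixed"], [5.0], [30.0], [-20.0], [0])  # sure != 0
        with pytest.raises(DataError):
            GambleTrials(["gain"], [10.0], [30.0], [-5.0], [0])   # loss != 0

    def test_rlparams_bounds_enforced(self):
        with pytest.raises(ValueError):
            RLParams(1.2, 0.3, 1, 1, 0)
        with pytest.raises(ValueError):
            RLParams(0.5, 0.3, -1, 1, 0)
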