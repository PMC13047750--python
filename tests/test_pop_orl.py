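"""PoP-ORL model: value signal, choice rule, updates, likelihood, agent."""

import math

import numpy as np
import pytest

from popigt.igt_task import DataError, SessionLog, TrialRecord
from popigt.pop_orl import (
    ModelConfig,
    ORLParams,
    init_state,
    log_likelihood,
    log_likelihood_reference,
    play_probability,
    simulate_agent,
    update_state,
)
from tests.conftest import random_session


class TestValueSignal:
    def test_fresh_state_value_equals_go_bias(self):
        st = init_state(ORLParams(0.3, 0.3, 5.0, 1.25))
        assert np.allclose(st.V, 1.25)
        st0 = init_state(ORLParams(0.3, 0.3, 5.0, 0.0))
        assert np.allclose(st0.V, 0.0)

    def test_frequency_weight_inert_while_ef_is_zero(self):
        a = init_state(ORLParams(0.5, 0.5, 0.0, 0.7))
        b = init_state(ORLParams(0.5, 0.5, 9.0, 0.7))
        assert np.allclose(a.V, b.V)

    @pytest.mark.parametrize("beta_b, expected", [
        (0.0, 0.5),
        (1.25, 1 / (1 + math.exp(-1.25))),  # ~0.777
        (30.0, 1.0),
    ])
    def test_play_probability_logistic(self, beta_b, expected):
        st = init_state(ORLParams(0.1, 0.1, 0.0, beta_b))
        assert play_probability(st, "A") == pytest.approx(expected, abs=1e-9)

    def test_play_probability_monotone_in_value(self):
        probs = [play_probability(init_state(ORLParams(0, 0, 0, b)), "C")
                 for b in np.linspace(-5, 5, 21)]
        assert np.all(np.diff(probs) > 0)


class TestUpdateState:
    def test_delta_rule_hand_example(self):
        params = ORLParams(0.4, 0.1, 1.0, 0.0)
        st = update_state(init_state(params), "A", "play", 100.0, params,
                          ModelConfig(outcome_scale=100.0))
        assert st.EV[0] == pytest.approx(0.4)  # 0 + 0.4 * (100/100 - 0)
        assert st.EF[0] == pytest.approx(0.4)  # 0 + 0.4 * (sign(100) - 0)

    def test_pass_leaves_state_unchanged(self):
        params = ORLParams(0.4, 0.3, 2.0, 0.5)
        st = update_state(init_state(params), "B", "play", -1250.0, params)
        after = update_state(st, "C", "pass", 0.0, params)
        assert np.array_equal(after.EV, st.EV)
        assert np.array_equal(after.EF, st.EF)

    def test_pass_with_nonzero_outcome_rejected(self):
        params = ORLParams(0.4, 0.3, 2.0, 0.5)
        with pytest.raises(DataError):
            update_state(init_state(params), "A", "pass", 100.0, params)

    def test_zero_learning_rates_freeze_values(self):
        params = ORLParams(0.0, 0.0, 3.0, 0.8)
        st = init_state(params)
        for outcome in (100.0, -1250.0, 0.0):
            st = update_state(st, "B", "play", outcome, params)
        assert np.allclose(st.EV, 0) and np.allclose(st.EF, 0)
        assert np.allclose(st.V, 0.8)

    def test_fictive_updating_touches_unplayed_decks(self):
        params = ORLParams(0.5, 0.25, 1.0, 0.0)
        on = update_state(init_state(params), "A", "play", 100.0, params,
                          ModelConfig(fictive_updating=True,
                                      fictive_attenuation=3.0))
        # other decks move toward -sign(+100)/3 with the opposite-valence rate
        assert on.EF[1] == pytest.approx(0.25 * (-1 / 3))
        off = update_state(init_state(params), "A", "play", 100.0, params,
                           ModelConfig(fictive_updating=False))
        assert off.EF[1] == 0.0

    def test_learning_rate_bounds_enforced(self):
        with pytest.raises(ValueError):
            ORLParams(1.2, 0.5, 0.0, 0.0)
        with pytest.raises(ValueError):
            ORLParams(0.5, -0.1, 0.0, 0.0)


class TestLogLikelihood:
    def test_single_play_trial_at_null_params(self):
        session = SessionLog("s", 1, [TrialRecord(0, "A", "play", 100.0, 2100.0)])
        params = ORLParams(0.0, 0.0, 0.0, 0.0)
        assert log_likelihood(params, session) == pytest.approx(math.log(0.5))

    def test_all_pass_session_at_null_params(self):
        trials = [TrialRecord(i, "ABCD"[i % 4], "pass", 0.0, 2000.0)
                  for i in range(120)]
        session = SessionLog("s", 1, trials)
        params = ORLParams(0.0, 0.0, 0.0, 0.0)
        assert log_likelihood(params, session) == pytest.approx(120 * math.log(0.5))

    def test_empty_session_scores_zero(self):
        params = ORLParams(0.2, 0.2, 1.0, 0.0)
        assert log_likelihood(params, SessionLog("s", 1, [])) == 0.0

    def test_matches_reference_loop_on_random_sessions(self, task_config):
        """Fast core vs literal trial-by-trial loop, 100 random sessions."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            params, session = random_session(task_config, rng)
            fast = log_likelihood(params, session)
            slow = log_likelihood_reference(params, session)
            assert abs(fast - slow) < 1e-10

    def test_all_pass_likelihood_ignores_learning_parameters(self):
        trials = [TrialRecord(i, "ABCD"[i % 4], "pass", 0.0, 2000.0)
                  for i in range(40)]
        session = SessionLog("s", 1, trials)
        base = log_likelihood(ORLParams(0.1, 0.1, 0.0, 0.9), session)
        for params in (ORLParams(0.9, 0.1, 0.0, 0.9),
                       ORLParams(0.1, 0.9, 0.0, 0.9),
                       ORLParams(0.1, 0.1, 7.0, 0.9)):
            assert log_likelihood(params, session) == pytest.approx(base)

    def test_timeouts_scored_as_pass(self, task_config):
        params = ORLParams(0.3, 0.2, 1.0, 0.5)
        play = SessionLog("s", 1, [TrialRecord(0, "A", "play", 100.0, 2100.0)])
        timed = SessionLog("s", 1, [TrialRecord(0, "A", "pass", 0.0, 2000.0,
                                                timeout=True)])
        passed = SessionLog("s", 1, [TrialRecord(0, "A", "pass", 0.0, 2000.0)])
        assert log_likelihood(params, timed) == log_likelihood(params, passed)
        assert log_likelihood(params, timed) != log_likelihood(params, play)

    def test_go_bias_raises_every_trial_play_probability(self, task_config):
        """Replaying a fixed session, a larger go bias strictly increases the
        play probability on every trial."""
        session = simulate_agent(ORLParams(0.3, 0.2, 2.0, 0.5), task_config,
                                 seed=9)

        def trial_probs(beta_b):
            params = ORLParams(0.3, 0.2, 2.0, beta_b)
            state = init_state(params)
            probs = []
            for t in session.trials:
                probs.append(play_probability(state, t.deck))
                state = update_state(state, t.deck, t.choice,
                                     t.outcome if t.choice == "play" else 0.0,
                                     params)
            return np.array(probs)

        low, mid, high = trial_probs(0.0), trial_probs(0.5), trial_probs(1.5)
        assert np.all(mid > low) and np.all(high > mid)


class TestSimulateAgent:
    def test_null_params_play_rate_near_half(self, task_config):
        rates = []
        params = ORLParams(0.0, 0.0, 0.0, 0.0)
        for seed in range(100):
            log = simulate_agent(params, task_config, seed=seed)
            rates.append(np.mean([t.choice == "play" for t in log.trials]))
        assert abs(np.mean(rates) - 0.5) < 0.05

    def test_extreme_go_bias_saturates_play_rate(self, task_config):
        log = simulate_agent(ORLParams(0.0, 0.0, 0.0, 8.0), task_config, seed=1)
        rate = np.mean([t.choice == "play" for t in log.trials])
        assert rate >= 0.99

    def test_same_seed_reproduces_session(self, task_config, example_params):
        a = simulate_agent(example_params, task_config, seed=11)
        b = simulate_agent(example_params, task_config, seed=11)
        assert [(t.deck, t.choice, t.outcome) for t in a.trials] == \
            [(t.deck, t.choice, t.outcome) for t in b.trials]

    def test_generating_parameters_beat_perturbed_ones(self, task_config):
        """Self-consistency: on average over 50 agents, the generating
        parameters score a higher log-likelihood than +-0.3 perturbations."""
        rng = np.random.default_rng(3)
        gen = ORLParams(0.35, 0.25, 2.0, 0.8)
        deltas = []
        for i in range(50):
            session = simulate_agent(gen, task_config, seed=int(rng.integers(2**31)))
            ll_gen = log_likelihood(gen, session)
            pert = ORLParams(
                min(1.0, gen.A_rew + 0.3), max(0.0, gen.A_pun - 0.3),
                gen.beta_f + 0.3, gen.beta_b - 0.3,
            )
            deltas.append(ll_gen - log_likelihood(pert, session))
        assert np.mean(deltas) > 0

    def test_no_fictive_updating_leaves_unplayed_deck_frequencies_zero(
            self, task_config):
        params = ORLParams(0.5, 0.5, 2.0, 3.0)
        mc = ModelConfig(fictive_updating=False)
        session = simulate_agent(params, task_config, model_config=mc, seed=5)
        state = init_state(params)
        played_decks = set()
        for t in session.trials:
            if t.choice == "play":
                played_decks.add(t.deck)
            state = update_state(state, t.deck, t.choice,
                                 t.outcome if t.choice == "play" else 0.0,
                                 params, mc)
        from popigt.pop_orl import DECK_INDEX

        for d, j in DECK_INDEX.items():
            if d not in played_decks:
                assert state.EF[j] == 0.0
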