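import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from advicebandit import (
    AgentParams,
    choice_probabilities,
    init_state,
    net_values,
    subject_loglik,
    trial_step,
    update_advice_value,
    update_card_value,
)
from conftest import random_trial_sequence
from oracle import oracle_loglik

ALL_MODELS = [1, 2, 3, 4, 5]


def _as_records(df: pd.DataFrame):
    return df.to_dict("records")


class TestStepArithmetic:
    def test_card_update_moves_only_chosen_card(self):
        state = init_state()
        new, trace = update_card_value(state, choice=2, reward=1.0, alpha=0.1)
        assert trace.delta_card == pytest.approx(0.5)
        assert new.q_cards[2] == pytest.approx(0.55)
        assert np.all(new.q_cards[[0, 1, 3]] == 0.5)
        # delta is reported even with zero learning rate
        frozen, tr0 = update_card_value(state, 2, 1.0, alpha=0.0)
        assert np.all(frozen.q_cards == 0.5) and tr0.delta_card == pytest.approx(0.5)

    def test_fully_predicted_outcome_changes_nothing(self):
        state = init_state()
        state.q_cards[1] = 1.0
        new, trace = update_card_value(state, 1, 1.0, alpha=0.4)
        assert trace.delta_card == 0.0
        assert new.q_cards[1] == 1.0

    def test_advice_update_follow_branch(self):
        state = init_state()
        new = update_advice_value(state, followed=True, reward=1.0, alpha=0.2,
                                  delta_card=0.5, model_id=3)
        assert new.q_follow == pytest.approx(0.6)
        assert new.q_not_follow == 0.5

    def test_model4_zero_moderator_freezes_advice_values(self):
        state = init_state()
        new = update_advice_value(state, True, 1.0, alpha=0.2, delta_card=0.0,
                                  model_id=4)
        assert new.q_follow == 0.5

    def test_advice_update_rejected_for_models_without_advice_values(self):
        with pytest.raises(ValueError):
            update_advice_value(init_state(), True, 1.0, 0.2, 0.5, model_id=2)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            update_card_value(init_state(), 0, 1.0, alpha=1.5)


class TestNetValues:
    def test_model2_reduces_to_cards_when_phi_zero(self):
        state = init_state()
        state.q_cards[:] = [0.1, 0.9, 0.5, 0.5]
        params = AgentParams(0.3, 5.0, phi=0.0)
        np.testing.assert_allclose(
            net_values(state, (0, 1), 1, True, params, 2), [0.1, 0.9]
        )

    def test_model5_with_omega_one_matches_model2(self):
        state = init_state()
        state.q_cards[:] = [0.3, 0.8, 0.5, 0.5]
        p = AgentParams(0.3, 5.0, omega=1.0, phi=0.2)
        np.testing.assert_allclose(
            net_values(state, (0, 1), 0, True, p, 5),
            net_values(state, (0, 1), 0, True, p, 2),
        )

    def test_model5_blend_arithmetic(self):
        state = init_state()
        state.q_cards[:] = [0.8, 0.2, 0.5, 0.5]
        state.q_follow = 0.4
        state.q_not_follow = 0.5
        p = AgentParams(0.3, 5.0, omega=0.5, phi=0.1)
        qnet = net_values(state, (0, 1), 0, True, p, 5)
        assert qnet[0] == pytest.approx(0.5 * 0.8 + 0.5 * 0.4 + 0.1)
        assert qnet[1] == pytest.approx(0.5 * 0.2 + 0.5 * 0.5)

    def test_concealed_trials_use_raw_card_values_in_every_model(self):
        state = init_state()
        state.q_cards[:] = [0.8, 0.2, 0.5, 0.5]
        state.q_follow = 0.9
        p = AgentParams(0.3, 5.0, omega=0.4, phi=0.7)
        for mid in ALL_MODELS:
            np.testing.assert_allclose(
                net_values(state, (0, 1), None, False, p, mid), [0.8, 0.2]
            )

    def test_revealed_without_advice_is_an_error(self):
        with pytest.raises(ValueError):
            net_values(init_state(), (0, 1), None, True, AgentParams(0.3, 5.0), 2)


class TestChoiceProbabilities:
    @pytest.mark.parametrize("beta", [0.0, 1.0, 50.0])
    def test_equal_values_give_coin_flip(self, beta):
        np.testing.assert_allclose(choice_probabilities([0.4, 0.4], beta), [0.5, 0.5])

    def test_softmax_arithmetic(self):
        probs = choice_probabilities([1.0, 0.5], beta=2.0)
        assert probs[0] == pytest.approx(1.0 / (1.0 + np.exp(-1.0)))
        assert probs.sum() == pytest.approx(1.0)

    def test_stable_at_extreme_beta(self):
        probs = choice_probabilities([1.0, 0.0], beta=1e4)
        assert np.isfinite(probs).all()
        assert probs[0] == pytest.approx(1.0)

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            choice_probabilities([0.5, 0.5], -1.0)


class TestSequenceLoglik:
    @pytest.mark.parametrize("model_id", ALL_MODELS)
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_independent_oracle(self, model_id, seed):
        """Vectorized likelihood equals the brute-force oracle to 1e-10."""
        rng = np.random.default_rng(seed)
        trials = random_trial_sequence(rng, n_trials=20, n_blocks=2)
        params = AgentParams(alpha=0.37, beta=4.2, omega=0.61, phi=-0.15)
        p = params.pinned(model_id)
        expected = oracle_loglik(
            _as_records(trials), p.alpha, p.beta, p.omega, p.phi, model_id
        )
        assert subject_loglik(trials, params, model_id) == pytest.approx(
            expected, abs=1e-10
        )

    def test_frozen_ten_trial_sequence(self):
        """Hand-specified 10-trial sequence; expectation frozen from the oracle."""
        trials = pd.DataFrame(
            {
                "subject": 0,
                "session": 0,
                "block": 0,
                "trial": range(10),
                "offer_a": [0, 0, 1, 2, 0, 1, 0, 2, 1, 0],
                "offer_b": [1, 2, 3, 3, 1, 2, 3, 3, 2, 2],
                "advised_card": [0, 2, 3, 2, 1, 1, 0, 3, 2, 0],
                "revealed": [1, 0, 1, 1, 0, 1, 1, 0, 1, 1],
                "choice": [0, 2, 3, 2, 1, 1, 3, 2, 2, 0],
                "reward": [1.0, 0.0, 1.0, 1.0, 0.0, 1.0, 0.0, 1.0, 1.0, 1.0],
                "rt": np.nan,
            }
        )
        params = AgentParams(alpha=0.3, beta=6.0, omega=0.7, phi=0.2)
        assert subject_loglik(trials, params, 5) == pytest.approx(
            -6.5047648666253535, abs=1e-10
        )

    @pytest.mark.parametrize("model_id", ALL_MODELS)
    def test_beta_zero_gives_log_half_per_trial(self, model_id):
        rng = np.random.default_rng(3)
        trials = random_trial_sequence(rng, n_trials=25, n_blocks=2)
        ll = subject_loglik(trials, AgentParams(0.3, 0.0, 0.7, 0.2), model_id)
        assert ll == pytest.approx(50 * np.log(0.5))

    def test_trial_step_composition_matches_sequence_loglik(self):
        """Summed trial_step log-probs (with block resets) equal the kernel."""
        rng = np.random.default_rng(4)
        trials = random_trial_sequence(rng, n_trials=15, n_blocks=2)
        params = AgentParams(0.25, 5.0, 0.6, 0.3)
        for mid in ALL_MODELS:
            total = 0.0
            state = None
            prev_block = None
            for _, row in trials.iterrows():
                if row["block"] != prev_block:
                    state = init_state()
                    prev_block = row["block"]
                logp, state, _ = trial_step(state, row, params, mid)
                total += logp
            assert subject_loglik(trials, params, mid) == pytest.approx(
                total, abs=1e-10
            )

    def test_choice_outside_offer_is_an_error(self):
        rng = np.random.default_rng(5)
        trials = random_trial_sequence(rng, n_trials=5, n_blocks=1)
        trials.loc[2, "choice"] = (trials.loc[2, ["offer_a", "offer_b"]].sum() + 1) % 4
        while trials.loc[2, "choice"] in (trials.loc[2, "offer_a"], trials.loc[2, "offer_b"]):
            trials.loc[2, "choice"] = (trials.loc[2, "choice"] + 1) % 4
        with pytest.raises(ValueError, match="outside offered pair"):
            subject_loglik(trials, AgentParams(0.3, 5.0), 1)

    def test_unsorted_input_is_an_error(self):
        rng = np.random.default_rng(6)
        trials = random_trial_sequence(rng, n_trials=5, n_blocks=2)
        shuffled = trials.sample(frac=1.0, random_state=1).reset_index(drop=True)
        with pytest.raises(ValueError, match="sorted"):
            subject_loglik(shuffled, AgentParams(0.3, 5.0), 1)

    def test_missing_choice_trials_are_skipped_without_state_update(self):
        rng = np.random.default_rng(7)
        trials = random_trial_sequence(rng, n_trials=12, n_blocks=1)
        dropped = trials.drop(index=[3, 8]).reset_index(drop=True)
        with_nan = trials.copy()
        with_nan.loc[[3, 8], "choice"] = np.nan
        p = AgentParams(0.3, 5.0, 0.7, 0.2)
        for mid in ALL_MODELS:
            assert subject_loglik(with_nan, p, mid) == pytest.approx(
                subject_loglik(dropped, p, mid), abs=1e-12
            )


class TestInvariants:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        alpha=st.floats(0.01, 0.99),
        beta=st.floats(0.0, 15.0),
        omega=st.floats(0.01, 0.99),
        phi=st.floats(-1.0, 1.0),
        seed=st.integers(0, 500),
    )
    def test_nesting_identities_exact(self, alpha, beta, omega, phi, seed):
        """M1 = M5(omega=1, phi=0); M2 = M5(omega=1); M3 = M5(phi=0)."""
        rng = np.random.default_rng(seed)
        trials = random_trial_sequence(rng, n_trials=12, n_blocks=1)
        cases = [
            (1, AgentParams(alpha, beta, 1.0, 0.0)),
            (2, AgentParams(alpha, beta, 1.0, phi)),
            (3, AgentParams(alpha, beta, omega, 0.0)),
        ]
        for mid, p in cases:
            assert subject_loglik(trials, p, mid) == pytest.approx(
                subject_loglik(trials, p, 5), abs=1e-10
            )

    @pytest.mark.parametrize("seed", [0, 1])
    def test_model3_equals_model4_when_card_delta_is_unit(self, seed):
        """When every card prediction error has magnitude 1, the moderator of
        model 4 is inert and models 3 and 4 coincide exactly.

        Construction: alpha = 1 with q_init = 0 keeps card values in {0, 1};
        choosing each reward opposite to the chosen card's tracked value
        forces |delta_card| = 1 on every trial.
        """
        rng = np.random.default_rng(seed)
        trials = random_trial_sequence(rng, n_trials=20, n_blocks=1)
        q = [0.0] * 4
        rewards = []
        for _, row in trials.iterrows():
            c = int(row["choice"])
            rewards.append(1.0 - q[c])
            q[c] = rewards[-1]  # alpha = 1 jumps the value to the reward
        trials["reward"] = rewards
        p = AgentParams(1.0, 4.0, 0.5, 0.0)
        ll3 = subject_loglik(trials, p, 3, q_init=0.0)
        ll4 = subject_loglik(trials, p, 4, q_init=0.0)
        assert ll3 != 0.0
        assert ll3 == pytest.approx(ll4, abs=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 500), model_id=st.sampled_from(ALL_MODELS))
    def test_q_values_bounded_and_probs_normalized(self, seed, model_id):
        rng = np.random.default_rng(seed)
        trials = random_trial_sequence(rng, n_trials=30, n_blocks=1)
        params = AgentParams(0.8, 7.0, 0.3, 0.9)
        state = init_state()
        for _, row in trials.iterrows():
            qnet = net_values(
                state,
                (row["offer_a"], row["offer_b"]),
                row["advised_card"] if row["revealed"] else None,
                bool(row["revealed"]),
                params.pinned(model_id),
                model_id,
            )
            probs = choice_probabilities(qnet, params.beta)
            assert probs.sum() == pytest.approx(1.0)
            assert (probs > 0).all() and (probs < 1).all()
            _, state, _ = trial_step(state, row, params, model_id)
            assert np.all(state.q_cards >= 0.0) and np.all(state.q_cards <= 1.0)
            assert 0.0 <= state.q_follow <= 1.0
            assert 0.0 <= state.q_not_follow <= 1.0

    @pytest.mark.parametrize("model_id", ALL_MODELS)
    def test_concealed_advice_never_enters_likelihood(self, model_id):
        """Permuting hidden advice labels leaves every model's loglik unchanged."""
        rng = np.random.default_rng(8)
        trials = random_trial_sequence(rng, n_trials=40, n_blocks=1)
        permuted = trials.copy()
        concealed = permuted["revealed"] == 0
        permuted.loc[concealed, "advised_card"] = permuted.loc[
            concealed, ["offer_a", "offer_b"]
        ].max(axis=1)
        p = AgentParams(0.3, 5.0, 0.7, 0.2)
        assert subject_loglik(trials, p, model_id) == pytest.approx(
            subject_loglik(permuted, p, model_id), abs=1e-12
        )
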