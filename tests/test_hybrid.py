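"""Hybrid RL model: values, likelihood, updates, RPEs, MAP fitting."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from twostep_ema.hybrid import (GeneratingDistribution, HybridParams, Priors,
                                choice_probabilities, decompose_rpes,
                                fit_subject, initial_values, mb_values,
                                negative_log_likelihood, penalized_nll,
                                simulate_agent, update_values)
from twostep_ema.task import TaskConfig

from conftest import simulate_cohort_trials


class TestMBValues:
    def test_symmetric_when_q2_constant(self):
        for c in (-2.0, 0.0, 3.5):
            q_mb = mb_values(np.full((2, 2), c), 0.8)
            assert np.allclose(q_mb, [c, c])

    def test_direct_arithmetic(self):
        q_mb = mb_values(np.array([[1.0, 2.0], [3.0, 4.0]]), 0.7)
        assert np.allclose(q_mb, [0.7 * 2 + 0.3 * 4, 0.7 * 4 + 0.3 * 2])
        assert np.allclose(q_mb, [2.6, 3.4])

    def test_uninformative_transitions(self):
        q_mb = mb_values(np.array([[1.0, 5.0], [-3.0, 2.0]]), 0.5)
        assert q_mb[0] == q_mb[1]

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            mb_values(np.array([[np.nan, 0.0], [0.0, 0.0]]), 0.7)


class TestChoiceProbabilities:
    def test_uniform_cases(self):
        assert np.allclose(choice_probabilities([1.3, 1.3], 2.0), [0.5, 0.5])
        assert np.allclose(choice_probabilities([9.0, -4.0], 0.0), [0.5, 0.5])

    def test_direct_arithmetic(self):
        p = choice_probabilities([2.6, 3.4], 1.0)
        expect = np.array([1.0, math.exp(0.8)]) / (1.0 + math.exp(0.8))
        assert np.allclose(p, expect, atol=1e-10)
        assert np.allclose(p, [0.3100, 0.6900], atol=5e-5)

    def test_overflow_safe_for_large_beta(self):
        p = choice_probabilities([100.0, -100.0], 1e8)
        assert np.all(np.isfinite(p)) and np.allclose(p, [1.0, 0.0])

    def test_repetition_bonus_shifts_toward_previous(self):
        p = choice_probabilities([0.0, 0.0], 1.0, rep=1.2, prev_action=1)
        assert p[1] > 0.5

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            choice_probabilities([0.0, 0.0], -1.0)


class TestUpdateValues:
    trial = dict(a1=0, s2=0, a2=1, points=4)

    def test_no_learning(self):
        params = HybridParams(0.0, 0.0, 0.7, 1.0, 1.0, 0.5, 0.0)
        latent = initial_values(params, 0.7)
        new, d1, d2 = update_values(latent, self.trial, params, 0.7)
        assert np.allclose(new.q_mf1, latent.q_mf1)
        assert np.allclose(new.q2, latent.q2)

    def test_trace_off_first_stage_uses_only_delta1(self):
        params = HybridParams(0.5, 0.5, 0.0, 1.0, 1.0, 0.5, 0.0)
        latent = initial_values(params, 0.7)
        new, d1, d2 = update_values(latent, self.trial, params, 0.7)
        # zero-initialized: delta1 = 0, so q_mf1 unchanged despite delta2 = 4
        assert d1 == 0.0 and d2 == 4.0
        assert new.q_mf1[0] == 0.0

    def test_hand_computed_update(self):
        params = HybridParams(0.5, 0.5, 1.0, 1.0, 1.0, 0.5, 0.0)
        latent = initial_values(params, 0.7)
        new, d1, d2 = update_values(latent, self.trial, params, 0.7)
        assert (d1, d2) == (0.0, 4.0)
        assert new.q2[0, 1] == 2.0
        assert new.q_mf1[0] == 2.0
        # derived values refreshed consistently
        assert np.allclose(new.q_mb1, [0.7 * 2.0, 0.3 * 2.0])
        assert np.allclose(
            new.q_net1, 0.5 * new.q_mb1 + 0.5 * new.q_mf1)


class TestLikelihood:
    def test_uniform_policy_closed_form(self, rng, mixed_params):
        trials = simulate_agent(mixed_params, TaskConfig(), rng)
        uniform = HybridParams(0.5, 0.5, 0.5, 0.0, 0.0, 0.5, 0.0)
        nll = negative_log_likelihood(uniform, trials)
        assert nll == pytest.approx(402 * math.log(2), abs=1e-9)

    def test_appending_trial_increases_nll(self, rng, mixed_params):
        trials = simulate_agent(mixed_params, TaskConfig(n_trials=100), rng)
        nlls = [
            negative_log_likelihood(mixed_params, trials.iloc[:k])
            for k in (50, 75, 100)
        ]
        assert nlls[0] < nlls[1] < nlls[2]

    def test_malformed_sequence_rejected(self, rng, mixed_params):
        trials = simulate_agent(mixed_params, TaskConfig(n_trials=20), rng)
        shuffled = trials.sample(frac=1.0, random_state=1)
        with pytest.raises(ValueError, match="trial"):
            negative_log_likelihood(mixed_params, shuffled)
        mixed = pd.concat([trials, trials.assign(subject="other")])
        with pytest.raises(ValueError, match="subject"):
            negative_log_likelihood(mixed_params, mixed)
        with pytest.raises(ValueError):
            negative_log_likelihood(mixed_params, trials.iloc[:0])

    def test_model_free_blind_to_transition_structure(self, rng):
        """Relabeling second-stage states leaves a pure MF likelihood
        unchanged but changes a pure MB likelihood."""
        gen = HybridParams(0.5, 0.5, 0.8, 2.0, 2.0, 0.5, 0.1)
        trials = simulate_agent(gen, TaskConfig(n_trials=150), rng)
        permuted = trials.copy()
        permuted["s2"] = 1 - permuted["s2"]
        permuted["transition"] = np.where(
            permuted["transition"] == "common", "rare", "common")
        mf = HybridParams(0.5, 0.5, 0.8, 2.0, 2.0, 0.0, 0.1)
        mb = HybridParams(0.5, 0.5, 0.8, 2.0, 2.0, 1.0, 0.1)
        assert negative_log_likelihood(mf, trials) == pytest.approx(
            negative_log_likelihood(mf, permuted), abs=1e-10)
        assert abs(
            negative_log_likelihood(mb, trials)
            - negative_log_likelihood(mb, permuted)
        ) > 1.0


@settings(max_examples=20, deadline=None)
@given(
    omega=st.floats(0.0, 1.0),
    alpha=st.floats(0.0, 1.0),
    seed=st.integers(0, 2**31 - 1),
)
def test_net_values_mix_exactly(omega, alpha, seed):
    params = HybridParams(alpha, alpha, 0.5, 1.0, 1.0, omega, 0.0)
    rng = np.random.default_rng(seed)
    latent = initial_values(params, 0.7)
    for _ in range(20):
        trial = dict(a1=int(rng.integers(2)), s2=int(rng.integers(2)),
                     a2=int(rng.integers(2)),
                     points=int(rng.choice([-3, -1, 2, 5])))
        latent, _, _ = update_values(latent, trial, params, 0.7)
        mix = omega * latent.q_mb1 + (1.0 - omega) * latent.q_mf1
        assert np.max(np.abs(latent.q_net1 - mix)) == 0.0


class TestSimulateAgent:
    def test_uniform_policy_choice_rates(self, rng):
        params = HybridParams(0.5, 0.5, 0.5, 0.0, 0.0, 0.5, 0.0)
        trials = simulate_agent(params, TaskConfig(n_trials=5000), rng)
        for col in ("a1", "a2"):
            assert abs(trials[col].mean() - 0.5) < 0.03

    def test_model_based_stay_pattern(self, rng):
        """A pure MB agent repeats rewarded choices after common but not
        rare transitions; a pure MF(lambda=1) agent repeats after reward
        regardless of transition."""
        mb = HybridParams(0.6, 0.6, 0.6, 3.0, 3.0, 1.0, 0.0)
        trials = simulate_cohort_trials(lambda i, r: mb, 10, 500, rng)
        stay_cc, stay_cr = _stay_after_reward(trials)
        assert stay_cc > stay_cr

        mf = HybridParams(0.6, 0.6, 1.0, 3.0, 3.0, 0.0, 0.0)
        trials = simulate_cohort_trials(lambda i, r: mf, 10, 500, rng)
        srw, spun = _stay_by_outcome(trials)
        assert srw > spun


def _stay_after_reward(trials):
    stays_common, stays_rare = [], []
    for _, grp in trials.groupby("subject"):
        a1 = grp["a1"].to_numpy()
        pts = grp["points"].to_numpy()
        tr = grp["transition"].to_numpy()
        for i in range(1, len(grp)):
            if pts[i - 1] > 0:
                (stays_common if tr[i - 1] == "common" else stays_rare).append(
                    a1[i] == a1[i - 1])
    return np.mean(stays_common), np.mean(stays_rare)


def _stay_by_outcome(trials):
    rew, pun = [], []
    for _, grp in trials.groupby("subject"):
        a1 = grp["a1"].to_numpy()
        pts = grp["points"].to_numpy()
        for i in range(1, len(grp)):
            (rew if pts[i - 1] > 0 else pun).append(a1[i] == a1[i - 1])
    return np.mean(rew), np.mean(pun)


class TestRPEDecomposition:
    def test_first_trial_onset_rpes_zero(self, rng, mixed_params):
        trials = simulate_agent(mixed_params, TaskConfig(n_trials=30), rng)
        rpes = decompose_rpes(mixed_params, trials)
        first = rpes[(rpes["trial"] == 1) & (rpes["event"] == "onset2")]
        assert (first[["delta_mf", "delta_mb", "delta_unique"]] == 0).all().all()

    def test_outcome_events_share_rpe(self, rng, mixed_params):
        trials = simulate_agent(mixed_params, TaskConfig(n_trials=100), rng)
        rpes = decompose_rpes(mixed_params, trials)
        outcome = rpes[rpes["event"] == "outcome"]
        assert np.all(outcome["delta_unique"] == 0.0)
        assert np.allclose(outcome["delta_mf"], outcome["delta_mb"])


class TestFitting:
    def test_empty_trials_error(self, rng):
        with pytest.raises(ValueError):
            fit_subject(pd.DataFrame(columns=["subject", "trial", "a1", "s2",
                                              "a2", "points"]), rng=rng)

    def test_few_trials_warns(self, rng, mixed_params):
        trials = simulate_agent(mixed_params, TaskConfig(n_trials=30), rng)
        with pytest.warns(UserWarning, match="trials"):
            fit_subject(trials, n_restarts=1, rng=rng)

    def test_fit_beats_generating_parameters(self, rng, mixed_params):
        trials = simulate_agent(mixed_params, TaskConfig(n_trials=300), rng)
        priors = Priors()
        fit = fit_subject(trials, priors=priors, n_restarts=4, rng=rng)
        assert fit.converged and fit.n_restarts_converged >= 1
        at_truth = penalized_nll(mixed_params, trials, priors)
        assert fit.penalized_nll <= at_truth + 1e-6
        assert fit.nll >= 0.0

    def test_uniform_data_gives_small_betas(self, rng):
        uniform = HybridParams(0.5, 0.5, 0.5, 0.0, 0.0, 0.5, 0.0)
        betas = []
        for _ in range(5):
            trials = simulate_agent(uniform, TaskConfig(n_trials=300), rng)
            fit = fit_subject(trials, n_restarts=4, rng=rng)
            betas.append((fit.params.beta1, fit.params.beta2))
        med = np.median(np.array(betas), axis=0)
        assert np.all(med < 0.3)


def test_generating_distribution_within_bounds(rng):
    gen = GeneratingDistribution()
    for _ in range(200):
        gen.sample(rng)  # HybridParams validates bounds on construction
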