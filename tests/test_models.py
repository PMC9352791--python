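"""Choice models: probabilities, heuristics, zoo composition, simulation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import norm

from mfarm import models
from mfarm.beliefs import BeliefEntry
from mfarm.models import (ModelSpec, apply_epsilon, choice_likelihood,
                          enumerate_model_zoo, hybrid_choice_probs,
                          simulate_session, thompson_choice_probs,
                          ucb_choice_probs)
from mfarm.taskgen import Bandit, GenerativeConfig, Trial, make_session
from conftest import GEN_PARAMS


def _belief(qs, ss, ns=(3, 1, 0)):
    return tuple(BeliefEntry(q, s, n) for q, s, n in zip(qs, ss, ns))


class TestModelZoo:
    def test_sixteen_distinct_models(self):
        zoo = enumerate_model_zoo()
        assert len(zoo) == 16
        assert len({s.label for s in zoo}) == 16

    def test_contains_named_winners(self):
        labels = {s.label for s in enumerate_model_zoo()}
        assert "Thompson+eta+eps" in labels  # winning model
        assert "UCB+eta+eps" in labels       # runner-up model
        assert {"Thompson", "UCB", "Random"} <= labels


class TestUcb:
    def test_symmetry_gives_uniform(self):
        p = ucb_choice_probs(_belief([5, 5, 5], [1, 1, 1], (1, 1, 1)), 1.0, 2.0)
        assert np.allclose(p, 1 / 3)

    def test_softmax_arithmetic(self):
        # values (1,0,0) at unit temperature
        p = ucb_choice_probs(_belief([1, 0, 0], [1e-12] * 3, (1, 1, 1)), 0.0, 1.0)
        e = np.e
        assert np.allclose(p, [e / (e + 2), 1 / (e + 2), 1 / (e + 2)], atol=1e-6)

    def test_high_precision_limit_is_argmax(self):
        p = ucb_choice_probs(_belief([6, 5, 4], [0.5] * 3, (1, 1, 1)), 0.0, 500.0)
        assert p[0] > 0.999

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            ucb_choice_probs(_belief([np.inf, 5, 4], [1, 1, 1]), 1.0, 1.0)


class TestThompson:
    def test_identical_posteriors_uniform(self):
        p = thompson_choice_probs(_belief([5, 5, 5], [1, 1, 1], (1, 1, 1)))
        assert np.allclose(p, 1 / 3, atol=1e-9)

    def test_two_arm_closed_form(self):
        # third arm pushed far below: effectively a 2-arm race
        p = thompson_choice_probs(
            _belief([6, 5, -100], [0.5, 0.5, 1e-6], (1, 1, 1)), n_nodes=40)
        assert p[0] == pytest.approx(norm.cdf(1 / np.sqrt(0.5)), abs=1e-4)

    def test_three_arm_matches_mc_oracle(self):
        p = thompson_choice_probs(_belief([6, 5, 5], [1, 1, 1], (1, 1, 1)))
        rng = np.random.default_rng(0)
        draws = np.array([6, 5, 5]) + rng.standard_normal((1_000_000, 3))
        mc = np.bincount(draws.argmax(axis=1), minlength=3) / 1e6
        assert np.allclose(p, mc, atol=0.005)

    def test_shift_invariance(self):
        b1 = _belief([6, 5, 4], [1.0, 0.7, 1.3], (1, 1, 1))
        b2 = _belief([9, 8, 7], [1.0, 0.7, 1.3], (1, 1, 1))
        assert np.allclose(thompson_choice_probs(b1), thompson_choice_probs(b2),
                           atol=1e-9)

    def test_novelty_bonus_shifts_novel_arm(self):
        base = thompson_choice_probs(_belief([5, 5, 5], [1, 1, 1]))
        boosted = thompson_choice_probs(_belief([5, 5, 5], [1, 1, 1]), eta=2.0)
        assert boosted[2] > base[2]

    def test_mc_mode_close_to_quadrature(self):
        b = _belief([6, 5.2, 4.8], [1.1, 0.8, 1.0], (1, 1, 1))
        pq = thompson_choice_probs(b, method="quadrature")
        pm = thompson_choice_probs(b, method="mc", n_draws=200_000, seed=3)
        assert np.allclose(pq, pm, atol=0.005)


class TestEpsilon:
    def test_identity_and_uniform_limits(self):
        p = np.array([0.7, 0.2, 0.1])
        assert np.allclose(apply_epsilon(p, 0.0), p)
        assert np.allclose(apply_epsilon(p, 1.0), 1 / 3)

    def test_arithmetic(self):
        assert np.allclose(apply_epsilon([0.7, 0.2, 0.1], 0.3),
                           [0.59, 0.24, 0.17])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            apply_epsilon([1, 0, 0], 1.5)

    @given(st.floats(0, 1), st.permutations([0, 1, 2]))
    def test_affine_and_commutes_with_relabelling(self, eps, perm):
        p = np.array([0.6, 0.3, 0.1])
        perm = np.array(perm)
        a = apply_epsilon(p[perm], eps)
        b = apply_epsilon(p, eps)[perm]
        assert np.allclose(a, b, atol=1e-12)
        assert apply_epsilon(p, eps).sum() == pytest.approx(1.0, abs=1e-12)
        assert (apply_epsilon(p, eps) >= eps / 3 - 1e-12).all()


class TestHybrid:
    def test_endpoint_weights(self):
        pu, pt = np.array([1.0, 0, 0]), np.array([0, 1.0, 0])
        assert np.allclose(hybrid_choice_probs(pu, pt, 1.0), pu)
        assert np.allclose(hybrid_choice_probs(pu, pt, 0.0), pt)
        assert np.allclose(hybrid_choice_probs(pu, pt, 0.5), [0.5, 0.5, 0])

    def test_rejects_bad_weight(self):
        with pytest.raises(ValueError):
            hybrid_choice_probs([1, 0, 0], [0, 1, 0], 2.0)


def _symmetric_trial():
    return Trial(0, 0, "short", (
        Bandit("certain_standard", 6.0, 6.0, (6, 6, 6)),
        Bandit("standard", 6.0, 6.0, (6,)),
        Bandit("low_value", 5.0, 5.0, (5,)),
    ))


class TestChoiceLikelihood:
    def test_pure_random_is_one_third(self):
        spec = ModelSpec("thompson", use_epsilon=True)
        params = dict(sigma0_short=1.0, sigma0_long=1.0, Q0=5.0,
                      epsilon_short=1.0, epsilon_long=1.0)
        t = _symmetric_trial()
        for c in range(3):
            assert choice_likelihood(spec, params, t, c) == pytest.approx(1 / 3)

    def test_null_heuristics_reduce_to_base_model(self):
        t = _symmetric_trial()
        base = ModelSpec("thompson")
        full = ModelSpec("thompson", use_epsilon=True, use_novelty=True)
        pb = dict(sigma0_short=1.1, sigma0_long=1.2, Q0=5.0)
        pf = dict(pb, epsilon_short=0.0, epsilon_long=0.0,
                  eta_short=0.0, eta_long=0.0)
        for c in range(3):
            assert choice_likelihood(full, pf, t, c) == \
                pytest.approx(choice_likelihood(base, pb, t, c), abs=1e-12)

    def test_probabilities_sum_to_one(self):
        t = _symmetric_trial()
        for spec in enumerate_model_zoo():
            params = {}
            for name in models.param_names(spec):
                base = name.rsplit("_", 1)[0] if name.endswith(("_short", "_long")) else name
                params[name] = {"epsilon": 0.2, "eta": 1.5, "sigma0": 1.1,
                                "Q0": 5.0, "info_bonus": 1.0, "inv_temp": 2.0,
                                "w": 0.4}[base]
            total = sum(choice_likelihood(spec, params, t, c) for c in range(3))
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_rejects_bad_choice_index(self):
        with pytest.raises(ValueError):
            choice_likelihood(ModelSpec("uniform"), {}, _symmetric_trial(), 4)


class TestSimulation:
    def test_deterministic_given_seed(self, small_session, winning_spec):
        a = simulate_session(winning_spec, GEN_PARAMS, small_session,
                             np.random.default_rng(5))
        b = simulate_session(winning_spec, GEN_PARAMS, small_session,
                             np.random.default_rng(5))
        assert a.equals(b)

    def test_draw_counts_per_horizon(self, small_session, winning_spec):
        ch = simulate_session(winning_spec, GEN_PARAMS, small_session,
                              np.random.default_rng(6))
        per_trial = ch.groupby("trial_id").size()
        horizons = {t.trial_id: t.horizon for t in small_session.trials}
        for tid, n in per_trial.items():
            assert n == (1 if horizons[tid] == "short" else 6)

    def test_pure_random_agent_uniform_first_draws(self):
        cfg = GenerativeConfig(n_trials_per_horizon=100)
        spec = ModelSpec("thompson", use_epsilon=True)
        params = dict(sigma0_short=1.0, sigma0_long=1.0, Q0=5.0,
                      epsilon_short=1.0, epsilon_long=1.0)
        counts = np.zeros(3)
        for i in range(20):
            sess = make_session(f"p{i}", 1000 + i, cfg)
            ch = simulate_session(spec, params, sess, np.random.default_rng(i))
            first = ch[ch.draw_index == 0]
            counts += np.bincount(first["chosen_position"], minlength=3)
        freq = counts / counts.sum()
        assert np.allclose(freq, 1 / 3, atol=0.02)

    def test_huge_novelty_bonus_dominates(self, small_session):
        spec = ModelSpec("thompson", use_novelty=True)
        params = dict(sigma0_short=1.0, sigma0_long=1.0, Q0=5.0,
                      eta_short=50.0, eta_long=50.0)
        ch = simulate_session(spec, params, small_session,
                              np.random.default_rng(8))
        first = ch[ch.draw_index == 0]
        has_novel = {t.trial_id: any(b.type == "novel" for b in t.bandits)
                     for t in small_session.trials}
        novel_trials = first[first["trial_id"].map(has_novel)]
        assert (novel_trials["chosen_bandit_type"] == "novel").mean() > 0.99
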