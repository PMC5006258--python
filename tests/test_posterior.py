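"""Posterior engine: conjugate updates, utility, imputation, interim summary."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bayesrar import (
    InvalidInputError,
    TrialConfig,
    closed_form_utility_moments,
    fit_transition_models,
    impute_final_counts,
    posterior_summary,
    update_dirichlet,
    utility,
)
from helpers import E, N, Q, complete_records, rec

counts_triples = st.tuples(*[st.integers(0, 50)] * 3)


class TestUpdateDirichlet:
    @pytest.mark.parametrize(
        "prior,counts,expected",
        [
            ((1 / 3,) * 3, (0, 0, 0), (1 / 3, 1 / 3, 1 / 3)),
            ((1 / 3,) * 3, (2, 5, 3), (7 / 3, 16 / 3, 10 / 3)),
            ((1, 7, 2), (1, 1, 1), (2, 8, 3)),
        ],
    )
    def test_conjugate_addition(self, prior, counts, expected):
        assert update_dirichlet(prior, counts) == pytest.approx(expected)

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidInputError):
            update_dirichlet((1, 1, 1), (1, -1, 0))

    @given(c1=counts_triples, c2=counts_triples)
    @settings(max_examples=100, deadline=None)
    def test_sequential_updates_compose(self, c1, c2):
        prior = np.array([1 / 3, 1 / 3, 1 / 3])
        seq = update_dirichlet(update_dirichlet(prior, c1), c2)
        joint = update_dirichlet(prior, np.add(c1, c2))
        assert np.allclose(seq, joint)


class TestUtility:
    @pytest.mark.parametrize(
        "theta,expected",
        [
            ((0, 1, 0), 1.75),  # no quitting, certain efficacy: the ceiling
            ((1, 0, 0), 0.0),  # certain quit: the floor
            ((0.2, 0.5, 0.3), 1.175),
        ],
    )
    def test_values(self, theta, expected):
        assert utility(theta) == pytest.approx(expected)

    def test_off_simplex_rejected(self):
        with pytest.raises(InvalidInputError):
            utility((0.5, 0.5, 0.5))

    def test_negative_weight_rejected(self):
        with pytest.raises(InvalidInputError):
            utility((0.2, 0.5, 0.3), weight=-1)

    @given(
        a=st.floats(0.01, 1),
        b=st.floats(0.01, 1),
        c=st.floats(0.01, 1),
        w=st.floats(0, 2),
    )
    @settings(max_examples=200, deadline=None)
    def test_range(self, a, b, c, w):
        theta = np.array([a, b, c]) / (a + b + c)
        assert 0.0 <= utility(theta, w) <= 1.0 + w + 1e-9


class TestTransitionModels:
    def test_prior_only_models(self):
        models = fit_transition_models([])
        assert len(models) == 8  # 4 arms x 2 interim weeks
        for m in models.values():
            assert sum(m.post_eff) == pytest.approx(10.0)
            assert sum(m.post_noeff) == pytest.approx(10.0)
            assert m.post_eff == (1, 7, 2)
            assert m.post_noeff == (1, 2, 7)

    def test_single_patient_updates_one_branch(self):
        models = fit_transition_models([rec(2, None, E, E)])
        assert models[(2, 8)].post_eff == (1, 8, 2)
        for key, m in models.items():
            if key != (2, 8):
                assert m.post_eff == (1, 7, 2)
            assert m.post_noeff == (1, 2, 7)

    def test_interim_quitter_changes_nothing(self):
        models = fit_transition_models([rec(1, Q, Q, Q)])
        assert all(
            m.post_eff == (1, 7, 2) and m.post_noeff == (1, 2, 7)
            for m in models.values()
        )

    def test_patient_observed_at_both_interims_feeds_both_models(self):
        models = fit_transition_models([rec(3, N, N, N)])
        assert models[(3, 4)].post_noeff == (1, 2, 8)
        assert models[(3, 8)].post_noeff == (1, 2, 8)


class TestImputeFinalCounts:
    def test_complete_records_pass_through(self, rng):
        records = complete_records({1: (2, 5, 3), 2: (1, 0, 4)})
        models = fit_transition_models(records)
        counts = impute_final_counts(records, models, rng)
        assert counts[0].tolist() == [2, 5, 3]
        assert counts[1].tolist() == [1, 0, 4]

    def test_interim_quit_imputes_quit_deterministically(self, rng):
        counts = impute_final_counts(
            [rec(1, Q, None, None)], fit_transition_models([]), rng
        )
        assert counts[0].tolist() == [1, 0, 0]

    def test_record_without_any_visit_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            impute_final_counts([rec(1)], fit_transition_models([]), rng)

    def test_prior_only_eff_imputation_rate(self, rng):
        """Posterior-predictive mean of Dirichlet(1,7,2) puts 0.7 on efficacy."""
        models = fit_transition_models([])
        record = rec(2, None, E, None)
        n = 10_000
        hits = 0
        for _ in range(n):
            counts = impute_final_counts([record], models, rng)
            hits += int(counts[1, 1])
        rate = hits / n
        # per-imputation variance 0.7 * 0.3 -> SE ~ 0.0046
        assert rate == pytest.approx(0.7, abs=4 * 0.0046)


class TestPosteriorSummary:
    def test_symmetry_under_identical_data(self, config):
        counts = {a: (6, 10, 8) for a in (1, 2, 3, 4)}
        s = posterior_summary(
            complete_records(counts), config.with_(n_draws=40_000), seed=5
        )
        assert s.p_max.sum() == pytest.approx(1.0)
        assert np.allclose(s.p_max, 0.25, atol=0.02)
        assert np.allclose(s.mean_utility, s.mean_utility[0], atol=0.01)

    def test_degenerate_separation(self, config):
        counts = {1: (0, 1000, 0), 2: (1000, 0, 0), 3: (1000, 0, 0), 4: (1000, 0, 0)}
        s = posterior_summary(complete_records(counts), config, seed=5)
        assert s.p_max[0] > 0.999

    def test_empty_arm_summarized_from_prior(self, config):
        counts = {1: (2, 3, 1), 2: (1, 1, 1), 3: (0, 2, 2)}  # arm 4 empty
        s = posterior_summary(complete_records(counts), config, seed=3)
        mean4, var4 = closed_form_utility_moments(config.outcome_prior)
        assert s.n_enrolled[3] == 0
        assert s.mean_utility[3] == pytest.approx(mean4, abs=0.02)
        assert s.var_utility[3] == pytest.approx(var4, rel=0.15)

    def test_variance_matches_closed_form(self, config):
        """Pooled MC variance of U agrees with Dirichlet moment algebra."""
        from oracles import variance_se

        counts = (4, 11, 6)
        alpha = np.array(config.outcome_prior) + counts
        s = posterior_summary(
            complete_records({1: counts}),
            config.with_(n_arms=2, burn_in_n=80, burn_in_spare=20, n_draws=100_000, m_imputations=1),
            seed=9,
        )
        _, var = closed_form_utility_moments(alpha)
        assert abs(s.var_utility[0] - var) < 3 * variance_se(alpha)

    def test_complete_data_invariant_to_imputation_count(self, config):
        records = complete_records({1: (3, 6, 2), 2: (4, 4, 4), 3: (1, 8, 2), 4: (5, 3, 4)})
        s1 = posterior_summary(records, config.with_(m_imputations=1), seed=11)
        s2 = posterior_summary(records, config.with_(m_imputations=20), seed=11)
        assert np.array_equal(s1.p_max, s2.p_max)
        assert np.array_equal(s1.mean_utility, s2.mean_utility)

    def test_incomplete_records_use_transition_information(self, config):
        """Early efficacy on one arm pulls its posterior utility up."""
        base = {a: (5, 5, 5) for a in (1, 2, 3, 4)}
        records = complete_records(base) + [rec(1, E, E, None) for _ in range(30)]
        s = posterior_summary(records, config, seed=2)
        assert s.mean_utility[0] > s.mean_utility[1] + 0.05
        assert s.n_enrolled[0] == 45

    def test_parameter_recovery_at_large_n(self, config, rng):
        """With many complete patients the posterior concentrates on truth."""
        theta = np.array([0.25, 0.45, 0.30])
        n = 2000
        cats = rng.choice(3, size=n, p=theta)
        counts = tuple(np.bincount(cats, minlength=3))
        s = posterior_summary(
            complete_records({1: counts}), config.with_(n_draws=40_000), seed=7
        )
        assert s.mean_utility[0] == pytest.approx(utility(theta), abs=0.03)
        assert s.var_utility[0] < 2e-3

    def test_two_arm_p_max_matches_quadrature(self, config):
        from oracles import prob_first_arm_best

        cfg = config.with_(n_arms=2, burn_in_n=80, burn_in_spare=20, n_draws=200_000, m_imputations=1)
        counts_a, counts_b = (1, 5, 2), (3, 1, 4)
        s = posterior_summary(complete_records({1: counts_a, 2: counts_b}), cfg, seed=13)
        expected = prob_first_arm_best(
            np.array(cfg.outcome_prior) + counts_a,
            np.array(cfg.outcome_prior) + counts_b,
        )
        assert s.p_max[0] == pytest.approx(expected, abs=0.01)
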