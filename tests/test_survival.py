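"""Discrete-time survival: closed forms, oracles, and cross-checks against
lifelines (independent implementation)."""

import numpy as np
import pytest

from h2a._tensor import Tensor
from h2a.survival import (DiscreteTimeSurvival, concordance_index,
                          discretize_times, fit_hazard_model,
                          integrated_gradients, km_curve, km_stratify,
                          pool_slide, survival_from_hazard, survival_loss)
from h2a.synthetic import generate_survival_cohort


class TestDiscretize:
    def test_quartiles_of_one_to_hundred(self):
        times = np.arange(1.0, 101.0)
        censor = np.zeros(100, dtype=int)
        cuts, labels = discretize_times(times, censor)
        assert np.allclose(cuts, [25.75, 50.5, 75.25])
        counts = np.bincount(labels, minlength=4)
        assert counts.min() >= 24 and counts.max() <= 26

    def test_censored_subjects_labeled_by_interval(self):
        times = np.concatenate([np.arange(1.0, 101.0), [10.0, 99.0, 300.0]])
        censor = np.concatenate([np.zeros(100, int), [1, 1, 1]])
        cuts, labels = discretize_times(times, censor)
        assert labels[100] == 0          # censored at 10 < 25.75
        assert labels[101] == 3
        assert labels[102] == 3          # beyond last cut -> last interval

    def test_all_equal_times_degenerate(self):
        with pytest.raises(ValueError):
            discretize_times(np.ones(20), np.zeros(20, int))

    def test_too_few_uncensored(self):
        with pytest.raises(ValueError):
            discretize_times(np.arange(1.0, 11.0),
                             np.array([0, 0, 0] + [1] * 7))


class TestSurvivalFromHazard:
    def test_half_hazards_closed_form(self):
        surv = survival_from_hazard(np.full(4, 0.5))
        assert np.array_equal(surv, [1.0, 0.5, 0.25, 0.125, 0.0625])

    def test_starts_at_one_and_non_increasing(self):
        rng = np.random.default_rng(0)
        h = rng.uniform(0.01, 0.99, 6)
        surv = survival_from_hazard(h)
        assert surv[0] == 1.0
        assert (np.diff(surv) <= 0).all()
        assert np.allclose(surv[1:], np.cumprod(1 - h), atol=1e-15)

    def test_out_of_range_hazard_rejected(self):
        with pytest.raises(ValueError):
            survival_from_hazard(np.array([0.5, 1.0]))


class TestSurvivalLoss:
    def test_censored_with_zero_hazard_is_zero(self):
        assert survival_loss(np.zeros(4), y=2, c=1, beta=0.5) == 0.0

    def test_uncensored_perfect_hazard_is_zero(self):
        h = np.array([1.0, 0.5, 0.5, 0.5])
        assert survival_loss(h, y=0, c=0, beta=0.0) == 0.0

    def test_uncensored_first_interval_half_hazard_is_ln2(self):
        h = np.full(4, 0.5)
        assert np.isclose(survival_loss(h, y=0, c=0, beta=0.0), np.log(2),
                          atol=1e-15)

    def test_beta_blends_full_and_uncensored_terms(self):
        rng = np.random.default_rng(1)
        h = rng.uniform(0.1, 0.9, 4)
        l0 = survival_loss(h, y=2, c=0, beta=0.0)
        l1 = survival_loss(h, y=2, c=0, beta=1.0)
        lmid = survival_loss(h, y=2, c=0, beta=0.3)
        assert np.isclose(lmid, 0.7 * l0 + 0.3 * l1, atol=1e-12)
        # for uncensored subjects the two terms coincide
        assert np.isclose(l0, l1, atol=1e-12)

    def test_censored_beta_one_drops_term(self):
        rng = np.random.default_rng(2)
        h = rng.uniform(0.1, 0.9, 4)
        assert survival_loss(h, y=2, c=1, beta=1.0) == 0.0


class TestConcordance:
    def test_perfect_and_inverted(self):
        rng = np.random.default_rng(3)
        t = rng.uniform(1, 100, 15)
        c = np.zeros(15, int)
        assert concordance_index(t, t, c) == 1.0
        assert concordance_index(-t, t, c) == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_all_pairs_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        s = rng.standard_normal(n)
        t = rng.uniform(1, 50, n)
        c = rng.integers(0, 2, n)
        if (c == 0).sum() < 2:
            c[:2] = 0
        num = den = 0.0
        for i in range(n):
            for j in range(n):
                if t[i] < t[j] and c[i] == 0:
                    den += 1
                    if s[i] < s[j]:
                        num += 1
                    elif s[i] == s[j]:
                        num += 0.5
        assert np.isclose(concordance_index(s, t, c), num / den, atol=1e-12)

    def test_agrees_with_lifelines(self):
        from lifelines.utils import concordance_index as ll_ci
        rng = np.random.default_rng(4)
        n = 50
        s = rng.standard_normal(n)
        t = rng.uniform(1, 50, n)
        c = rng.integers(0, 2, n)
        # lifelines: event_observed = 1 means death observed (our c == 0)
        assert np.isclose(concordance_index(s, t, c),
                          ll_ci(t, s, event_observed=1 - c), atol=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        s = rng.standard_normal(30)
        t = rng.uniform(1, 20, 30)
        c = rng.integers(0, 2, 30)
        c[:2] = 0
        a = concordance_index(s, t, c)
        b = concordance_index(np.exp(2 * s) + 5, t, c)
        assert np.isclose(a, b, atol=1e-12)

    def test_no_admissible_pairs(self):
        with pytest.raises(ValueError):
            concordance_index([1.0, 2.0], [5.0, 5.0], [0, 0])


class TestPooling:
    def test_single_spot_both_modes(self):
        v = np.array([[1.0, 2.0, 3.0]])
        assert np.array_equal(pool_slide(v, "average"), v[0])
        assert np.allclose(pool_slide(v, "attention", np.ones(3)), v[0])

    def test_average_of_constant_matrix(self):
        v = np.tile([2.0, 5.0], (7, 1))
        assert np.array_equal(pool_slide(v, "average"), [2.0, 5.0])

    def test_zero_gate_attention_equals_average(self):
        rng = np.random.default_rng(6)
        v = rng.uniform(0, 3, (10, 4))
        assert np.allclose(pool_slide(v, "attention", np.zeros(4)),
                           pool_slide(v, "average"), atol=1e-12)

    def test_empty_slide_rejected(self):
        with pytest.raises(ValueError):
            pool_slide(np.zeros((0, 3)))


class TestKaplanMeier:
    def test_distinct_event_times_step_curve(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        c = np.zeros(4, int)
        times, surv = km_curve(t, c)
        assert np.allclose(surv, [0.75, 0.5, 0.25, 0.0])

    def test_all_censored_flat_at_one(self):
        times, surv = km_curve(np.arange(1.0, 6.0), np.ones(5, int))
        assert len(times) == 0

    def test_agrees_with_lifelines(self):
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(7)
        t = rng.uniform(1, 20, 40)
        c = rng.integers(0, 2, 40)
        times, surv = km_curve(t, c)
        kmf = KaplanMeierFitter().fit(t, event_observed=1 - c)
        for u, s in zip(times, surv):
            assert np.isclose(s, float(kmf.survival_function_at_times(u).iloc[0]),
                              atol=1e-10)

    def test_stratified_informative_cohort_orders_curves(self):
        co = generate_survival_cohort(300, 3, np.array([2.0, 0, 0]), 0.2,
                                      seed=8)
        risk = co.features @ np.array([2.0, 0, 0])
        res = km_stratify(risk, co.times, co.censor)
        t_hi, s_hi = res["high"]
        t_lo, s_lo = res["low"]
        grid = np.linspace(0.05, np.percentile(co.times, 90), 20)

        def at(ts, ss, u):
            idx = np.searchsorted(ts, u, side="right") - 1
            return 1.0 if idx < 0 else ss[idx]

        assert all(at(t_hi, s_hi, u) <= at(t_lo, s_lo, u) + 1e-12
                   for u in grid)

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError):
            km_stratify(np.ones(10), np.arange(1.0, 11.0),
                        np.zeros(10, int))


class TestIntegratedGradients:
    def test_zero_path_gives_zero_attributions(self):
        f = lambda t: (t * t).sum()
        x = np.array([1.0, 2.0])
        assert np.array_equal(integrated_gradients(f, x, x, steps=8),
                              np.zeros(2))

    def test_linear_model_exact_at_any_steps(self):
        w = np.array([0.5, -1.5, 2.0])
        f = lambda t: (t * Tensor(w)).sum()
        x = np.array([1.0, 2.0, -1.0])
        x0 = np.array([0.0, 1.0, 1.0])
        for steps in (2, 7, 64):
            ig = integrated_gradients(f, x, x0, steps=steps)
            assert np.allclose(ig, w * (x - x0), atol=1e-12)

    def test_completeness_for_nonlinear_model(self):
        rng = np.random.default_rng(9)
        w1 = Tensor(rng.standard_normal((4, 8)) * 0.5)
        w2 = Tensor(rng.standard_normal((8, 4)) * 0.5)

        def f(t):
            # discrete-hazard-style head: sigmoid interval outputs
            return ((t.reshape(1, 4) @ w1).elu() @ w2).sigmoid().sum()

        x = rng.standard_normal(4)
        x0 = np.zeros(4)
        ig = integrated_gradients(f, x, x0, steps=512)
        delta = float(f(Tensor(x)).data - f(Tensor(x0)).data)
        assert abs(ig.sum() - delta) <= 1e-3

    def test_shape_mismatch_rejected(self):
        f = lambda t: t.sum()
        with pytest.raises(ValueError):
            integrated_gradients(f, np.zeros(3), np.zeros(2), steps=4)


class TestHazardModelFitting:
    def test_zero_learning_rate_keeps_parameters(self):
        co = generate_survival_cohort(80, 3, np.ones(3), 0.2, seed=10)
        a = DiscreteTimeSurvival(epochs=5, learning_rate=0.0, seed=1)
        a.fit(co.features, (co.times, co.censor))
        b = DiscreteTimeSurvival(epochs=1, learning_rate=0.0, seed=1)
        b.fit(co.features, (co.times, co.censor))
        assert np.array_equal(a.model_.weight_matrix(),
                              b.model_.weight_matrix())
        assert a.loss_trace_[0] == pytest.approx(a.loss_trace_[-1])

    def test_informative_cohort_recovers_ranking(self):
        w = np.array([1.5, -1.0, 0.5, 0.0, 0.0])
        co = generate_survival_cohort(400, 5, w, 0.3, seed=11)
        model, trace = fit_hazard_model(co, epochs=300, learning_rate=0.05,
                                        seed=0)
        assert trace[-1] < trace[0]
        risk = model.risk_score(co.features)
        ci = concordance_index(-risk, co.times, co.censor)
        assert ci >= 0.7
        rec = model.weight_matrix().mean(axis=1)
        assert np.corrcoef(rec, w)[0, 1] >= 0.8

    def test_estimator_follows_sklearn_conventions(self):
        est = DiscreteTimeSurvival(beta=0.25)
        params = est.get_params()
        assert params["beta"] == 0.25
        est.set_params(epochs=10)
        assert est.epochs == 10
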