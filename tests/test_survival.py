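"""Kaplan-Meier, log-rank and binary Cox against closed forms, brute-force
oracles and an independent survival library."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prognosig import (
    SurvivalData,
    fit_binary_cox,
    km_estimate,
    logrank_test,
)
from prognosig.survival import cox_partial_loglik

from conftest import random_cohort


class TestSurvivalData:
    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            SurvivalData(times=np.array([1.0, -2.0]), events=np.array([1, 0]))
        with pytest.raises(ValueError):
            SurvivalData(times=np.array([1.0, 2.0]), events=np.array([1, 2]))
        with pytest.raises(ValueError):
            SurvivalData(times=np.array([1.0]), events=np.array([1]), ids=("a", "a"))
        with pytest.raises(ValueError):
            SurvivalData(times=np.array([]), events=np.array([]))

    def test_zero_time_rejected_not_nudged(self):
        with pytest.raises(ValueError):
            SurvivalData(times=np.array([0.0, 1.0]), events=np.array([1, 1]))


class TestKaplanMeier:
    def test_all_events_closed_form(self):
        data = SurvivalData(times=np.array([1.0, 2.0, 3.0]), events=np.array([1, 1, 1]))
        km = km_estimate(data)
        assert np.allclose(km.survival_probs, [2 / 3, 1 / 3, 0.0])
        assert np.array_equal(km.at_risk, [3, 2, 1])

    def test_single_patient(self):
        km = km_estimate(SurvivalData(times=np.array([5.0]), events=np.array([1])))
        assert km.survival_at(5.0) == 0.0
        assert km.survival_at(4.9) == 1.0

    def test_interleaved_censoring_matches_hand_product_limit(self):
        rng = np.random.default_rng(7)
        data = random_cohort(rng, 20, ties=True)
        km = km_estimate(data)
        # independent hand computation of prod(1 - d_i / n_i)
        s = 1.0
        expected = {}
        for t in np.unique(data.times):
            n_at_risk = int(np.sum(data.times >= t))
            d = int(np.sum((data.times == t) & (data.events == 1)))
            if d > 0:
                s *= 1.0 - d / n_at_risk
                expected[t] = s
        assert list(expected) == list(km.event_times)
        assert np.allclose(list(expected.values()), km.survival_probs)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=2, max_value=40), st.integers(min_value=0, max_value=10_000))
    def test_no_censoring_equals_empirical_survival(self, n, seed):
        rng = np.random.default_rng(seed)
        times = rng.exponential(5.0, n) + 0.01
        data = SurvivalData(times=times, events=np.ones(n, dtype=int))
        km = km_estimate(data)
        for t, s in zip(km.event_times, km.survival_probs):
            assert s == pytest.approx(np.mean(times > t))

    def test_all_censored_is_error(self):
        data = SurvivalData(times=np.array([1.0, 2.0]), events=np.array([0, 0]))
        with pytest.raises(ValueError, match="no events"):
            km_estimate(data)


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 0, 1, 1])
        data = SurvivalData(times=np.tile(t, 3), events=np.tile(e, 3))
        labels = np.repeat([1, 2, 3], 4)
        res = logrank_test(data, labels)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 2

    def test_permutation_oracle_small_cohort(self):
        rng = np.random.default_rng(11)
        data = random_cohort(rng, 12, ties=True)
        labels = np.array([0] * 6 + [1] * 6)
        res = logrank_test(data, labels, n_permutations=4000, seed=3)
        # exhaustive oracle: every placement of six group-1 patients
        from prognosig.survival import _logrank_statistic

        obs = _logrank_statistic(data.times, data.events, labels, 2)
        count = 0
        total = 0
        for combo in itertools.combinations(range(12), 6):
            lab = np.zeros(12, dtype=int)
            lab[list(combo)] = 1
            total += 1
            if _logrank_statistic(data.times, data.events, lab, 2) >= obs - 1e-12:
                count += 1
        exact_p = count / total
        assert res.permutation_p == pytest.approx(exact_p, abs=0.05)

    def test_strong_separation_three_groups(self):
        rng = np.random.default_rng(5)
        rates = np.repeat([1.0, 2.0, 4.0], 100)
        times = rng.exponential(1.0 / rates)
        data = SurvivalData(times=times + 1e-9, events=np.ones(300, dtype=int))
        res = logrank_test(data, np.repeat([1, 2, 3], 100))
        assert res.p_value < 1e-6

    def test_invariant_to_patient_order_and_group_names(self):
        rng = np.random.default_rng(9)
        data = random_cohort(rng, 30)
        labels = rng.integers(0, 3, 30)
        res = logrank_test(data, labels)
        perm = rng.permutation(30)
        data_p = SurvivalData(times=data.times[perm], events=data.events[perm])
        res_p = logrank_test(data_p, labels[perm])
        assert res_p.statistic == pytest.approx(res.statistic)
        res_r = logrank_test(data, np.array([17, 3, 99])[labels])
        assert res_r.statistic == pytest.approx(res.statistic)

    def test_single_group_is_error(self):
        data = SurvivalData(times=np.array([1.0, 2.0]), events=np.array([1, 1]))
        with pytest.raises(ValueError):
            logrank_test(data, np.array([1, 1]))

    def test_agrees_with_lifelines(self):
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(21)
        for _ in range(10):
            n = int(rng.integers(20, 60))
            data = random_cohort(rng, n, ties=bool(rng.integers(0, 2)))
            labels = rng.integers(0, 3, n)
            if np.unique(labels).size < 2:
                continue
            res = logrank_test(data, labels)
            ref = multivariate_logrank_test(data.times, labels, data.events)
            assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-8)
            assert res.p_value == pytest.approx(ref.p_value, rel=1e-8)


class TestBinaryCox:
    def test_null_covariate_small_beta(self):
        rng = np.random.default_rng(123)
        n = 200
        data = SurvivalData(times=rng.exponential(10, n) + 0.01, events=np.ones(n, dtype=int))
        group = rng.integers(0, 2, n)
        fit = fit_binary_cox(data, group)
        assert abs(fit.beta) < 0.5
        assert fit.wald_p > 0.05

    def test_identical_groups_give_zero_beta(self):
        t = np.array([1.0, 3.0, 4.0, 7.0])
        e = np.array([1, 1, 0, 1])
        data = SurvivalData(times=np.tile(t, 2), events=np.tile(e, 2))
        group = np.repeat([0, 1], 4)
        fit = fit_binary_cox(data, group)
        assert fit.beta == pytest.approx(0.0, abs=1e-10)
        assert fit.hazard_ratio == pytest.approx(1.0)

    def test_grid_search_likelihood_oracle(self):
        rng = np.random.default_rng(17)
        data = random_cohort(rng, 10, ties=True)
        group = np.array([0, 1, 0, 1, 1, 0, 0, 1, 0, 1])
        fit = fit_binary_cox(data, group)
        # independent Breslow partial log-likelihood evaluated on a grid
        order = np.argsort(data.times)
        times, events, g = data.times[order], data.events[order], group[order]
        taus = np.unique(times[events == 1])
        grid = np.arange(-5.0, 5.0 + 1e-9, 1e-4)
        ll = np.zeros_like(grid)
        for tau in taus:
            risk = times >= tau
            dead = (times == tau) & (events == 1)
            d1 = int(np.sum(dead & (g == 1)))
            d = int(dead.sum())
            r1 = int(np.sum(risk & (g == 1)))
            r0 = int(risk.sum()) - r1
            ll += d1 * grid - d * np.log(r0 + r1 * np.exp(grid))
        beta_star = grid[np.argmax(ll)]
        assert fit.beta == pytest.approx(beta_star, abs=1e-3)
        assert cox_partial_loglik(data, group, fit.beta) == pytest.approx(ll.max(), abs=1e-6)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_flipping_group_coding_negates_beta(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        data = random_cohort(rng, n)
        group = rng.integers(0, 2, n)
        if np.unique(group).size < 2:
            return
        a = fit_binary_cox(data, group)
        b = fit_binary_cox(data, 1 - group)
        assert b.beta == pytest.approx(-a.beta, abs=1e-6)
        assert b.hazard_ratio == pytest.approx(1.0 / a.hazard_ratio, rel=1e-6)

    def test_complete_separation_capped_with_flag(self):
        # group 1 dies first, every group-0 patient censored afterwards
        times = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        events = np.array([1, 1, 1, 0, 0, 0])
        group = np.array([1, 1, 1, 0, 0, 0])
        with pytest.warns(RuntimeWarning, match="separation"):
            fit = fit_binary_cox(SurvivalData(times=times, events=events), group)
        assert fit.separation
        assert np.isfinite(fit.beta)

    def test_wald_p_matches_lifelines_on_random_cohorts(self):
        from lifelines import CoxPHFitter
        import pandas as pd

        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(50):
            n = int(rng.integers(15, 40))
            ties = bool(rng.integers(0, 2))
            data = random_cohort(rng, n, ties=ties)
            group = rng.integers(0, 2, n)
            if np.unique(group).size < 2:
                continue
            fit = fit_binary_cox(data, group, ties="efron")
            if fit.separation:
                continue
            df = pd.DataFrame({"t": data.times, "e": data.events, "g": group})
            cph = CoxPHFitter().fit(df, "t", "e", fit_options={"precision": 1e-11})
            assert fit.beta == pytest.approx(cph.params_["g"], abs=1e-6)
            assert fit.wald_p == pytest.approx(cph.summary.loc["g", "p"], abs=1e-6)
            checked += 1
        assert checked >= 30

    def test_empty_group_is_error(self):
        data = SurvivalData(times=np.array([1.0, 2.0]), events=np.array([1, 1]))
        with pytest.raises(ValueError):
            fit_binary_cox(data, np.array([1, 1]))
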