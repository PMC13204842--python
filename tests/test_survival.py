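"""Survival and association statistics against brute-force oracles."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from cd138sno.survival import (
    association_2x2_variants,
    chisq_test,
    concordance_index,
    cox_fit,
    fisher_exact,
    km_estimate,
    logrank_test,
    mannwhitney,
    schoenfeld_check,
    spearman,
)


class TestKaplanMeier:
    def test_three_distinct_events_by_hand(self):
        curve = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_allclose(curve.at_risk, [3, 2, 1])

    def test_all_censored_constant_one(self):
        curve = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert curve.event_times.size == 0

    def test_single_event_steps_to_fraction(self):
        curve = km_estimate([5.0, 1.0, 2.0, 3.0], [0, 1, 0, 0])
        np.testing.assert_allclose(curve.survival, [3 / 4])

    def test_matches_empirical_survival_without_censoring(self, rng):
        """Oracle: with no censoring KM equals the empirical survivor function."""
        times = rng.exponential(10, size=40)
        curve = km_estimate(times, np.ones(40, dtype=int))
        for t, s in zip(curve.event_times, curve.survival):
            assert s == pytest.approx((times > t).mean(), abs=1e-12)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([0.0, 1.0], [1, 1])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        times = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        events = [1, 1, 0, 1, 1, 0]
        groups = [0, 0, 0, 1, 1, 1]
        chi2, df, p = logrank_test(times, events, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1 and p == pytest.approx(1.0)

    def test_matches_hand_computed_o_minus_e(self):
        """Oracle: O-E and hypergeometric variance accumulated by hand."""
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([1, 1, 1, 0, 1, 1])
        groups = np.array([0, 1, 0, 1, 1, 0])
        o_minus_e, var = 0.0, 0.0
        for t in sorted(times[events == 1]):
            at_risk = times >= t
            n, n1 = at_risk.sum(), (at_risk & (groups == 1)).sum()
            d = ((times == t) & (events == 1)).sum()
            d1 = ((times == t) & (events == 1) & (groups == 1)).sum()
            o_minus_e += d1 - d * n1 / n
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        expected_chi2 = o_minus_e**2 / var
        chi2, df, _ = logrank_test(times, events, groups)
        assert chi2 == pytest.approx(expected_chi2, rel=1e-10)
        assert df == 1

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [1, 1], [0, 0])


class TestCox:
    def test_coef_matches_partial_likelihood_grid(self):
        """Oracle: maximize the written-out partial likelihood directly."""
        x = np.array([1.0, 1.0, 0.0, 0.0])
        times = np.array([1.0, 3.0, 2.0, 4.0])
        events = np.array([1, 1, 1, 1])

        def neg_log_pl(beta):
            # events in time order: t=1 (x=1), t=2 (x=0), t=3 (x=1), t=4 (x=0)
            ll = 0.0
            for t in sorted(times):
                risk = times >= t
                xi = x[times == t][0]
                ll += beta * xi - np.log(np.exp(beta * x[risk]).sum())
            return -ll

        opt = minimize_scalar(neg_log_pl, bounds=(-10, 10), method="bounded")
        fit = cox_fit(pd.DataFrame({"x": x}), times, events)
        assert fit.summary.loc["x", "coef"] == pytest.approx(opt.x, abs=1e-4)

    def test_monotone_likelihood_flagged_not_raised(self):
        fit = cox_fit(
            pd.DataFrame({"x": [1.0, 0.0]}), [1.0, 2.0], [1, 1], run_schoenfeld=False
        )
        assert not fit.converged
        assert fit.flag

    def test_collinear_covariates_rejected(self, rng):
        x = rng.binomial(1, 0.5, 60).astype(float)
        frame = pd.DataFrame({"a": x, "b": x})
        times = rng.exponential(10, 60)
        with pytest.raises(ValueError, match="collinear|degenerate"):
            cox_fit(frame, times, np.ones(60, dtype=int))

    def test_breslow_agrees_with_efron_without_ties(self, rng):
        x = rng.binomial(1, 0.5, 80).astype(float)
        times = rng.exponential(1 / (0.05 * np.exp(0.8 * x)))
        events = np.ones(80, dtype=int)
        efron = cox_fit(pd.DataFrame({"x": x}), times, events, run_schoenfeld=False)
        breslow = cox_fit(pd.DataFrame({"x": x}), times, events, ties="breslow")
        assert breslow.summary.loc["x", "coef"] == pytest.approx(
            efron.summary.loc["x", "coef"], abs=1e-4
        )

    def test_wald_ci_brackets_hr(self, rng):
        x = rng.binomial(1, 0.4, 100).astype(float)
        times = rng.exponential(1 / (0.05 * np.exp(x)))
        fit = cox_fit(pd.DataFrame({"x": x}), times, np.ones(100, dtype=int))
        row = fit.summary.loc["x"]
        assert row["ci_low"] <= row["hr"] <= row["ci_high"]
        assert 0 <= fit.c_index <= 1


class TestSchoenfeld:
    def test_calibrated_under_proportional_hazards(self, rng):
        """Under PH the KM-transform test rejects at ~alpha (two-sided
        binomial 99% bounds); the identity transform, which correlates
        residuals with raw heavy-tailed times, may be conservative but must
        never be anti-conservative. Reversing the time axis of data with no
        covariate effect (the only case where reversal preserves
        proportionality) also stays within the anti-conservative bound."""
        n, reps, alpha = 300, 200, 0.05
        km_rej = id_rej = reversed_rej = 0
        for _ in range(reps):
            x = rng.binomial(1, 0.5, n).astype(float)
            times = rng.exponential(1 / (0.02 * np.exp(0.7 * x)))
            events = np.ones(n, dtype=int)
            fit = cox_fit(pd.DataFrame({"x": x}), times, events, run_schoenfeld=False)
            km_rej += schoenfeld_check(fit, time_transform="km")["x"] < alpha
            id_rej += schoenfeld_check(fit, time_transform="identity")["x"] < alpha
            null_times = rng.exponential(50.0, n)
            rev = null_times.max() + null_times.min() - null_times
            fit_rev = cox_fit(pd.DataFrame({"x": x}), rev, events, run_schoenfeld=False)
            reversed_rej += schoenfeld_check(fit_rev, time_transform="km")["x"] < alpha
        bound = 2.576 * np.sqrt(reps * alpha * (1 - alpha))
        assert abs(km_rej - reps * alpha) <= bound
        assert id_rej <= reps * alpha + bound
        assert reversed_rej <= reps * alpha + bound

    def test_requires_two_events(self):
        fit = cox_fit(
            pd.DataFrame({"x": [1.0, 0.0, 1.0, 0.0]}),
            [1.0, 2.0, 3.0, 4.0],
            [1, 0, 0, 0],
            run_schoenfeld=False,
        )
        with pytest.raises(ValueError, match="2 events"):
            schoenfeld_check(fit)


class TestConcordance:
    def test_identical_risks_give_half(self):
        assert concordance_index([1.0] * 5, [1, 2, 3, 4, 5], [1] * 5) == 0.5

    def test_perfect_ordering_gives_one(self):
        times = np.array([5.0, 3.0, 9.0, 1.0])
        assert concordance_index(-times, times, np.ones(4, dtype=int)) == 1.0

    def test_matches_pair_enumeration(self, rng):
        """Oracle: Harrell's C over all comparable pairs, enumerated."""
        n = 25
        times = rng.exponential(10, n)
        events = rng.binomial(1, 0.6, n)
        risk = rng.normal(size=n)
        num = den = 0.0
        for i, j in itertools.combinations(range(n), 2):
            a, b = (i, j) if times[i] < times[j] else (j, i)
            if times[a] == times[b]:
                if events[a] and events[b]:
                    den += 1
                    num += 0.5 if risk[a] != risk[b] else 0.5
                continue
            if not events[a]:
                continue  # shorter time censored: not comparable
            den += 1
            if risk[a] > risk[b]:
                num += 1
            elif risk[a] == risk[b]:
                num += 0.5
        assert concordance_index(risk, times, events) == pytest.approx(num / den)


class TestChiSquare:
    def test_proportional_table_statistic_zero(self):
        chi2, df, p = chisq_test([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0)
        assert df == 1 and p == pytest.approx(1.0)

    def test_matches_direct_sum_oracle(self, rng):
        counts = rng.integers(1, 40, size=(2, 3)).astype(float)
        expected = np.outer(counts.sum(1), counts.sum(0)) / counts.sum()
        stat_oracle = ((counts - expected) ** 2 / expected).sum()
        chi2, df, _ = chisq_test(counts)
        assert chi2 == pytest.approx(stat_oracle, abs=1e-12)
        assert df == 2

    def test_2x2_closed_form(self, rng):
        a, b, c, d = rng.integers(1, 30, size=4)
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        chi2, _, _ = chisq_test([[a, b], [c, d]])
        assert chi2 == pytest.approx(closed, rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chisq_test([[0, 0], [3, 4]])


class TestFisher:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[2, 0], [0, 2]], 1 / 3),
            ([[0, 5], [5, 0]], 2 / 252),
            ([[0, 0], [3, 4]], 1.0),  # zero margin
        ],
    )
    def test_enumerated_examples(self, table, expected):
        assert fisher_exact(table) == pytest.approx(expected, rel=1e-7)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1.5, 2], [3, 4]])

    def test_matches_full_margin_enumeration(self, rng):
        """Oracle: enumerate all tables with the observed margins and sum the
        probabilities of those no more likely than the observed table."""
        for _ in range(25):
            a, b, c, d = (int(v) for v in rng.integers(0, 6, size=4))
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            r1, c1, n = a + b, a + c, a + b + c + d

            def prob(k):
                return comb(r1, k) * comb(n - r1, c1 - k) / comb(n, c1)

            p_obs = prob(a)
            p_two = sum(
                prob(k)
                for k in range(max(0, c1 - (n - r1)), min(r1, c1) + 1)
                if prob(k) <= p_obs * (1 + 1e-7)
            )
            assert fisher_exact([[a, b], [c, d]]) == pytest.approx(p_two, rel=1e-7)


class TestMannWhitney:
    def test_exact_small_sample(self):
        u, p = mannwhitney([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert u == 0.0
        assert p == pytest.approx(2 / comb(6, 3))

    def test_identical_multisets_give_p_one(self):
        _, p = mannwhitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mannwhitney([], [1.0])

    def test_exact_matches_combinatorial_enumeration(self, rng):
        """Oracle: exact two-sided p by enumerating all label assignments."""
        x = rng.normal(size=4)
        y = rng.normal(size=5)
        pooled = np.concatenate([x, y])
        u_obs, p_obs = mannwhitney(x, y)

        def u_stat(idx):
            xs = pooled[list(idx)]
            ys = np.delete(pooled, list(idx))
            return sum((xi > ys).sum() + 0.5 * (xi == ys).sum() for xi in xs)

        mean_u = len(x) * len(y) / 2
        us = [u_stat(idx) for idx in itertools.combinations(range(9), 4)]
        extreme = sum(abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12 for u in us)
        assert p_obs == pytest.approx(extreme / len(us), rel=1e-10)

    def test_large_sample_uses_tie_corrected_normal(self, rng):
        from scipy import stats

        x = rng.integers(0, 5, 30).astype(float)
        y = rng.integers(1, 6, 35).astype(float)
        u, p = mannwhitney(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert u == ref.statistic
        assert p == pytest.approx(ref.pvalue, abs=1e-6)


class TestSpearman:
    def test_monotone_limits(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert spearman(x, [2.0, 4.0, 6.0, 8.0])[0] == pytest.approx(1.0)
        assert spearman(x, [8.0, 6.0, 4.0, 2.0])[0] == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_tied_instance_matches_rank_then_pearson(self, rng):
        """Oracle: average ranks then plain Pearson correlation."""
        from scipy.stats import rankdata

        x = rng.integers(0, 4, 20).astype(float)
        y = x + rng.integers(0, 3, 20)
        rho, _ = spearman(x, y)
        rx, ry = rankdata(x), rankdata(y)
        pearson = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(pearson, abs=1e-12)


class TestAssociationVariants:
    def test_reports_all_three_p_values(self):
        out = association_2x2_variants([[14, 21], [10, 66]])
        assert set(out) >= {"p_pearson", "p_yates", "p_fisher", "suggested_test"}
        assert out["suggested_test"] == "chi_square"

    def test_small_expected_count_suggests_fisher(self):
        out = association_2x2_variants([[4, 31], [0, 76]])
        assert out["min_expected"] < 5
        assert out["suggested_test"] == "fisher"
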