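"""Rank test, contingency tests, logistic regression, backward selection."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from prs_ldl.association_stats import (
    ConvergenceError,
    SeparationError,
    StatError,
    backward_select,
    dichotomize_ldl,
    fisher_exact,
    kruskal_wallis,
    logistic_fit,
    pearson_chi2,
)


def midranks(values):
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def kruskal_oracle(groups):
    """Direct evaluation of H = (12/(N(N+1))) sum n_g rbar_g^2 - 3(N+1),
    divided by the tie correction 1 - sum(t^3 - t)/(N^3 - N)."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = midranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie


class TestKruskalWallis:
    def test_matches_rank_formula(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]}
        result = kruskal_wallis(groups)
        expected = kruskal_oracle([np.array(v) for v in groups.values()])
        assert result.statistic == pytest.approx(expected, abs=1e-12)
        assert result.df == 1
        assert result.p_value == pytest.approx(sps.chi2.sf(expected, 1), abs=1e-12)

    def test_matches_rank_formula_with_ties(self):
        groups = [np.array([1.0, 2.0, 2.0, 5.0]), np.array([2.0, 3.0, 3.0]),
                  np.array([1.0, 5.0, 5.0, 5.0])]
        result = kruskal_wallis({"a": groups[0], "b": groups[1], "c": groups[2]})
        assert result.statistic == pytest.approx(kruskal_oracle(groups), abs=1e-12)
        assert result.df == 2

    def test_identical_groups_h_zero(self):
        result = kruskal_wallis({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert result.statistic == pytest.approx(0.0, abs=1e-12)

    def test_all_tied_degenerate(self):
        result = kruskal_wallis({"a": [5.0], "b": [5.0]})
        assert result.statistic == 0.0
        assert result.p_value == 1.0

    def test_two_group_p_equals_mann_whitney_normal_approx(self):
        rng = np.random.default_rng(8)
        x = np.round(rng.normal(0, 1, 40), 1)  # rounding induces ties
        y = np.round(rng.normal(0.4, 1, 30), 1)
        result = kruskal_wallis({"x": x, "y": y})
        # tie-corrected two-sided Mann-Whitney normal approximation
        n1, n2 = len(x), len(y)
        n = n1 + n2
        ranks = midranks(np.concatenate([x, y]))
        u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
        var = n1 * n2 / 12 * ((n + 1) - np.sum(counts**3 - counts) / (n * (n - 1)))
        z = (u - n1 * n2 / 2) / math.sqrt(var)
        p_mw = 2 * sps.norm.sf(abs(z))
        assert result.p_value == pytest.approx(p_mw, abs=1e-9)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 25), rng.normal(1, 1, 25)
        base = kruskal_wallis({"x": x, "y": y})
        warped = kruskal_wallis({"x": np.exp(x), "y": np.exp(y)})
        assert warped.statistic == pytest.approx(base.statistic, abs=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(StatError):
            kruskal_wallis({"a": [1.0], "b": []})

    def test_group_summaries(self):
        result = kruskal_wallis({"a": [3, 1, 2], "b": [9, 7]})
        summary = {s.label: s for s in result.groups}
        assert summary["a"].median == 2 and summary["a"].minimum == 1
        assert summary["b"].maximum == 9 and summary["b"].n == 2


class TestPearsonChi2:
    def test_sex_row_statistic(self):
        """Men/women split across the two cohorts: chi2 = 0.252."""
        result = pearson_chi2([[48, 45], [34, 27]])
        assert result.statistic == pytest.approx(0.252, abs=5e-4)
        assert result.df == 1

    def test_hypertension_row_statistic(self):
        """Hypertension 48/93 vs 45/60: chi2 = 8.368."""
        result = pearson_chi2([[48, 45], [45, 15]])
        assert result.statistic == pytest.approx(8.368, abs=5e-4)

    def test_independence_is_zero(self):
        assert pearson_chi2([[10, 10], [10, 10]]).statistic == pytest.approx(0.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(StatError):
            pearson_chi2([[0, 0], [5, 3]])

    @given(
        st.lists(st.integers(min_value=1, max_value=50), min_size=4, max_size=4)
    )
    @settings(max_examples=50, deadline=None)
    def test_equals_squared_two_proportion_z(self, counts):
        """On any 2x2 table the (uncorrected) chi-square equals the square of
        the two-proportion z statistic."""
        a, b, c, d = counts
        result = pearson_chi2([[a, b], [c, d]])
        n1, n2 = a + b, c + d
        p1, p2 = a / n1, c / n2
        pool = (a + c) / (n1 + n2)
        z = (p1 - p2) / math.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
        assert result.statistic == pytest.approx(z**2, abs=1e-10)


def fisher_2x2_oracle(a, b, c, d):
    """Brute force over all margin-fixed 2x2 tables, point-probability rule."""
    r1, c1, n = a + b, a + c, a + b + c + d
    lf = [math.lgamma(i + 1) for i in range(n + 1)]

    def log_p(x):
        x2, x3, x4 = r1 - x, c1 - x, n - r1 - c1 + x
        return (lf[r1] - lf[x] - lf[x2]) + (lf[n - r1] - lf[x3] - lf[x4]) - (
            lf[n] - lf[c1] - lf[n - c1]
        )

    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = {x: math.exp(log_p(x)) for x in range(lo, hi + 1)}
    obs = probs[a]
    return sum(p for p in probs.values() if p <= obs * (1 + 1e-7))


class TestFisherExact:
    def test_against_enumeration_oracle(self):
        assert fisher_exact([[1, 9], [11, 3]]) == pytest.approx(
            fisher_2x2_oracle(1, 9, 11, 3), abs=1e-12
        )

    def test_balanced_table_is_one(self):
        assert fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_statin_row_bound(self):
        """Statin use 29/93 vs 3/61 is extreme: p at or below 0.001."""
        assert fisher_exact([[29, 64], [3, 58]]) <= 0.001

    @given(st.lists(st.integers(min_value=0, max_value=12), min_size=4, max_size=4))
    @settings(max_examples=100, deadline=None)
    def test_2x2_matches_oracle_property(self, counts):
        a, b, c, d = counts
        table = np.array([[a, b], [c, d]])
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            return
        assert fisher_exact(table) == pytest.approx(
            fisher_2x2_oracle(a, b, c, d), abs=1e-12
        )

    @pytest.mark.parametrize(
        "table,expected",
        [
            # reference values from R fisher.test (independent implementation)
            ([[3, 4, 5], [5, 4, 3]], 0.8731582053698),
            ([[8, 1, 4], [2, 5, 7]], 0.0350630412348001),
        ],
    )
    def test_2x3_matches_r(self, table, expected):
        assert fisher_exact(table) == pytest.approx(expected, rel=1e-10)

    def test_2x3_matches_direct_enumeration(self):
        """Oracle: enumerate every margin-fixed 2x3 table directly."""
        table = np.array([[4, 2, 6], [3, 7, 1]])
        cols = table.sum(axis=0)
        r1, n = table[0].sum(), table.sum()

        def prob(xs):
            num = math.comb(int(cols[0]), xs[0]) * math.comb(int(cols[1]), xs[1]) * math.comb(
                int(cols[2]), xs[2]
            )
            return num / math.comb(int(n), int(r1))

        obs = prob(tuple(table[0]))
        total = sum(
            prob((x0, x1, r1 - x0 - x1))
            for x0 in range(int(cols[0]) + 1)
            for x1 in range(int(cols[1]) + 1)
            if 0 <= r1 - x0 - x1 <= cols[2]
            and prob((x0, x1, r1 - x0 - x1)) <= obs * (1 + 1e-7)
        )
        assert fisher_exact(table) == pytest.approx(total, abs=1e-12)

    def test_oversized_table_refused(self):
        big = np.full((2, 6), 200)
        with pytest.raises(StatError, match="pearson_chi2"):
            fisher_exact(big)


def simulate_logistic(beta, n, rng, intercept=-1.0):
    x = rng.normal(0, 1, size=(n, len(beta)))
    eta = intercept + x @ np.asarray(beta)
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return pd.DataFrame(x, columns=[f"x{i}" for i in range(len(beta))]), y


class TestLogisticFit:
    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        design, y = simulate_logistic([0.7, -0.4], 500, rng)
        fit = logistic_fit(y, design)
        sm_fit = sm.Logit(y, sm.add_constant(design.to_numpy())).fit(disp=0)
        np.testing.assert_allclose(
            [t.beta for t in fit.terms], sm_fit.params, rtol=1e-6, atol=1e-8
        )
        np.testing.assert_allclose(
            [t.se for t in fit.terms], sm_fit.bse, rtol=1e-5, atol=1e-8
        )

    def test_log_likelihood_trace_nondecreasing(self):
        rng = np.random.default_rng(12)
        design, y = simulate_logistic([1.5], 300, rng)
        fit = logistic_fit(y, design)
        trace = np.array(fit.ll_trace)
        assert (np.diff(trace) >= -1e-10).all()

    def test_recovers_known_coefficients(self):
        rng = np.random.default_rng(77)
        design, y = simulate_logistic([0.8], 2000, rng, intercept=-1.0)
        fit = logistic_fit(y, design)
        est = fit.estimate("x0")
        assert abs(est.beta - 0.8) < 3 * est.se
        intercept = fit.estimate("intercept")
        assert abs(intercept.beta - (-1.0)) < 3 * intercept.se

    def test_wald_type_i_error_rate(self):
        """Null covariate rejected at alpha=0.05 in roughly 5% of replicates."""
        rng = np.random.default_rng(2)
        rejections = 0
        reps = 200
        for _ in range(reps):
            design, y = simulate_logistic([0.0], 400, rng, intercept=0.0)
            fit = logistic_fit(y, design)
            rejections += fit.estimate("x0").p_value < 0.05
        assert 0.005 < rejections / reps < 0.105

    def test_odds_ratio_is_exp_beta(self):
        rng = np.random.default_rng(6)
        design, y = simulate_logistic([0.5], 400, rng)
        est = logistic_fit(y, design).estimate("x0")
        assert est.odds_ratio == pytest.approx(math.exp(est.beta), rel=1e-12)
        assert est.ci_low < est.odds_ratio < est.ci_high

    def test_complete_separation_detected(self):
        x = np.linspace(-2, 2, 40)
        x = x[x != 0]
        y = (x > 0).astype(int)
        with pytest.raises(SeparationError):
            logistic_fit(y, pd.DataFrame({"x": x}))

    def test_constant_outcome_rejected(self):
        with pytest.raises(StatError):
            logistic_fit(np.ones(10), pd.DataFrame({"x": np.arange(10.0)}))

    def test_constant_column_rejected(self):
        y = np.array([0, 1] * 10)
        with pytest.raises(StatError, match="constant column"):
            logistic_fit(y, pd.DataFrame({"x": np.ones(20)}))


class TestBackwardSelect:
    def test_alpha_one_drops_nothing(self):
        rng = np.random.default_rng(9)
        design, y = simulate_logistic([0.5, 0.0], 300, rng)
        trace, fit = backward_select(y, design, alpha=1.0)
        assert trace.steps == ()
        assert set(trace.final_terms) == {"x0", "x1"}

    def test_single_significant_candidate_zero_steps(self):
        rng = np.random.default_rng(10)
        design, y = simulate_logistic([2.0], 500, rng)
        trace, fit = backward_select(y, design, alpha=0.05)
        assert trace.steps == ()
        assert trace.final_terms == ("x0",)
        assert fit.estimate("x0").p_value < 0.05

    def test_null_term_dropped_strong_retained(self):
        """Selection consistency: over replicates the strong effect survives
        and the pure-noise term is usually eliminated."""
        rng = np.random.default_rng(11)
        reps, strong_kept, null_dropped = 60, 0, 0
        for _ in range(reps):
            design, y = simulate_logistic([2.0, 0.0], 1000, rng)
            trace, _ = backward_select(y, design, alpha=0.05)
            strong_kept += "x0" in trace.final_terms
            null_dropped += "x1" not in trace.final_terms
        assert strong_kept >= int(0.95 * reps)
        assert null_dropped >= int(0.80 * reps)

    def test_all_terms_eliminated_returns_intercept_only(self):
        rng = np.random.default_rng(14)
        design, y = simulate_logistic([0.0], 300, rng, intercept=0.3)
        trace, fit = backward_select(y, design, alpha=1e-6)
        assert trace.final_terms == ()
        assert [t.term for t in fit.terms] == ["intercept"]


class TestDichotomizeLdl:
    def test_thresholding(self):
        out = dichotomize_ldl([5.67, 4.9, 3.88, 6.0], threshold=4.9)
        assert out.tolist() == [1.0, 0.0, 0.0, 1.0]

    def test_missing_stays_missing(self):
        out = dichotomize_ldl([5.0, float("nan")])
        assert out[0] == 1.0 and math.isnan(out[1])

    def test_non_positive_rejected(self):
        with pytest.raises(StatError):
            dichotomize_ldl([3.2, -0.1])
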