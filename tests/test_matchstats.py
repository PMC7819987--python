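"""Statistical procedures against closed-form oracles, independent
library implementations, and exhaustive-search references."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from fuzzyct import (
    CohortParams,
    SeparationError,
    adjusted_or,
    balance_report,
    estimate_propensity,
    fit_logistic,
    generate_cohort,
    greedy_match,
    logit_caliper,
    matched_conditional_or,
    odds_ratio_2x2,
    roc_auc,
    standardized_difference,
    subgroup_interaction,
)
from fuzzyct.matchstats import roc_curve_points


def _design_from_2x2(a, b, c, d):
    """Single binary covariate design for a 2x2 table."""
    n1, n0 = a + b, c + d
    X = np.column_stack(
        [np.ones(n1 + n0), np.r_[np.ones(n1), np.zeros(n0)]]
    )
    y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    return X, y


class TestLogistic:
    def test_matches_2x2_closed_form(self):
        X, y = _design_from_2x2(44, 6, 22, 28)
        fit = fit_logistic(X, y)
        assert fit.coef[1] == pytest.approx(np.log(44 * 28 / (6 * 22)), abs=1e-6)
        assert fit.coef[0] == pytest.approx(np.log(22 / 28), abs=1e-6)
        assert fit.converged

    @given(
        a=st.integers(1, 60),
        b=st.integers(1, 60),
        c=st.integers(1, 60),
        d=st.integers(1, 60),
    )
    @settings(max_examples=60, deadline=None)
    def test_closed_form_on_random_tables(self, a, b, c, d):
        X, y = _design_from_2x2(a, b, c, d)
        fit = fit_logistic(X, y)
        assert fit.coef[1] == pytest.approx(
            np.log(a * d / (b * c)), abs=1e-5
        )

    def test_symmetric_data_zero_slope(self):
        X, y = _design_from_2x2(25, 25, 25, 25)
        assert fit_logistic(X, y).coef[1] == pytest.approx(0.0, abs=1e-8)

    def test_separation_raises(self):
        X = np.column_stack([np.ones(10), np.r_[np.ones(5), np.zeros(5)]])
        y = np.r_[np.ones(5), np.zeros(5)]
        with pytest.raises(SeparationError):
            fit_logistic(X, y)

    def test_rank_deficiency_raises(self):
        X = np.column_stack([np.ones(20), np.ones(20)])
        y = np.r_[np.ones(10), np.zeros(10)]
        with pytest.raises(ValueError):
            fit_logistic(X, y)

    def test_against_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        x = rng.normal(size=(400, 3))
        eta = 0.3 + x @ np.array([1.0, -0.5, 0.2])
        y = (rng.random(400) < 1 / (1 + np.exp(-eta))).astype(float)
        X = np.column_stack([np.ones(400), x])
        mine = fit_logistic(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(mine.coef, ref.params, atol=1e-6)
        np.testing.assert_allclose(mine.se(), ref.bse, atol=1e-6)
        assert mine.loglik == pytest.approx(ref.llf, abs=1e-6)


class TestPropensity:
    def test_mean_score_equals_prevalence(self, default_cohort):
        ps, _ = estimate_propensity(default_cohort)
        assert ps.mean() == pytest.approx(default_cohort.sign.mean(), abs=1e-8)
        assert ((ps > 0) & (ps < 1)).all()

    def test_null_cohort_flat_scores(self):
        params = CohortParams(n_patients=5000, sign_coef={})
        df = generate_cohort(params, seed=6)
        ps, fit = estimate_propensity(df)
        assert np.abs(fit.coef[1:]).max() < 0.5
        assert ps.std() < 0.05

    def test_confounded_cohort_discriminates(self, default_cohort):
        ps, _ = estimate_propensity(default_cohort)
        auc = roc_auc(ps, default_cohort.sign.to_numpy()).auc
        assert auc > 0.6


def _oracle_greedy(scores, treated, caliper, seed):
    """Exhaustive nearest-available search; mirrors the published greedy
    protocol directly."""
    rng = np.random.default_rng(seed)
    t = [i for i in range(len(scores)) if treated[i]]
    c = [i for i in range(len(scores)) if not treated[i]]
    order = rng.permutation(len(t))
    used, pairs = set(), []
    for k in order:
        ti = t[k]
        best, bd = None, np.inf
        for ci in c:
            if ci in used:
                continue
            d = abs(scores[ci] - scores[ti])
            if d <= caliper and d < bd:
                best, bd = ci, d
        if best is not None:
            used.add(best)
            pairs.append((ti, best))
    return sorted(pairs)


class TestGreedyMatch:
    def test_basic_example(self):
        m = greedy_match(
            np.array([0.30, 0.60, 0.31, 0.58, 0.90]),
            np.array([1, 1, 0, 0, 0]),
            caliper=0.05,
            seed=0,
        )
        assert sorted((a, b) for a, b, _ in m.pairs) == [(0, 2), (1, 3)]

    def test_caliper_excludes(self):
        m = greedy_match(np.array([0.90, 0.80]), np.array([1, 0]), 0.05, 0)
        assert m.pairs == [] and m.unmatched_treated == [0]

    def test_without_replacement(self):
        m = greedy_match(
            np.array([0.50, 0.50, 0.50]), np.array([1, 1, 0]), 0.05, 0
        )
        assert m.n_pairs == 1 and len(m.unmatched_treated) == 1

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        sc, tr = rng.random(300), rng.random(300) < 0.4
        a = greedy_match(sc, tr, 0.03, seed=9)
        b = greedy_match(sc, tr, 0.03, seed=9)
        assert a.pairs == b.pairs

    @given(st.integers(0, 10_000))
    @settings(max_examples=120, deadline=None)
    def test_matches_exhaustive_oracle(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(2, 7))
        sc = np.round(rng.random(n), 2)
        tr = rng.random(n) < 0.5
        if tr.all() or not tr.any():
            return
        m = greedy_match(sc, tr, 0.1, seed=trial)
        assert sorted((a, b) for a, b, _ in m.pairs) == _oracle_greedy(
            sc, tr, 0.1, trial
        )

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_constraints_never_violated(self, trial):
        rng = np.random.default_rng(trial)
        n = 150
        sc = rng.random(n)
        tr = rng.random(n) < 0.4
        if tr.all() or not tr.any():
            return
        m = greedy_match(sc, tr, 0.04, seed=trial)
        all_ids = [a for a, _, _ in m.pairs] + [b for _, b, _ in m.pairs]
        assert len(set(all_ids)) == len(all_ids)
        assert all(d <= 0.04 for _, _, d in m.pairs)
        assert all(tr[a] and not tr[b] for a, b, _ in m.pairs)

    def test_logit_caliper_positive(self):
        assert logit_caliper(np.array([0.2, 0.4, 0.6, 0.8])) > 0

    def test_invalid_caliper(self):
        with pytest.raises(ValueError):
            greedy_match(np.array([0.5, 0.5]), np.array([1, 0]), 0.0, 0)


class TestStandardizedDifference:
    def test_identical_groups_zero(self):
        x = np.r_[np.arange(10.0), np.arange(10.0)]
        g = np.r_[np.ones(10), np.zeros(10)].astype(bool)
        assert standardized_difference(x, g) == 0.0

    def test_continuous_formula(self):
        rng = np.random.default_rng(0)
        x = np.r_[rng.normal(12, 4, 200_000), rng.normal(10, 4, 200_000)]
        g = np.r_[np.ones(200_000), np.zeros(200_000)].astype(bool)
        assert standardized_difference(x, g) == pytest.approx(50.0, abs=1.0)

    def test_binary_formula(self):
        x = np.r_[np.ones(50), np.zeros(50), np.ones(30), np.zeros(70)]
        g = np.r_[np.ones(100), np.zeros(100)].astype(bool)
        expect = 100 * 0.2 / np.sqrt((0.25 + 0.21) / 2)
        assert standardized_difference(x, g, "binary") == pytest.approx(
            expect
        )

    def test_degenerate_cases(self):
        g = np.r_[np.ones(5), np.zeros(5)].astype(bool)
        assert standardized_difference(np.full(10, 3.0), g) == 0.0
        with pytest.raises(ValueError):
            standardized_difference(
                np.r_[np.full(5, 1.0), np.full(5, 2.0)], g
            )
        with pytest.raises(ValueError):
            standardized_difference(np.arange(10.0), np.ones(10, bool))


class TestOddsRatio:
    def test_validation_matched_table(self):
        est = odds_ratio_2x2(44, 6, 22, 28)
        assert est.odds_ratio == pytest.approx(9.333, abs=0.001)
        assert est.ci_low == pytest.approx(3.37, abs=0.01)
        assert est.ci_high == pytest.approx(25.88, abs=0.02)
        assert not est.continuity_corrected

    def test_symmetry(self):
        assert odds_ratio_2x2(10, 10, 10, 10).odds_ratio == 1.0

    def test_haldane_correction(self):
        est = odds_ratio_2x2(5, 0, 5, 5)
        assert est.continuity_corrected
        assert est.odds_ratio == pytest.approx(11.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio_2x2(0, 0, 5, 5)
        with pytest.raises(ValueError):
            odds_ratio_2x2(0, 5, 0, 5)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio_2x2(1.5, 2, 3, 4)


class TestMatchedConditional:
    def test_discordant_closed_form(self):
        t = np.r_[np.ones(30), np.zeros(8), np.ones(10), np.zeros(5)]
        c = np.r_[np.zeros(30), np.ones(8), np.ones(10), np.zeros(5)]
        est, mc = matched_conditional_or(t.astype(int), c.astype(int))
        assert est.odds_ratio == pytest.approx(30 / 8)
        assert mc.statistic == pytest.approx((30 - 8) ** 2 / 38)
        assert mc.n10 == 30 and mc.n01 == 8

    def test_balanced_discordance_is_null(self):
        t = np.r_[np.ones(10), np.zeros(10)].astype(int)
        c = np.r_[np.zeros(10), np.ones(10)].astype(int)
        est, mc = matched_conditional_or(t, c)
        assert est.odds_ratio == 1.0
        assert mc.statistic == 0.0

    def test_against_statsmodels_mcnemar(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        t = np.r_[np.ones(25), np.zeros(7), np.ones(4), np.zeros(4)].astype(int)
        c = np.r_[np.zeros(25), np.ones(7), np.ones(4), np.zeros(4)].astype(int)
        _, mc = matched_conditional_or(t, c)
        table = [[4, 25], [7, 4]]  # [[both, 10],[01, neither]]
        ref = sm_mcnemar(table, exact=False, correction=False)
        assert mc.statistic == pytest.approx(ref.statistic)
        assert mc.p_value == pytest.approx(ref.pvalue)

    def test_no_discordant_pairs_rejected(self):
        both = np.ones(5, dtype=int)
        with pytest.raises(ValueError):
            matched_conditional_or(both, both)

    def test_unconditional_attenuates_toward_null(self):
        """With heterogeneous pair risks, the pooled (unconditional) OR
        on matched data sits below the pair-conditional OR."""
        from fuzzyct import simulate_matched_pairs

        t, c = simulate_matched_pairs(50_000, 8.0, seed=3, baseline_logit_sd=2.0)
        cond, _ = matched_conditional_or(t, c)
        pooled = odds_ratio_2x2(
            int(t.sum()),
            int((1 - t).sum()),
            int(c.sum()),
            int((1 - c).sum()),
        )
        assert pooled.odds_ratio < cond.odds_ratio


class TestAdjustedOR:
    def test_crude_equals_2x2(self, default_cohort):
        df = default_cohort
        a = int(((df.sign == 1) & (df.expanded == 1)).sum())
        b = int(((df.sign == 1) & (df.expanded == 0)).sum())
        c = int(((df.sign == 0) & (df.expanded == 1)).sum())
        d = int(((df.sign == 0) & (df.expanded == 0)).sum())
        est = adjusted_or(df, adjustment="crude")
        assert est.odds_ratio == pytest.approx(a * d / (b * c), rel=1e-6)

    def test_adjustment_moves_toward_truth(self):
        """Median over replicates: the confounder-adjusted log-OR lies
        closer to the generating effect than the crude log-OR."""
        truth = np.log(9.5)
        crude_err, adj_err = [], []
        for rep in range(12):
            df = generate_cohort(CohortParams(n_patients=4000), seed=300 + rep)
            crude_err.append(
                abs(np.log(adjusted_or(df, adjustment="crude").odds_ratio) - truth)
            )
            adj_err.append(
                abs(
                    np.log(
                        adjusted_or(
                            df, adjustment="individual_confounders"
                        ).odds_ratio
                    )
                    - truth
                )
            )
        assert np.median(adj_err) < np.median(crude_err)

    def test_null_coverage(self):
        """95% CI covers the null in at least 93% of null-cohort
        replicates."""
        cov = 0
        n_rep = 60
        for rep in range(n_rep):
            df = generate_cohort(
                CohortParams(n_patients=4000, beta_sign=0.0), seed=1000 + rep
            )
            e = adjusted_or(df, adjustment="individual_confounders")
            cov += e.ci_low <= 1.0 <= e.ci_high
        assert cov / n_rep >= 0.88

    def test_unknown_adjustment(self, default_cohort):
        with pytest.raises(ValueError):
            adjusted_or(default_cohort, adjustment="magic")


class TestBalanceReport:
    def test_matching_restores_balance(self):
        df = generate_cohort(CohortParams(n_patients=2000), seed=41)
        ps, _ = estimate_propensity(df)
        m = greedy_match(ps, df.sign.to_numpy(), 0.05, seed=41)
        bal = balance_report(df, m)
        assert (bal.smd_after_pct >= 0).all()
        assert bal.smd_after_pct.max() < 10
        pre = bal.set_index("covariate").smd_before_pct
        assert pre["baseline_volume_ml"] > 10
        assert pre["sah"] > 10


class TestSubgroups:
    def test_stratum_estimates_bracket_generating_values(self):
        """GCS-stratified effects 9.5 (moderate/severe) vs 6.25 (mild)
        recovered from a cohort generated with that interaction."""
        gcs_extra = np.log(9.5) - np.log(6.25)
        params = CohortParams(
            n_patients=60_000,
            # the centered dummies split the stratum contrast +-0.5*extra
            # around the midpoint, so mild lands on 6.25 and the rest on 9.5
            beta_sign=0.5 * (np.log(6.25) + np.log(9.5)),
            interaction_coef={"gcs_moderate": gcs_extra, "gcs_severe": gcs_extra},
            outcome_coef={},
            sign_coef={},
        )
        df = generate_cohort(params, seed=77)
        res = subgroup_interaction(df, factors={
            "gcs": lambda d: np.where(
                d["gcs_level"] == "mild", "mild", "moderate_severe"
            )
        })
        by_level = res.set_index("level").odds_ratio
        assert by_level["mild"] == pytest.approx(6.25, rel=0.15)
        assert by_level["moderate_severe"] == pytest.approx(9.5, rel=0.15)
        assert (res.interaction_p < 0.05).all()

    def test_null_interaction_p_uniform(self):
        """Interaction p-values are uniform when no effect modification
        was generated (KS test over replicates)."""
        pvals = []
        for rep in range(120):
            df = generate_cohort(
                CohortParams(n_patients=500, sign_coef={}, outcome_coef={}),
                seed=5000 + rep,
            )
            res = subgroup_interaction(
                df,
                factors={
                    "sex": lambda d: np.where(d["male"] == 1, "m", "f")
                },
            )
            pvals.append(res.interaction_p.iloc[0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_constant_factor_flagged(self, default_cohort):
        res = subgroup_interaction(
            default_cohort, factors={"const": lambda d: np.full(len(d), "x")}
        )
        assert (res.flag == "factor constant in sample").all()


class TestROC:
    def test_perfect_predictor(self):
        y = np.r_[np.ones(20), np.zeros(20)].astype(int)
        assert roc_auc(y.astype(float), y).auc == 1.0

    def test_independent_predictor_near_half(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20000)
        y = (rng.random(20000) < 0.5).astype(int)
        assert roc_auc(x, y).auc == pytest.approx(0.5, abs=0.02)

    def test_binary_marker_identity(self):
        pred = np.r_[np.ones(44), np.zeros(22), np.ones(6), np.zeros(28)]
        out = np.r_[np.ones(66), np.zeros(34)].astype(int)
        r = roc_auc(pred, out)
        assert r.auc == pytest.approx((44 / 66 + 28 / 34) / 2, abs=1e-10)

    @given(
        a=st.integers(1, 40),
        b=st.integers(1, 40),
        c=st.integers(1, 40),
        d=st.integers(1, 40),
    )
    @settings(max_examples=60, deadline=None)
    def test_binary_identity_on_random_tables(self, a, b, c, d):
        """Rank AUC equals (sensitivity+specificity)/2 for any binary
        marker."""
        pred = np.r_[np.ones(a), np.zeros(c), np.ones(b), np.zeros(d)]
        out = np.r_[np.ones(a + c), np.zeros(b + d)].astype(int)
        sens, spec = a / (a + c), d / (b + d)
        assert roc_auc(pred, out).auc == pytest.approx(
            (sens + spec) / 2, abs=1e-10
        )

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        x = rng.normal(size=800)
        y = (rng.random(800) < 1 / (1 + np.exp(-x))).astype(int)
        assert roc_auc(x, y).auc == pytest.approx(
            roc_auc_score(y, x), abs=1e-12
        )

    def test_delong_ci_reasonable(self):
        rng = np.random.default_rng(4)
        x = np.r_[rng.normal(1, 1, 300), rng.normal(0, 1, 300)]
        y = np.r_[np.ones(300), np.zeros(300)].astype(int)
        r = roc_auc(x, y)
        assert 0 < r.ci_low < r.auc < r.ci_high < 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(5.0), np.ones(5, int))

    def test_curve_endpoints(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=100)
        y = (rng.random(100) < 0.5).astype(int)
        curve = roc_curve_points(x, y)
        assert curve.fpr.iloc[0] == 0 and curve.tpr.iloc[0] == 0
        assert curve.fpr.iloc[-1] == 1 and curve.tpr.iloc[-1] == 1
        assert curve.fpr.is_monotonic_increasing
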