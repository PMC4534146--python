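"""Odds ratios, complete-case filtering and the IRLS logistic fit."""

import numpy as np
import pandas as pd
import pytest

from dcis_cna import reference_data as ref
from dcis_cna.association import (
    ModelSpec,
    ZeroCellError,
    build_design,
    collapse_race,
    default_model_spec,
    filter_complete_cases,
    fit_logistic,
    odds_ratio_wald,
    univariate_or_table,
    wald_test_term,
)


class TestOddsRatioWald:
    @pytest.mark.parametrize(
        "cells, or_, lo, hi",
        [
            ((16, 15, 14, 29), 2.21, 0.85, 5.71),
            ((11, 8, 14, 29), 2.85, 0.94, 8.66),
            ((4, 4, 14, 29), 2.07, 0.45, 9.52),
            ((33, 12, 14, 29), 5.70, 2.27, 14.27),
            ((17, 5, 14, 29), 7.04, 2.16, 23.00),
        ],
    )
    def test_published_univariate_estimates(self, cells, or_, lo, hi):
        """Category counts from the published prevalence table reproduce the
        printed univariate ORs and CIs to 2 decimals."""
        r = odds_ratio_wald(*cells)
        assert round(r.odds_ratio, 2) == or_
        assert round(r.ci_low, 2) == lo
        assert round(r.ci_high, 2) == hi

    def test_balanced_table(self):
        r = odds_ratio_wald(1, 1, 1, 1)
        assert r.odds_ratio == pytest.approx(1.0)
        assert r.ci_low * r.ci_high == pytest.approx(1.0)  # log-symmetric

    def test_zero_cell_raises_unless_haldane(self):
        with pytest.raises(ZeroCellError):
            odds_ratio_wald(5, 0, 3, 4)
        r = odds_ratio_wald(5, 0, 3, 4, haldane=True)
        assert r.odds_ratio == pytest.approx((5.5 * 4.5) / (0.5 * 3.5))

    def test_matches_statsmodels(self):
        sm_ct = pytest.importorskip("statsmodels.stats.contingency_tables")
        t = sm_ct.Table2x2(np.array([[17, 5], [14, 29]]))
        r = odds_ratio_wald(17, 5, 14, 29)
        assert r.odds_ratio == pytest.approx(t.oddsratio)
        lo, hi = t.oddsratio_confint()
        assert r.ci_low == pytest.approx(lo)
        assert r.ci_high == pytest.approx(hi)

    def test_table_from_reference_counts(self):
        counts = {k: (v[2], v[1]) for k, v in ref.CATEGORY_COUNTS.items()}
        table = univariate_or_table(counts)
        for cat, (or_, lo, hi) in ref.UNIVARIATE_OR_PRINTED.items():
            assert round(table.loc[cat, "or"], 2) == or_
            assert round(table.loc[cat, "ci_low"], 2) == lo
            assert round(table.loc[cat, "ci_high"], 2) == hi


class TestCompleteCases:
    def _frame(self, n, rng=None, miss=0.0):
        rng = rng or np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "group": rng.choice(["dcis_only", "dcis_ibc"], n),
                "gain_category": rng.choice(["no_gains", "all_three"], n),
                "age_group": rng.choice(["<40", "50-64"], n),
                "race": rng.choice(["nh_white", "other"], n),
                "hr_status": rng.choice(["positive", "negative"], n),
                "grade": rng.choice(["1", "2"], n),
                "her2_gain": rng.choice(["no", "yes"], n),
            }
        )
        if miss > 0:
            for col in ("race", "hr_status", "grade"):
                df.loc[rng.random(n) < miss, col] = ""
        return df

    def test_no_missingness_is_identity(self):
        df = self._frame(50)
        out = filter_complete_cases(df, default_model_spec())
        assert len(out) == 50

    def test_single_missing_value_excluded(self):
        df = self._frame(10)
        df.loc[3, "grade"] = ""
        out = filter_complete_cases(df, default_model_spec())
        assert len(out) == 9
        assert "s3" not in set(out["sample_id"])

    def test_unable_to_determine_excluded(self):
        df = self._frame(10)
        df.loc[4, "gain_category"] = "unable_to_determine"
        out = filter_complete_cases(df, default_model_spec())
        assert "s4" not in set(out["sample_id"])

    def test_independent_missingness_retention_rate(self):
        """20 % missingness on 3 variables retains ~0.8^3 of samples."""
        rng = np.random.default_rng(7)
        df = self._frame(10_000, rng=rng, miss=0.2)
        out = filter_complete_cases(df, default_model_spec())
        p = 0.8**3
        se = np.sqrt(p * (1 - p) / 10_000)
        assert abs(len(out) / 10_000 - p) < 3 * se

    def test_collapse_race(self):
        s = pd.Series(["nh_white", "hispanic", "nh_black", "nh_api", ""])
        out = collapse_race(s)
        assert list(out) == ["nh_white", "other", "other", "nh_api", ""]


def expand_2x2(a, b, c, d):
    """Per-sample data for a saturated single-exposure logistic model."""
    x = np.r_[np.ones(a + b), np.zeros(c + d)]
    y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    X = np.column_stack([np.ones_like(x), x])
    return X, y


class TestFitLogistic:
    def test_saturated_model_equals_cross_product_or(self):
        X, y = expand_2x2(17, 5, 14, 29)
        fit = fit_logistic(X, y, names=["intercept", "exposed"])
        r = odds_ratio_wald(17, 5, 14, 29)
        assert np.exp(fit.params[1]) == pytest.approx(r.odds_ratio, rel=1e-8)
        assert fit.bse[1] == pytest.approx(r.se_log_or, rel=1e-6)
        ors = fit.odds_ratios()
        assert ors.loc["exposed", "ci_low"] == pytest.approx(r.ci_low, rel=1e-6)
        assert ors.loc["exposed", "ci_high"] == pytest.approx(r.ci_high, rel=1e-6)

    def test_loglikelihood_never_decreases(self, rng):
        for _ in range(20):
            n = 200
            X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
            eta = X @ np.r_[0.3, 1.0, -0.5, 0.0]
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            fit = fit_logistic(X, y)
            assert np.all(np.diff(fit.loglik_path) >= -1e-8)
            assert fit.converged

    def test_matches_statsmodels_glm(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        n = 300
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2)), rng.random(n) < 0.3])
        eta = X @ np.r_[-0.2, 0.8, -0.4, 0.9]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = fit_logistic(X, y)
        ref_fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert fit.params == pytest.approx(ref_fit.params, abs=1e-6)
        assert fit.bse == pytest.approx(ref_fit.bse, rel=1e-5)
        assert fit.log_likelihood == pytest.approx(ref_fit.llf, rel=1e-8)

    def test_permutation_invariance(self, rng):
        n = 150
        X = np.column_stack([np.ones(n), rng.random(n) < 0.4])
        y = (rng.random(n) < 0.5).astype(float)
        fit = fit_logistic(X, y)
        perm = rng.permutation(n)
        fit2 = fit_logistic(X[perm], y[perm])
        assert fit.params == pytest.approx(fit2.params, abs=1e-10)

    def test_constant_outcome_raises(self):
        X = np.column_stack([np.ones(20), np.arange(20.0)])
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(X, np.ones(20))

    def test_separation_flagged(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = x.copy()  # perfectly separated
        X = np.column_stack([np.ones(40), x])
        fit = fit_logistic(X, y)
        assert fit.converged is False

    def test_rank_deficient_design_names_columns(self):
        n = 50
        x = np.random.default_rng(0).normal(size=n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        y = (x > 0).astype(float)
        with pytest.raises(np.linalg.LinAlgError, match="x2"):
            fit_logistic(X, y)


class TestWaldTerm:
    def test_single_df_equals_normal_test(self):
        X, y = expand_2x2(17, 5, 14, 29)
        fit = fit_logistic(
            X, y, names=["intercept", "exposed"], term_cols={"exposed": [1]}
        )
        p_term = wald_test_term(fit, "exposed")
        p_coef = fit.odds_ratios().loc["exposed", "p_wald"]
        assert p_term == pytest.approx(p_coef, rel=1e-10)

    def test_type_i_error_calibration(self, rng):
        """Under the null the 1-df Wald test rejects at ~5 %."""
        rejections = 0
        reps = 800
        n = 120
        for _ in range(reps):
            x = (rng.random(n) < 0.5).astype(float)
            y = (rng.random(n) < 0.5).astype(float)
            X = np.column_stack([np.ones(n), x])
            fit = fit_logistic(X, y, term_cols={"x": [1]})
            if wald_test_term(fit, "x") < 0.05:
                rejections += 1
        rate = rejections / reps
        half = 2.576 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < half + 0.005

    def test_multi_df_term_via_design(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {
                "group": rng.choice(["dcis_only", "dcis_ibc"], 400),
                "cat": rng.choice(["a", "b", "c"], 400),
            }
        )
        spec = ModelSpec(terms=(("cat", ("a", ("b", "c"))),))
        X, y, names, term_cols = build_design(df, spec)
        fit = fit_logistic(X, y, names=names, term_cols=term_cols)
        p = wald_test_term(fit, "cat")
        assert 0.0 <= p <= 1.0

    def test_unknown_term_raises(self):
        X, y = expand_2x2(5, 5, 5, 5)
        fit = fit_logistic(X, y)
        with pytest.raises(KeyError):
            wald_test_term(fit, "nope")
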