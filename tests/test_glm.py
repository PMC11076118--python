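"""Tests for GLM fitting, drop1 LLRTs, model reduction and summaries.

The frozen expectations in TestAgainstRGlmOracle were computed with R's
glm/summary/drop1 (quasibinomial and gaussian families) on the same
12-row dataset.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from gfptract.glm import (
    AliasingError,
    GLMError,
    GLMSpec,
    MarginalityError,
    analyze_occupancy,
    analyze_paternity,
    describe_by,
    drop1_llrt,
    fit_glm,
    pearson_dispersion,
    posthoc_contrasts,
    pseudo_r2,
    reduce_model,
    spearman_correlation,
)
from gfptract.simulate import DesignSpec, EffectSpec, simulate_experiment, \
    simulate_paternity

from _oracles import spearman_bruteforce


def two_group(ya, yb, name="thermal", levels=("control", "heat")):
    return pd.DataFrame({
        name: [levels[0]] * len(ya) + [levels[1]] * len(yb),
        "y": list(ya) + list(yb),
    })


@pytest.fixture(scope="module")
def oracle_df():
    return pd.DataFrame({
        "thermal": ["control"] * 6 + ["heat"] * 6,
        "time": (["30min"] * 3 + ["24h"] * 3) * 2,
        "cover": [42, 38, 51, 12, 15, 9, 30, 27, 33, 7, 11, 5],
        "intens": [3120, 2950, 3300, 1010, 1180, 920,
                   2410, 2260, 2550, 760, 880, 690],
    })


# ------------------------------------------------------------------ fitting

class TestFitGLM:
    @pytest.mark.parametrize("seed", range(5))
    def test_gaussian_equals_closed_form_ols(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "thermal": rng.choice(["control", "heat"], 40),
            "time": rng.choice(["30min", "24h"], 40),
            "y": rng.normal(100, 20, 40),
        })
        fit = fit_glm(df, GLMSpec("gaussian", "y", ("thermal", "time")))
        X = np.column_stack([
            np.ones(40),
            (df.thermal == "heat").to_numpy(float),
            (df.time == "24h").to_numpy(float),
        ])
        beta = np.linalg.lstsq(X, df.y.to_numpy(), rcond=None)[0]
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-8)

    def test_gaussian_one_factor_recovers_group_means(self):
        fit = fit_glm(two_group([1, 2, 3, 4, 5], [7, 8, 9, 10, 11]),
                      GLMSpec("gaussian", "y", ("thermal",)))
        assert fit.params["Intercept"] == pytest.approx(3.0)
        assert fit.params["thermal[heat]"] == pytest.approx(6.0)

    def test_two_cell_quasibinomial_slope_closed_form(self):
        df = pd.DataFrame({"g": ["control", "heat"],
                           "s": [9.0, 1.0], "f": [1.0, 9.0]})
        fit = fit_glm(df, GLMSpec("quasibinomial", ("s", "f"), ("g",)))
        assert fit.params["g[heat]"] == pytest.approx(-2 * math.log(9), abs=1e-6)
        assert fit.params["Intercept"] == pytest.approx(math.log(9), abs=1e-6)

    def test_constant_response_zero_slopes(self):
        df = two_group([5.0] * 6, [5.0] * 6)
        fit = fit_glm(df, GLMSpec("gaussian", "y", ("thermal",)))
        assert fit.params["thermal[heat]"] == pytest.approx(0.0, abs=1e-10)

    def test_aliased_terms_error(self):
        df = two_group([1, 2, 3], [4, 5, 6])
        df["copy"] = df["thermal"]
        with pytest.raises(AliasingError):
            fit_glm(df, GLMSpec("gaussian", "y", ("thermal", "copy")))

    def test_coefficients_invariant_to_dispersion(self):
        """Quasi-binomial dispersion scales SEs only, never coefficients."""
        rec, _ = simulate_experiment(DesignSpec(), EffectSpec(), seed=0)
        sub = rec[rec.site == "total_tract"]
        spec = GLMSpec("quasibinomial", ("cover_percent", 100), ("thermal",))
        fit = fit_glm(sub, spec)
        binom_se = pd.Series(np.asarray(fit.result.bse), index=fit.exog_names)
        phi = pearson_dispersion(fit)
        assert phi > 1.5  # the generator really is overdispersed
        assert np.allclose(fit.bse, binom_se * np.sqrt(phi))
        assert np.allclose(
            fit.params,
            pd.Series(np.asarray(fit.result.params), index=fit.exog_names))


class TestAgainstRGlmOracle:
    """Frozen R glm/drop1 results on the 12-row oracle dataset."""

    def test_quasibinomial_matches_r(self, oracle_df):
        fit = fit_glm(oracle_df,
                      GLMSpec("quasibinomial", ("cover", 100),
                              ("thermal", "time")))
        assert np.allclose(
            fit.params, [-0.2667554768, -0.5664729318, -1.6979113827],
            atol=1e-6)
        assert np.allclose(
            fit.bse, [0.1087199534, 0.1460892995, 0.1618749960], atol=1e-6)
        assert pearson_dispersion(fit) == pytest.approx(0.9946628950, abs=1e-6)
        assert fit.deviance == pytest.approx(8.8632600995, abs=1e-6)
        assert fit.null_deviance == pytest.approx(152.5653749608, abs=1e-6)
        # scaled-deviance chi2 = (deviance drop) / phi
        tt = drop1_llrt(fit, "thermal")
        assert tt.statistic == pytest.approx(15.2091765553 / 0.9946628950,
                                             rel=1e-5)

    def test_gaussian_matches_r(self, oracle_df):
        fit = fit_glm(oracle_df,
                      GLMSpec("gaussian", "intens", ("thermal", "time")))
        assert np.allclose(
            fit.params, [3009.1666666667, -488.3333333333, -1858.3333333333],
            atol=1e-5)
        assert np.allclose(
            fit.bse, [93.2551756085, 107.6818014818, 107.6818014818],
            atol=1e-5)
        t_thermal = drop1_llrt(fit, "thermal")
        t_time = drop1_llrt(fit, "time")
        assert t_thermal.statistic == pytest.approx(20.5659187096, rel=1e-6)
        assert t_time.statistic == pytest.approx(297.8260001597, rel=1e-6)
        assert t_thermal.p_value == pytest.approx(0.00141608501382, rel=1e-6)


# ---------------------------------------------------------------- dispersion

class TestDispersion:
    def test_gaussian_phi_is_residual_mean_square(self):
        df = two_group([1.0, 2, 3, 4], [4.0, 5, 7, 8])
        fit = fit_glm(df, GLMSpec("gaussian", "y", ("thermal",)))
        resid = df.y - df.groupby("thermal").y.transform("mean")
        assert pearson_dispersion(fit) == pytest.approx(
            float((resid**2).sum()) / 6)

    def test_perfect_fit_gives_zero(self):
        df = two_group([4.0, 4, 4], [9.0, 9, 9])
        fit = fit_glm(df, GLMSpec("gaussian", "y", ("thermal",)))
        assert pearson_dispersion(fit) == pytest.approx(0.0, abs=1e-12)

    def test_no_residual_df_errors(self):
        df = two_group([1.0], [2.0])
        fit = fit_glm(df, GLMSpec("gaussian", "y", ("thermal",)))
        with pytest.raises(GLMError):
            pearson_dispersion(fit)

    def test_recovers_beta_binomial_inflation(self):
        """Beta-binomial with ICC rho inflates phi to ~ 1 + 99 rho."""
        rho = 0.05
        eff = EffectSpec.null(cover_overdispersion=rho)
        phis = []
        for seed in range(10):
            rec, _ = simulate_experiment(DesignSpec(cell_sizes=(25,) * 8),
                                         eff, seed=200 + seed)
            sub = rec[rec.site == "total_tract"]  # 200 observations
            fit = fit_glm(sub, GLMSpec("quasibinomial",
                                       ("cover_percent", 100), ("thermal",)))
            phis.append(pearson_dispersion(fit))
        target = 1 + 99 * rho
        assert abs(np.mean(phis) / target - 1) < 0.15


# ------------------------------------------------------------------- drop1

class TestDrop1:
    def test_zero_effect_noise_free_gives_p_one(self):
        df = two_group([5.0, 5, 5, 5], [5.0, 5, 5, 5])
        fit = fit_glm(df, GLMSpec("gaussian", "y", ("thermal",)))
        tt = drop1_llrt(fit, "thermal")
        assert tt.statistic == 0.0 and tt.p_value == 1.0

    def test_f_equals_classical_anova(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "g": np.repeat(["a", "b", "c"], 8),
            "y": rng.normal(0, 1, 24) + np.repeat([0.0, 0.4, 1.0], 8),
        })
        fit = fit_glm(df, GLMSpec("gaussian", "y", ("g",)))
        tt = drop1_llrt(fit, "g")
        F, p = sps.f_oneway(*[grp.y.to_numpy() for _, grp in df.groupby("g")])
        assert tt.statistic == pytest.approx(F, rel=1e-10)
        assert tt.p_value == pytest.approx(p, rel=1e-10)
        assert tt.df == 2 and tt.statistic_kind == "F"

    def test_marginality_protects_main_effects(self):
        rec, _ = simulate_experiment(DesignSpec(), EffectSpec(), seed=0)
        sub = rec[rec.site == "total_tract"]
        fit = fit_glm(sub, GLMSpec(
            "quasibinomial", ("cover_percent", 100),
            ("thermal", "time", "thermal:time")))
        with pytest.raises(MarginalityError):
            drop1_llrt(fit, "thermal")

    def test_unknown_or_degenerate_term_errors(self):
        df = two_group([1.0, 2, 3], [4.0, 5, 6])
        df["single"] = "only_level"
        fit = fit_glm(df, GLMSpec("gaussian", "y", ("thermal", "single")))
        with pytest.raises(GLMError):
            drop1_llrt(fit, "absent")
        with pytest.raises(GLMError):
            drop1_llrt(fit, "single")  # contributes no columns -> ddf 0


# ---------------------------------------------------------- model reduction

class TestReduceModel:
    TERMS = ("thermal", "female_status", "time",
             "thermal:female_status", "thermal:time", "female_status:time")

    def test_no_interactions_returned_unchanged(self):
        df = two_group([1.0, 2, 3], [4.0, 5, 6])
        fit = fit_glm(df, GLMSpec("gaussian", "y", ("thermal",)))
        assert reduce_model(fit) is fit

    def test_null_interactions_usually_pruned(self):
        kept = 0
        for seed in range(12):
            rec, _ = simulate_experiment(DesignSpec(), EffectSpec.null(),
                                         seed=100 + seed)
            sub = rec[rec.site == "total_tract"]
            fit = fit_glm(sub, GLMSpec("quasibinomial",
                                       ("cover_percent", 100), self.TERMS))
            final = reduce_model(fit)
            kept += any(":" in t for t in final.spec.terms)
        assert kept <= 2  # ~ alpha-level false retention

    def test_strong_interaction_retained(self):
        rng = np.random.default_rng(5)
        cells = {("control", "30min"): 0.40, ("heat", "30min"): 0.25,
                 ("control", "24h"): 0.25, ("heat", "24h"): 0.45}
        rows = []
        for (th, tm), p in cells.items():
            for _ in range(40):
                rows.append({"thermal": th, "time": tm,
                             "cover_percent": rng.binomial(100, p)})
        df = pd.DataFrame(rows)
        fit = fit_glm(df, GLMSpec("quasibinomial", ("cover_percent", 100),
                                  ("thermal", "time", "thermal:time")))
        final = reduce_model(fit)
        assert "thermal:time" in final.spec.terms


# ------------------------------------------------------- post-hoc contrasts

class TestPosthoc:
    def test_zero_effect_gives_zero_change_p_one(self):
        df = two_group([4.0, 6, 5], [4.0, 6, 5])
        fit = fit_glm(df, GLMSpec("gaussian", "y", ("thermal",)))
        (c,) = posthoc_contrasts(fit)
        assert c.percent_change == pytest.approx(0.0, abs=1e-9)
        assert c.p_value == pytest.approx(1.0)

    def test_t_squared_equals_drop1_f(self):
        rng = np.random.default_rng(8)
        df = two_group(rng.normal(10, 2, 12), rng.normal(8, 2, 12))
        fit = fit_glm(df, GLMSpec("gaussian", "y", ("thermal",)))
        (c,) = posthoc_contrasts(fit)
        tt = drop1_llrt(fit, "thermal")
        assert c.statistic**2 == pytest.approx(tt.statistic, rel=1e-8)
        assert c.statistic_kind == "t"

    def test_cover_effect_percent_change_recovery(self):
        effects = EffectSpec.null()
        effects.cover_effects["thermal"] = {
            "total_tract": 0.68, "spermatheca": 0.68}
        changes = []
        for seed in range(30):
            rec, _ = simulate_experiment(DesignSpec(), effects, seed=500 + seed)
            sub = rec[rec.site == "total_tract"]
            fit = fit_glm(sub, GLMSpec("quasibinomial", ("cover_percent", 100),
                                       ("thermal", "female_status", "time")))
            c = next(c for c in posthoc_contrasts(fit) if c.factor == "thermal")
            changes.append(c.percent_change)
        assert abs(np.mean(changes) - (-32.0)) < 3.0

    def test_group_means_reported(self):
        df = two_group([1.0, 2, 3], [7.0, 8, 9])
        fit = fit_glm(df, GLMSpec("gaussian", "y", ("thermal",)))
        (c,) = posthoc_contrasts(fit)
        mean, se, n = c.group_means["heat"]
        assert (mean, n) == (8.0, 3)
        assert se == pytest.approx(1.0 / math.sqrt(3))


# --------------------------------------------------------------- pseudo-R2

class TestPseudoR2:
    def test_intercept_only_zero(self):
        df = two_group([1.0, 2, 3], [4.0, 5, 6])
        fit = fit_glm(df, GLMSpec("gaussian", "y", ()))
        assert pseudo_r2(fit) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_fit_one(self):
        df = two_group([4.0, 4, 4], [9.0, 9, 9])
        fit = fit_glm(df, GLMSpec("gaussian", "y", ("thermal",)))
        assert pseudo_r2(fit) == pytest.approx(1.0)

    def test_monotone_in_nested_terms(self):
        rec, _ = simulate_experiment(DesignSpec(), EffectSpec(), seed=4)
        sub = rec[rec.site == "total_tract"]
        values = []
        for terms in [(), ("thermal",), ("thermal", "time"),
                      ("thermal", "time", "female_status")]:
            fit = fit_glm(sub, GLMSpec("quasibinomial",
                                       ("cover_percent", 100), terms))
            values.append(pseudo_r2(fit))
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_constant_response_undefined(self):
        df = two_group([5.0, 5, 5], [5.0, 5, 5])
        fit = fit_glm(df, GLMSpec("gaussian", "y", ("thermal",)))
        with pytest.raises(GLMError):
            pseudo_r2(fit)


# ------------------------------------------------------ spearman / describe

class TestSpearman:
    def test_monotone_pairs(self):
        x = [1.0, 2, 3, 4, 5]
        rho, s = spearman_correlation(x, [10.0, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)
        assert s == pytest.approx(0.0)
        rho_rev, _ = spearman_correlation(x, [50.0, 40, 30, 20, 10])
        assert rho_rev == pytest.approx(-1.0)

    def test_zero_variance_errors(self):
        with pytest.raises(GLMError):
            spearman_correlation([1.0, 1, 1], [1.0, 2, 3])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 4), min_size=4, max_size=12),
           st.lists(st.integers(0, 4), min_size=4, max_size=12))
    def test_ties_match_bruteforce_ranks(self, xs, ys):
        n = min(len(xs), len(ys))
        x, y = np.array(xs[:n], float), np.array(ys[:n], float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        rho, s = spearman_correlation(x, y)
        rho_bf, s_bf = spearman_bruteforce(x, y)
        assert rho == pytest.approx(rho_bf, abs=1e-12)
        assert s == pytest.approx(s_bf)


class TestDescribeBy:
    def test_closed_form_two_values(self):
        df = pd.DataFrame({"g": ["a", "a", "b"], "v": [2.0, 6.0, 5.0]})
        out = describe_by(df, "g", "v")
        a = out[out.g == "a"].iloc[0]
        assert a["mean"] == 4.0 and a.se == pytest.approx(2.0)  # |a-b|/2
        b = out[out.g == "b"].iloc[0]
        assert b.se == 0.0 and b.n == 1  # n = 1 is the flag

    def test_matches_oracle_formulas(self, rng):
        df = pd.DataFrame({"g": rng.choice(["a", "b"], 50),
                           "v": rng.normal(0, 1, 50)})
        out = describe_by(df, "g", "v")
        for _, row in out.iterrows():
            vals = df[df.g == row.g].v
            assert row["mean"] == pytest.approx(vals.mean())
            assert row.se == pytest.approx(vals.std(ddof=1) / np.sqrt(len(vals)))


# ------------------------------------------------------- experiment drivers

class TestAnalyzeOccupancy:
    def test_table_structure_and_families(self):
        rec, _ = simulate_experiment(DesignSpec(), EffectSpec.null(), seed=42)
        res = analyze_occupancy(rec)
        table = res.to_table()
        assert len(res.reports) == 4  # 2 sites x 2 responses
        for (site, response), rep in res.reports.items():
            main_rows = [t for t in rep.term_tests if ":" not in t.term]
            assert {t.term for t in main_rows} == {
                "thermal", "female_status", "time"}
            expected_kind = "chi_squared" if response == "cover" else "F"
            assert all(t.statistic_kind == expected_kind for t in main_rows)
        assert (table.fixed_factor == "residual").sum() == 4
        assert table.model.isin(["GLM Q-bin (logit)", "GLM Gaus (ID)"]).all()

    def test_detects_injected_site_specific_pattern(self):
        """Thermal hits both sites, time only the tract, prior mating
        only the spermatheca — the analysis should find that pattern."""
        rec, _ = simulate_experiment(DesignSpec(), EffectSpec(), seed=7)
        res = analyze_occupancy(rec)
        p = {key: {t.term: t.p_value for t in rep.term_tests}
             for key, rep in res.reports.items()}
        for site in ("total_tract", "spermatheca"):
            assert p[(site, "cover")]["thermal"] < 0.05
        assert p[("total_tract", "cover")]["time"] < 0.001
        assert p[("total_tract", "cover")]["female_status"] > 0.05
        assert p[("spermatheca", "cover")]["female_status"] < 0.001
        assert p[("spermatheca", "cover")]["time"] > 0.05

    def test_errors_recorded_per_response(self):
        rec, _ = simulate_experiment(DesignSpec(), EffectSpec(), seed=1)
        rec = rec.copy()
        rec.loc[rec.site == "spermatheca", "cover_percent"] = 105.0  # invalid
        res = analyze_occupancy(rec)
        assert ("spermatheca", "cover") in res.errors
        assert ("total_tract", "cover") in res.reports

    def test_missing_columns_error(self):
        with pytest.raises(GLMError):
            analyze_occupancy(pd.DataFrame({"site": []}))


class TestAnalyzePaternity:
    def test_identical_arms_not_significant(self):
        counts = [10, 14, 18, 22, 12, 16, 20, 24, 11, 19]
        df = pd.DataFrame({
            "male_treatment": ["control"] * 10 + ["heat"] * 10,
            "n_filiform": counts * 2,
            "n_clubbed": [30 - c for c in counts] * 2,
        })
        rep = analyze_paternity(df)
        (tt,) = rep.term_tests
        assert tt.statistic == pytest.approx(0.0, abs=1e-8)
        assert tt.p_value == pytest.approx(1.0)

    def test_residual_df_is_n_minus_two(self):
        pat = simulate_paternity(19, 18, EffectSpec(), seed=0)
        rep = analyze_paternity(pat)
        assert rep.df_resid == len(pat) - 2

    def test_shift_recovery_quick(self):
        eff = EffectSpec.null(paternity_effect=-1.5)
        est = [analyze_paternity(simulate_paternity(19, 18, eff, seed=s))
               .coefficients["male_treatment[heat]"] for s in range(40)]
        assert abs(np.mean(est) + 1.5) < 0.2

    def test_all_empty_broods_error(self):
        df = pd.DataFrame({"male_treatment": ["control", "heat"],
                           "n_filiform": [0, 0], "n_clubbed": [0, 0]})
        with pytest.raises(GLMError):
            analyze_paternity(df)
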