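"""Validation statistics: group tests, incremental R^2, AUC/DeLong,
likelihood-ratio, residualization, partial correlation, moderation,
mediation, outlier masking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from methylcog import (auc, delong_test, discrimination_suite, group_tests,
                       incremental_r2, mediation_bootstrap, moderation_fit,
                       nested_lr_test, odds_reduction_percent, outlier_mask,
                       partial_correlation, residualize, welch_anova)
from methylcog.cohort import simulate_mediation_triple
from methylcog.stats import fit_logistic

from ._oracles import auc_brute_force


class TestGroupTests:
    def test_identical_groups_null(self):
        s = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        g = pd.Series([0, 0, 0, 1, 1, 1])
        res = group_tests(s, g)
        assert res["test"] == "welch_t"
        assert res["t"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_hand_welch_t(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        g = pd.Series(["a", "a", "a", "b", "b", "b"])
        res = group_tests(s, g)
        assert res["t"] == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), abs=1e-9)
        assert res["df"] == pytest.approx(4.0, abs=1e-9)

    def test_welch_t_matches_scipy_on_unequal_variances(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 3, 50)
        s = pd.Series(np.r_[a, b])
        g = pd.Series([0] * 30 + [1] * 50)
        res = group_tests(s, g)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert res["p"] == pytest.approx(ref.pvalue, rel=1e-10)

    def test_welch_anova_matches_pingouin(self, rng):
        """Cross-check the hand-rolled Welch ANOVA against pingouin."""
        pingouin = pytest.importorskip("pingouin")
        vals = np.r_[rng.normal(0, 1, 20), rng.normal(0.4, 2, 30),
                     rng.normal(-0.2, 0.5, 25)]
        grp = np.r_[np.zeros(20), np.ones(30), np.full(25, 2)]
        F, df1, df2, p = welch_anova([vals[grp == k] for k in range(3)])
        ref = pingouin.welch_anova(
            pd.DataFrame({"y": vals, "g": grp}), dv="y", between="g")
        assert F == pytest.approx(ref["F"].iloc[0], rel=1e-9)
        assert df2 == pytest.approx(ref["ddof2"].iloc[0], rel=1e-9)
        assert p == pytest.approx(ref["p_unc"].iloc[0], rel=1e-9)

    def test_continuous_grouping_uses_pearson(self, rng):
        s = pd.Series(rng.normal(size=100))
        res = group_tests(s, pd.Series(rng.normal(size=100)))
        assert res["test"] == "pearson"

    def test_small_group_rejected(self):
        s = pd.Series([1.0, 2.0, 3.0])
        g = pd.Series(["a", "a", "b"])
        with pytest.raises(ValueError, match="'b'"):
            group_tests(s, g)


class TestIncrementalR2:
    def test_orthogonal_added_predictor_delta_r2_is_r_squared(self, rng):
        n = 100_000
        base = pd.DataFrame({"b1": rng.normal(size=n)})
        added = pd.Series(rng.normal(size=n), name="x")
        r_target = 0.3
        y = pd.Series(r_target * added + np.sqrt(1 - r_target ** 2)
                      * rng.normal(size=n))
        fit = incremental_r2(y, base, added)
        assert fit.delta_r2 == pytest.approx(r_target ** 2, abs=0.01)

    def test_sr2_equals_delta_r2_for_single_predictor(self, rng):
        n = 200
        base = pd.DataFrame({"b1": rng.normal(size=n), "b2": rng.normal(size=n)})
        added = pd.Series(rng.normal(size=n), name="x")
        y = pd.Series(base["b1"] + 0.5 * added + rng.normal(size=n))
        fit = incremental_r2(y, base, added)
        assert fit.sr2["x"] == pytest.approx(fit.delta_r2, abs=1e-12)
        assert fit.delta_r2 >= 0

    def test_duplicated_column_raises(self, rng):
        n = 50
        base = pd.DataFrame({"b1": rng.normal(size=n)})
        added = pd.Series(base["b1"].to_numpy(), name="x")
        with pytest.raises(ValueError, match="collinear"):
            incremental_r2(pd.Series(rng.normal(size=n)), base, added)

    def test_null_added_predictor_mean_delta_r2(self):
        """Under the null, E[delta R^2] ~ 1/(n-k) for one noise predictor."""
        rng = np.random.default_rng(77)
        n, reps = 60, 2000
        deltas = np.empty(reps)
        for i in range(reps):
            y = pd.Series(rng.normal(size=n))
            base = pd.DataFrame({"b": rng.normal(size=n)})
            added = pd.Series(rng.normal(size=n), name="x")
            deltas[i] = incremental_r2(y, base, added).delta_r2
        assert deltas.mean() == pytest.approx(1.0 / (n - 2), rel=0.15)


class TestAuc:
    def test_worked_example(self):
        assert auc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8]) == 0.75

    def test_perfect_separation(self):
        assert auc([0, 0, 1, 1], [0.0, 0.1, 0.9, 1.0]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([0, 1, 0, 1], [0.3, 0.3, 0.3, 0.3]) == 0.5

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(5):
            n = int(rng.integers(20, 200))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            s = np.round(rng.normal(size=n), 1)  # induce ties
            assert auc(y, s) == pytest.approx(auc_brute_force(y, s), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1, 1, 1], [0.1, 0.2, 0.3])


class TestDelong:
    def test_identical_scores_p_one(self, rng):
        y = rng.integers(0, 2, size=80)
        y[:5], y[-5:] = 0, 1
        s = rng.normal(size=80)
        res = delong_test(y, s, s.copy())
        assert res["delta_auc"] == 0.0 and res["p"] == 1.0

    def test_monotone_transform_invariance(self, rng):
        y = np.r_[np.zeros(40, int), np.ones(40, int)]
        s = rng.normal(size=80)
        res = delong_test(y, s, np.exp(2 * s) + 3)
        assert res["delta_auc"] == pytest.approx(0.0, abs=1e-12)

    def test_variance_matches_paired_bootstrap(self):
        """DeLong variance of delta AUC against a 2000-rep paired bootstrap."""
        rng = np.random.default_rng(5)
        n = 300
        y = np.r_[np.zeros(150, int), np.ones(150, int)]
        latent = rng.normal(size=n) + 0.8 * y
        a = latent + rng.normal(scale=0.7, size=n)
        b = latent + rng.normal(scale=0.9, size=n)
        res = delong_test(y, a, b)
        var_delong = (res["delta_auc"] / res["z"]) ** 2
        boots = np.empty(2000)
        for i in range(2000):
            idx = rng.integers(0, n, n)
            while len(np.unique(y[idx])) < 2:
                idx = rng.integers(0, n, n)
            boots[i] = auc(y[idx], a[idx]) - auc(y[idx], b[idx])
        assert var_delong == pytest.approx(boots.var(ddof=1), rel=0.15)

    def test_detects_genuinely_better_score(self, rng):
        y = np.r_[np.zeros(200, int), np.ones(200, int)]
        good = y + rng.normal(scale=0.8, size=400)
        noise = rng.normal(size=400)
        res = delong_test(y, good, noise)
        assert res["delta_auc"] > 0.1 and res["p"] < 0.001


class TestNestedLr:
    def test_identical_models_chi2_zero(self, rng):
        y = pd.Series(rng.integers(0, 2, size=100).astype(float))
        X = pd.DataFrame({"x": rng.normal(size=100)})
        fit = fit_logistic(y, X)
        res = nested_lr_test(fit, fit)
        assert res["chi2"] == 0.0 and res["p"] == 1.0

    def test_true_predictor_detected(self):
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(60):
            x = rng.normal(size=300)
            p = 1 / (1 + np.exp(-(0.8 * x)))
            y = pd.Series((rng.random(300) < p).astype(float))
            f0 = fit_logistic(y, pd.DataFrame({"z": rng.normal(size=300)}))
            f1 = fit_logistic(y, pd.DataFrame({"z": f0.model.exog[:, 1],
                                               "x": x}))
            if nested_lr_test(f0, f1)["p"] < 0.05:
                hits += 1
        assert hits >= 57  # >= 95% power at this effect size

    def test_null_chi2_distribution(self):
        """Added noise predictor: chi2 follows chi-square with 1 df."""
        rng = np.random.default_rng(9)
        reps = 800
        stat = np.empty(reps)
        for i in range(reps):
            y = pd.Series(rng.integers(0, 2, size=120).astype(float))
            x0 = pd.DataFrame({"a": rng.normal(size=120)})
            f0 = fit_logistic(y, x0)
            f1 = fit_logistic(y, x0.assign(b=rng.normal(size=120)))
            stat[i] = nested_lr_test(f0, f1)["chi2"]
        ks = sps.kstest(stat, sps.chi2(1).cdf)
        assert ks.pvalue > 0.01


class TestDiscriminationSuite:
    def test_or_reported_as_percent_reduction(self):
        assert odds_reduction_percent(0.74) == pytest.approx(26.0)
        assert odds_reduction_percent(0.67) == pytest.approx(33.0)

    def test_protective_score_lowers_odds_and_lifts_auc(self, rng):
        n = 900
        g = rng.normal(size=n)
        age = rng.uniform(65, 90, n)
        p = 1 / (1 + np.exp(1.2 + 1.2 * g))
        pheno = pd.DataFrame({
            "mci": (rng.random(n) < p).astype(int),
            "age": age, "sex": rng.choice(["F", "M"], n),
            "education": rng.normal(12, 3, n),
        })
        score = pd.Series(g + 0.6 * rng.normal(size=n), index=pheno.index)
        fit = discrimination_suite(pheno, score)
        assert fit.models["base+score"]["score_or_per_sd"] < 0.8
        assert fit.models["base+score"]["auc"] > fit.models["base"]["auc"]
        cmp = fit.comparisons[0]
        assert cmp["lr_p"] < 0.001 and cmp["chi2"] > 0

    def test_screener_ladder_present(self, rng):
        n = 400
        pheno = pd.DataFrame({
            "mci": rng.integers(0, 2, n), "age": rng.uniform(60, 90, n),
            "sex": rng.choice(["F", "M"], n),
            "education": rng.normal(12, 2, n),
            "screener": rng.normal(27, 2, n),
        })
        score = pd.Series(rng.normal(size=n), index=pheno.index)
        fit = discrimination_suite(pheno, score, screener_col="screener")
        assert set(fit.models) == {"base", "base+score", "base+screener",
                                   "base+screener+score"}
        assert len(fit.comparisons) == 3


class TestResidualize:
    def test_uncorrelated_score_gives_centered_score(self, rng):
        s = pd.Series(rng.normal(size=500))
        age = pd.Series(rng.uniform(60, 90, 500))
        res = residualize(s, age)
        assert np.corrcoef(res, age)[0, 1] == pytest.approx(0.0, abs=1e-10)
        assert res.mean() == pytest.approx(0.0, abs=1e-10)

    def test_pure_age_score_residuals_vanish(self, rng):
        age = pd.Series(rng.uniform(60, 90, 100))
        res = residualize(2.0 * age, age)
        assert np.abs(res).max() < 1e-10

    def test_orthogonality_on_arbitrary_input(self, rng):
        s = pd.Series(rng.normal(size=200) + 0.05 * np.arange(200))
        age = pd.Series(rng.uniform(50, 90, 200))
        res = residualize(s, age)
        assert abs(np.corrcoef(res, age)[0, 1]) < 1e-10

    def test_constant_age_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            residualize(pd.Series([1.0, 2.0, 3.0]), pd.Series([70.0] * 3))


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self, rng):
        x = pd.Series(rng.normal(size=80))
        y = pd.Series(rng.normal(size=80) + 0.5 * x)
        res = partial_correlation(x, y)
        assert res["r"] == pytest.approx(sps.pearsonr(x, y).statistic, abs=1e-12)

    def test_independent_covariate_leaves_r(self, rng):
        n = 5000
        x = pd.Series(rng.normal(size=n))
        y = pd.Series(0.4 * x + rng.normal(size=n))
        c = pd.DataFrame({"c": rng.normal(size=n)})
        assert partial_correlation(x, y, c)["r"] == pytest.approx(
            sps.pearsonr(x, y).statistic, abs=0.02)

    def test_common_cause_removed(self, rng):
        n = 100_000
        z = rng.normal(size=n)
        x = pd.Series(z + rng.normal(size=n))
        y = pd.Series(z + rng.normal(size=n))
        res = partial_correlation(x, y, pd.DataFrame({"z": z}))
        assert abs(res["r"]) < 0.01

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n = 200
        df = pd.DataFrame({"x": rng.normal(size=n), "c1": rng.normal(size=n),
                           "c2": rng.normal(size=n)})
        df["y"] = 0.3 * df.x + 0.5 * df.c1 + rng.normal(size=n)
        res = partial_correlation(df.x, df.y, df[["c1", "c2"]])
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        assert res["r"] == pytest.approx(ref["r"].iloc[0], abs=1e-9)
        assert res["p"] == pytest.approx(ref["p_val"].iloc[0], rel=1e-6)

    def test_insufficient_pairs_rejected(self):
        x = pd.Series([1.0, 2.0, np.nan, 4.0])
        y = pd.Series([1.0, np.nan, 3.0, 4.0])
        with pytest.raises(ValueError, match="complete pairs"):
            partial_correlation(x, y, pd.DataFrame({"c": [1.0, 2.0, 3.0, 4.0]}))


class TestModeration:
    def test_recovers_simulated_interaction(self):
        rng = np.random.default_rng(10)
        reps, n, beta_int = 200, 600, 0.16
        est = np.empty(reps)
        for i in range(reps):
            focal = pd.Series(rng.normal(size=n))
            mod = pd.Series(rng.integers(0, 2, n).astype(float))
            y = pd.Series(0.4 * focal + 0.2 * mod + beta_int * focal * mod
                          + rng.normal(size=n))
            est[i] = moderation_fit(y, focal, mod)["interaction_beta"]
        assert est.mean() == pytest.approx(beta_int, abs=0.02)

    def test_null_interaction_type_i_error(self):
        rng = np.random.default_rng(11)
        reps = 400
        rejections = 0
        for _ in range(reps):
            focal = pd.Series(rng.normal(size=200))
            mod = pd.Series(rng.integers(0, 2, 200).astype(float))
            y = pd.Series(0.4 * focal + rng.normal(size=200))
            if moderation_fit(y, focal, mod)["interaction_p"] < 0.05:
                rejections += 1
        assert 0.02 <= rejections / reps <= 0.08

    def test_constant_moderator_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            moderation_fit(pd.Series(rng.normal(size=20)),
                           pd.Series(rng.normal(size=20)),
                           pd.Series(np.ones(20)))


class TestMediation:
    def test_acme_plus_ade_equals_total(self, rng):
        df = simulate_mediation_triple(500, seed=3)
        res = mediation_bootstrap(df["treatment"], df["mediator"],
                                  df["outcome"], B=100, seed=1)
        assert res.acme + res.ade == pytest.approx(res.total, abs=1e-10)

    def test_recovers_35_percent_mediated(self):
        df = simulate_mediation_triple(1500, seed=21)
        res = mediation_bootstrap(df["treatment"], df["mediator"],
                                  df["outcome"], B=1000, seed=2)
        assert res.prop_ci[0] <= 0.35 <= res.prop_ci[1]
        assert res.proportion_mediated == pytest.approx(0.35, abs=0.10)

    def test_null_b_path_ci_coverage(self):
        """With b = 0 the ACME CI should cover 0 at ~95%."""
        rng = np.random.default_rng(13)
        covered, reps = 0, 150
        for i in range(reps):
            n = 200
            t = (rng.random(n) < 0.4).astype(float)
            m = 0.6 * t + rng.normal(size=n)
            y = 0.5 * t + rng.normal(size=n)  # mediator plays no role
            res = mediation_bootstrap(pd.Series(t), pd.Series(m), pd.Series(y),
                                      B=200, seed=i)
            if res.acme_ci[0] <= 0.0 <= res.acme_ci[1]:
                covered += 1
        assert 0.89 <= covered / reps <= 0.99

    def test_education_adjustment_attenuates_mediation(self):
        df = simulate_mediation_triple(4000, a=0.0, edu_to_mediator=1.0,
                                       seed=4)
        unadj = mediation_bootstrap(df["treatment"], df["mediator"],
                                    df["outcome"], B=200, seed=5)
        adj = mediation_bootstrap(df["treatment"], df["mediator"],
                                  df["outcome"], df[["education"]],
                                  B=200, seed=5)
        assert adj.proportion_mediated < unadj.proportion_mediated
        assert unadj.proportion_mediated > 0.2

    def test_determinism(self):
        df = simulate_mediation_triple(300, seed=6)
        r1 = mediation_bootstrap(df["treatment"], df["mediator"],
                                 df["outcome"], B=150, seed=9)
        r2 = mediation_bootstrap(df["treatment"], df["mediator"],
                                 df["outcome"], B=150, seed=9)
        assert r1.acme_ci == r2.acme_ci and r1.acme_p == r2.acme_p


class TestOutlierMask:
    def test_hand_computed_madz_not_flagged(self):
        x = np.arange(1.0, 10.0)  # median 5, MAD 2; MAD-Z(9) = 1.349
        mask = outlier_mask(x)
        assert not mask.any()

    def test_extreme_point_flagged(self):
        x = np.r_[np.full(20, 1.0), 50.0]
        with pytest.warns(UserWarning, match="MAD is zero"):
            mask = outlier_mask(x)
        assert mask[-1] and mask[:-1].sum() == 0

    def test_null_rate_below_half_percent(self, rng):
        x = rng.normal(size=10_000)
        assert outlier_mask(x).mean() < 0.005

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            outlier_mask(np.array([1.0, 2.0]))
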