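"""Inferential battery for score validation.

Group comparisons (Welch t / Welch ANOVA / Pearson), incremental validity
(delta R^2 and semi-partial R^2), MCI discrimination (logistic ORs, AUC,
DeLong paired-AUC tests, nested likelihood-ratio tests), age
residualization, partial correlations, moderation, nonparametric bootstrap
mediation, and dual-criterion outlier masking.

All p-values are unadjusted two-tailed at alpha = 0.05, and every
randomized procedure records the seed it ran under.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# group tests
# --------------------------------------------------------------------------

def welch_anova(groups: list[np.ndarray]) -> tuple[float, float, float, float]:
    """Welch's heteroscedastic one-way ANOVA.

    Returns (F, df1, df2, p).  Weights are w_i = n_i / s_i^2; the
    denominator degrees of freedom follow Welch (1951).
    """
    k = len(groups)
    n = np.array([len(g) for g in groups], dtype=float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    w = n / v
    mw = (w * m).sum() / w.sum()
    num = ((w * (m - mw) ** 2).sum()) / (k - 1)
    h = ((1 - w / w.sum()) ** 2 / (n - 1)).sum()
    den = 1 + 2 * (k - 2) / (k ** 2 - 1) * h
    F = num / den
    df1 = k - 1
    df2 = (k ** 2 - 1) / (3 * h)
    p = float(sps.f.sf(F, df1, df2))
    return float(F), float(df1), float(df2), p


def group_tests(score: pd.Series, grouping: pd.Series) -> dict:
    """Dispatch on the grouping variable's type.

    Binary grouping -> Welch two-sample t-test; three or more levels ->
    Welch ANOVA; continuous -> Pearson correlation with a t-based p.
    """
    joined = pd.concat([score.rename("score"), grouping.rename("group")],
                       axis=1).dropna()
    s, grp = joined["score"], joined["group"]
    is_numeric = pd.api.types.is_numeric_dtype(grp)
    levels = grp.unique()
    if is_numeric and len(levels) > 10:
        r, p = sps.pearsonr(s, grp.astype(float))
        return {"test": "pearson", "r": float(r), "p": float(p),
                "n": len(s), "significant": bool(p < 0.05)}
    groups = [s[grp == lev].to_numpy(dtype=float) for lev in sorted(levels)]
    for lev, g in zip(sorted(levels), groups):
        if len(g) < 2:
            raise ValueError(f"group {lev!r} has fewer than 2 observations")
    if len(levels) == 2:
        res = sps.ttest_ind(groups[0], groups[1], equal_var=False)
        return {"test": "welch_t", "t": float(res.statistic),
                "df": float(res.df), "p": float(res.pvalue),
                "means": {str(lev): float(g.mean())
                          for lev, g in zip(sorted(levels), groups)},
                "n": len(s), "significant": bool(res.pvalue < 0.05)}
    F, df1, df2, p = welch_anova(groups)
    return {"test": "welch_anova", "F": F, "df1": df1, "df2": df2, "p": p,
            "n": len(s), "significant": bool(p < 0.05)}


# --------------------------------------------------------------------------
# incremental validity
# --------------------------------------------------------------------------

@dataclass
class IncrementalFit:
    base_r2: float
    full_r2: float
    delta_r2: float
    sr2: dict[str, float]
    coefficients: pd.DataFrame  # coef, se, t, p, ci_low, ci_high
    n: int

    def to_dict(self) -> dict:
        return {"base_r2": self.base_r2, "full_r2": self.full_r2,
                "delta_r2": self.delta_r2, "sr2": self.sr2, "n": self.n,
                "coefficients": self.coefficients.round(6).to_dict("index")}


def _check_collinear(X: pd.DataFrame) -> None:
    A = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        # identify an offending column by leave-one-out rank
        for col in X.columns:
            sub = X.drop(columns=[col])
            B = np.column_stack([np.ones(len(X)), sub.to_numpy(dtype=float)])
            if np.linalg.matrix_rank(B) == np.linalg.matrix_rank(A):
                raise ValueError(f"exact collinearity involving column {col!r}")
        raise ValueError("exact collinearity in design")


def incremental_r2(
    outcome: pd.Series,
    base: pd.DataFrame,
    added: pd.Series | pd.DataFrame,
) -> IncrementalFit:
    """Hierarchical OLS: base model vs base + added predictor(s).

    Reports delta R^2, the semi-partial R^2 of each added predictor (full
    R^2 minus the R^2 of the full model without that predictor; for a
    single added predictor sr^2 equals delta R^2 exactly), and full-model
    coefficients with t-based 95% CIs.
    """
    added = added.to_frame() if isinstance(added, pd.Series) else added
    data = pd.concat([outcome.rename("_y"), base, added], axis=1).dropna()
    y = data["_y"]
    Xb = data[list(base.columns)]
    Xf = data[list(base.columns) + list(added.columns)]
    _check_collinear(Xf)
    fit_b = sm.OLS(y, sm.add_constant(Xb.astype(float))).fit()
    fit_f = sm.OLS(y, sm.add_constant(Xf.astype(float))).fit()
    sr2 = {}
    for col in added.columns:
        X_wo = Xf.drop(columns=[col])
        r2_wo = sm.OLS(y, sm.add_constant(X_wo.astype(float))).fit().rsquared
        sr2[col] = float(fit_f.rsquared - r2_wo)
    ci = fit_f.conf_int()
    coefs = pd.DataFrame({
        "coef": fit_f.params, "se": fit_f.bse, "t": fit_f.tvalues,
        "p": fit_f.pvalues, "ci_low": ci[0], "ci_high": ci[1],
    })
    return IncrementalFit(float(fit_b.rsquared), float(fit_f.rsquared),
                          float(fit_f.rsquared - fit_b.rsquared), sr2,
                          coefs, int(fit_f.nobs))


# --------------------------------------------------------------------------
# discrimination: AUC, DeLong, likelihood-ratio
# --------------------------------------------------------------------------

def auc(labels, scores) -> float:
    """Mann-Whitney concordance AUC with half credit for ties."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.min() == y.max():
        raise ValueError("both classes must be present to compute an AUC")
    ranks = sps.rankdata(s)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _delong_placements(y: np.ndarray, s: np.ndarray):
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)
    # placement of each positive among the negatives and vice versa (ties get 1/2)
    gt = pos[:, None] > neg[None, :]
    eq = pos[:, None] == neg[None, :]
    v10 = (gt.sum(axis=1) + 0.5 * eq.sum(axis=1)) / n
    v01 = (gt.sum(axis=0) + 0.5 * eq.sum(axis=0)) / m
    return v10, v01


def delong_test(labels, scores_a, scores_b) -> dict:
    """DeLong's paired test for the difference of two correlated AUCs.

    Uses the structural-components (placement-value) covariance estimate
    and a two-sided z test on delta AUC.  Identical or degenerate score
    pairs (zero variance of the difference) return delta AUC with p = 1 by
    convention.
    """
    y = np.asarray(labels, dtype=int)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    v10a, v01a = _delong_placements(y, a)
    v10b, v01b = _delong_placements(y, b)
    auc_a, auc_b = v10a.mean(), v10b.mean()
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    delta = auc_a - auc_b
    if var_diff <= 0:
        logger.info("delong_test: zero variance of the AUC difference; p = 1")
        return {"auc_a": float(auc_a), "auc_b": float(auc_b),
                "delta_auc": float(delta), "z": 0.0, "p": 1.0}
    z = delta / np.sqrt(var_diff)
    p = float(2 * sps.norm.sf(abs(z)))
    return {"auc_a": float(auc_a), "auc_b": float(auc_b),
            "delta_auc": float(delta), "z": float(z), "p": p}


def fit_logistic(y: pd.Series, X: pd.DataFrame):
    """Logistic regression (statsmodels Newton/IRLS, log-likelihood tol 1e-8)."""
    Xc = sm.add_constant(X.astype(float))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y.astype(float), Xc).fit(disp=0, tol=1e-8,
                                                    maxiter=200)
    except Exception as e:  # perfect separation or singular design
        raise RuntimeError(f"logistic fit failed for predictors "
                           f"{list(X.columns)}: {e}") from e
    if not np.all(np.isfinite(fit.params)):
        raise RuntimeError(f"logistic fit diverged (separation?) for "
                           f"predictors {list(X.columns)}")
    return fit


def nested_lr_test(fit_reduced, fit_full) -> dict:
    """Likelihood-ratio test for nested fits: chi2 = 2 (LL_full - LL_reduced)."""
    chi2 = 2.0 * (fit_full.llf - fit_reduced.llf)
    df = int(fit_full.df_model - fit_reduced.df_model)
    if chi2 < -1e-6:
        raise RuntimeError("full model has lower likelihood than reduced model; "
                           "fits are not properly nested or did not converge")
    chi2 = max(chi2, 0.0)
    p = float(sps.chi2.sf(chi2, df)) if df > 0 else 1.0
    return {"chi2": float(chi2), "df": df, "p": p}


def odds_reduction_percent(odds_ratio: float) -> float:
    """Report an OR < 1 as a percent reduction in odds: 100 (1 - OR)."""
    return 100.0 * (1.0 - odds_ratio)


@dataclass
class DiscriminationFit:
    models: dict[str, dict] = field(default_factory=dict)
    comparisons: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"models": self.models, "comparisons": self.comparisons}


def discrimination_suite(
    pheno: pd.DataFrame,
    score: pd.Series,
    diagnosis_col: str = "mci",
    base_cols: tuple[str, ...] = ("age", "sex", "education"),
    screener_col: str | None = None,
    extra_sets: dict[str, list[str]] | None = None,
) -> DiscriminationFit:
    """Ladder of nested logistic models for the binary diagnosis.

    Fits base; base+score; optionally base+screener(+score) and
    base+extras(+score) for each supplied extra predictor set.  The score
    is standardized first so its OR is per SD; each nested pair gets a
    DeLong delta-AUC test (on fitted probabilities) and a likelihood-ratio
    test.
    """
    data = pheno.copy()
    data["_score"] = (score - score.mean()) / score.std()
    keep = [diagnosis_col, "_score", *base_cols]
    if screener_col:
        keep.append(screener_col)
    for cols in (extra_sets or {}).values():
        keep.extend(cols)
    data = data[list(dict.fromkeys(keep))].dropna()
    y = data[diagnosis_col].astype(int)

    def design(cols):
        X = data[list(cols)]
        num = X.select_dtypes(include=[np.number])
        cat = X.select_dtypes(exclude=[np.number])
        if len(cat.columns):
            num = pd.concat([num, pd.get_dummies(cat.astype(str),
                                                 drop_first=True, dtype=float)],
                            axis=1)
        return num

    ladders = [("base", list(base_cols)),
               ("base+score", list(base_cols) + ["_score"])]
    pairs = [("base", "base+score")]
    if screener_col:
        ladders += [("base+screener", list(base_cols) + [screener_col]),
                    ("base+screener+score",
                     list(base_cols) + [screener_col, "_score"])]
        pairs += [("base", "base+screener"),
                  ("base+screener", "base+screener+score")]
    for name, cols in (extra_sets or {}).items():
        ladders += [(f"base+{name}", list(base_cols) + list(cols)),
                    (f"base+{name}+score", list(base_cols) + list(cols) + ["_score"])]
        pairs += [(f"base+{name}", f"base+{name}+score")]

    out = DiscriminationFit()
    fits, probs = {}, {}
    for name, cols in ladders:
        fit = fit_logistic(y, design(cols))
        fits[name] = fit
        probs[name] = np.asarray(fit.predict())
        ci = fit.conf_int()
        entry = {
            "auc": auc(y.to_numpy(), probs[name]),
            "log_likelihood": float(fit.llf),
            "n": int(fit.nobs),
            "coefficients": {k: float(v) for k, v in fit.params.items()},
        }
        if "_score" in fit.params.index:
            or_ = float(np.exp(fit.params["_score"]))
            entry["score_or_per_sd"] = or_
            entry["score_or_ci"] = [float(np.exp(ci.loc["_score", 0])),
                                    float(np.exp(ci.loc["_score", 1]))]
            entry["score_p"] = float(fit.pvalues["_score"])
            entry["score_odds_reduction_pct"] = odds_reduction_percent(or_)
        out.models[name] = entry
    for red, full in pairs:
        d = delong_test(y.to_numpy(), probs[full], probs[red])
        lr = nested_lr_test(fits[red], fits[full])
        out.comparisons.append({
            "reduced": red, "full": full,
            "delta_auc": d["delta_auc"], "delong_p": d["p"],
            "chi2": lr["chi2"], "df": lr["df"], "lr_p": lr["p"],
        })
    return out


# --------------------------------------------------------------------------
# residualization, partial correlation, moderation
# --------------------------------------------------------------------------

def residualize(score: pd.Series, age: pd.Series) -> pd.Series:
    """OLS residuals of a score on chronological age (intercept included).

    The residual is uncorrelated with age by construction; for a clock this
    is the usual "age acceleration" metric.
    """
    joined = pd.concat([score.rename("s"), age.rename("a")], axis=1).dropna()
    if len(joined) < 3:
        raise ValueError("residualize needs at least 3 observations")
    a = joined["a"].to_numpy(dtype=float)
    if a.std() == 0:
        raise ValueError("age is constant; cannot residualize")
    X = np.column_stack([np.ones(len(a)), a])
    coef, *_ = np.linalg.lstsq(X, joined["s"].to_numpy(dtype=float), rcond=None)
    resid = joined["s"].to_numpy(dtype=float) - X @ coef
    return pd.Series(resid, index=joined.index, name=f"{score.name}_resid")


def partial_correlation(
    x: pd.Series,
    y: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> dict:
    """Partial Pearson correlation of x and y given covariates.

    Computed as the correlation of OLS residuals; p from a t distribution
    with n - k - 2 df and a Fisher-z 95% CI.  Rows are pairwise-complete
    (dropped if any of x, y, or a covariate is missing).  With no
    covariates this equals the plain Pearson correlation.
    """
    frames = [x.rename("_x"), y.rename("_y")]
    k = 0
    if covariates is not None and covariates.shape[1] > 0:
        frames.append(covariates)
        k = covariates.shape[1]
    data = pd.concat(frames, axis=1).dropna()
    n = len(data)
    if n < k + 3:
        raise ValueError(f"only {n} complete pairs; need at least {k + 3}")
    if k:
        C = np.column_stack([np.ones(n), data.iloc[:, 2:].to_numpy(dtype=float)])
        rx = data["_x"].to_numpy(float) - C @ np.linalg.lstsq(C, data["_x"].to_numpy(float), rcond=None)[0]
        ry = data["_y"].to_numpy(float) - C @ np.linalg.lstsq(C, data["_y"].to_numpy(float), rcond=None)[0]
    else:
        rx, ry = data["_x"].to_numpy(float), data["_y"].to_numpy(float)
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - k - 2
    t = r * np.sqrt(df / max(1e-300, 1.0 - r * r))
    p = float(2 * sps.t.sf(abs(t), df))
    zr = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(n - k - 3)
    ci = (float(np.tanh(zr - 1.959963984540054 * se)),
          float(np.tanh(zr + 1.959963984540054 * se)))
    return {"r": r, "ci": ci, "p": p, "n": n, "df": df}


def moderation_fit(
    outcome: pd.Series,
    focal: pd.Series,
    moderator: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> dict:
    """OLS with a focal x moderator interaction term.

    Returns the interaction coefficient with 95% CI and p, plus the full
    coefficient table.
    """
    mod = moderator.copy()
    if not pd.api.types.is_numeric_dtype(mod):
        mod = pd.get_dummies(mod.astype(str), drop_first=True, dtype=float).iloc[:, 0]
    if mod.dropna().nunique() < 2:
        raise ValueError("moderator is constant")
    X = pd.DataFrame({"focal": focal, "moderator": mod,
                      "focal_x_moderator": focal * mod})
    if covariates is not None:
        X = pd.concat([X, covariates], axis=1)
    data = pd.concat([outcome.rename("_y"), X], axis=1).dropna()
    _check_collinear(data.drop(columns="_y"))
    fit = sm.OLS(data["_y"], sm.add_constant(data.drop(columns="_y").astype(float))).fit()
    ci = fit.conf_int()
    return {
        "interaction_beta": float(fit.params["focal_x_moderator"]),
        "interaction_ci": [float(ci.loc["focal_x_moderator", 0]),
                           float(ci.loc["focal_x_moderator", 1])],
        "interaction_p": float(fit.pvalues["focal_x_moderator"]),
        "n": int(fit.nobs),
        "coefficients": {kk: float(vv) for kk, vv in fit.params.items()},
    }


# --------------------------------------------------------------------------
# mediation
# --------------------------------------------------------------------------

@dataclass
class MediationResult:
    acme: float
    ade: float
    total: float
    proportion_mediated: float | None
    acme_ci: tuple[float, float]
    ade_ci: tuple[float, float]
    total_ci: tuple[float, float]
    prop_ci: tuple[float, float] | None
    acme_p: float
    b_iterations: int
    seed: int
    note: str | None = None

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("acme", "ade", "total", "proportion_mediated", "acme_p",
              "b_iterations", "seed", "note")}
        d["acme_ci"], d["ade_ci"] = list(self.acme_ci), list(self.ade_ci)
        d["total_ci"] = list(self.total_ci)
        d["prop_ci"] = None if self.prop_ci is None else list(self.prop_ci)
        return d


def _ols_coef(y: np.ndarray, cols: list[np.ndarray]) -> np.ndarray:
    X = np.column_stack([np.ones(len(y))] + cols)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef


def _mediation_point(t, m, y, C):
    cov_cols = [C[:, j] for j in range(C.shape[1])] if C is not None else []
    a = _ols_coef(m, [t] + cov_cols)[1]
    coef_y = _ols_coef(y, [m, t] + cov_cols)
    b, direct = coef_y[1], coef_y[2]
    total = _ols_coef(y, [t] + cov_cols)[1]
    return a * b, direct, total


def mediation_bootstrap(
    treatment: pd.Series,
    mediator: pd.Series,
    outcome: pd.Series,
    covariates: pd.DataFrame | None = None,
    B: int = 1000,
    seed: int = 0,
) -> MediationResult:
    """Product-of-coefficients mediation with a case-resampling bootstrap.

    ACME = a*b with a from mediator ~ treatment (+ covariates) and b from
    outcome ~ mediator + treatment (+ covariates); ADE is the direct
    coefficient; for linear models ACME + ADE equals the total effect
    exactly.  Percentile 95% CIs and a two-sided bootstrap p for the ACME.
    Proportion mediated = ACME / total (undefined when the total effect is
    negligible).  Deterministic given ``seed``.
    """
    if B < 100:
        raise ValueError("B must be at least 100 bootstrap iterations")
    frames = [treatment.rename("_t"), mediator.rename("_m"), outcome.rename("_y")]
    if covariates is not None and covariates.shape[1]:
        frames.append(covariates)
    data = pd.concat(frames, axis=1).dropna()
    t = data["_t"].to_numpy(dtype=float)
    m = data["_m"].to_numpy(dtype=float)
    y = data["_y"].to_numpy(dtype=float)
    C = data.iloc[:, 3:].to_numpy(dtype=float) if data.shape[1] > 3 else None

    acme, ade, total = _mediation_point(t, m, y, C)
    rng = np.random.default_rng(seed)
    n = len(t)
    boots = np.empty((B, 3))
    for i in range(B):
        idx = rng.integers(0, n, size=n)
        boots[i] = _mediation_point(t[idx], m[idx], y[idx],
                                    None if C is None else C[idx])
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    frac_pos = (boots[:, 0] > 0).mean()
    acme_p = float(min(1.0, 2 * min(frac_pos, 1 - frac_pos)))

    note, prop, prop_ci = None, None, None
    if abs(total) < 1e-10:
        note = "total effect ~ 0; proportion mediated undefined"
    else:
        prop = float(acme / total)
        prop_boot = boots[:, 0] / boots[:, 2]
        ok = np.abs(boots[:, 2]) > 1e-10
        if ok.sum() >= B // 2:
            plo, phi = np.percentile(prop_boot[ok], [2.5, 97.5])
            prop_ci = (float(plo), float(phi))
    return MediationResult(float(acme), float(ade), float(total), prop,
                           (float(lo[0]), float(hi[0])),
                           (float(lo[1]), float(hi[1])),
                           (float(lo[2]), float(hi[2])),
                           prop_ci, acme_p, B, seed, note)


# --------------------------------------------------------------------------
# outliers
# --------------------------------------------------------------------------

def outlier_mask(x: pd.Series | np.ndarray, z_cut: float = 3.0,
                 madz_cut: float = 3.5) -> np.ndarray:
    """Dual-criterion outlier flag: |z| >= z_cut OR |MAD-Z| >= madz_cut.

    MAD-Z = 0.6745 (x - median) / MAD.  If the MAD is zero the MAD-Z
    criterion is skipped with a warning and the z criterion still applies.
    """
    v = np.asarray(x, dtype=float)
    if len(v) < 3:
        raise ValueError("outlier_mask needs at least 3 observations")
    sd = v.std(ddof=1)
    z = np.zeros_like(v) if sd == 0 else (v - v.mean()) / sd
    flag = np.abs(z) >= z_cut
    mad = np.median(np.abs(v - np.median(v)))
    if mad == 0:
        warnings.warn("MAD is zero; MAD-Z criterion skipped", stacklevel=2)
    else:
        madz = 0.6745 * (v - np.median(v)) / mad
        flag |= np.abs(madz) >= madz_cut
    return flag
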