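"""Group-level inference on fitted behavioral sensitivities.

Covers the four analyses run on per-participant guilt/inequity coefficients:

* Welch two-sample t tests (Satterthwaite df) for sex contrasts on
  beta(Guilt) and beta(Inequity);
* Pearson (optionally Spearman) correlations between beta(Guilt) and the
  three post-task questionnaire items;
* the large-sample covariate regression of beta(Guilt) on Big Five,
  demographic and socioeconomic scores plus their Sex interactions
  (men = 1), mirroring the 22-coefficient table;
* a three-variable mediation model sex -> mediator -> beta with
  percentile-bootstrap (optionally BCa) inference on the indirect effect
  a*b.  For any fixed dataset the OLS decomposition c = c' + a*b holds
  exactly, so testing a*b is testing c - c'.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "WelchResult",
    "PathEstimate",
    "MediationResult",
    "GroupReport",
    "welch_test",
    "questionnaire_correlation",
    "interaction_regression",
    "mediate",
    "group_analysis",
]


@dataclass(frozen=True)
class WelchResult:
    statistic: float
    df: float
    pvalue: float


def welch_test(group1, group2) -> WelchResult:
    """Welch's unequal-variance t test with Satterthwaite df (two-sided)."""
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue))


def questionnaire_correlation(beta_guilt, items: pd.DataFrame,
                              method: str = "pearson") -> dict[str, tuple[float, float]]:
    """Correlate beta(Guilt) with each questionnaire item column.

    Items are ordinal (1-5) but treated numerically; ``method`` may be
    "pearson" (default) or "spearman".  Returns {item: (r, p)}.
    """
    y = np.asarray(beta_guilt, dtype=float)
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    out = {}
    for col in items.columns:
        r = fn(y, items[col].to_numpy(float))
        out[col] = (float(r.statistic), float(r.pvalue))
    return out


#: covariate order of the published coefficient table
REGRESSION_COVARIATES = [
    "neuroticism", "extraversion", "openness", "agreeableness",
    "conscientiousness", "age", "self_edu_history", "parents_edu_history",
    "income", "occupation", "subjective_ses",
]


@dataclass
class GroupReport:
    """Bundle of group-level results (any subset may be filled)."""

    welch: dict[str, WelchResult] = field(default_factory=dict)
    questionnaire: dict[str, tuple[float, float]] = field(default_factory=dict)
    regression: pd.DataFrame | None = None
    adj_r_squared: float | None = None
    n_obs: int | None = None


def interaction_regression(covariates: pd.DataFrame, beta_guilt,
                           include_main_sex: bool = False,
                           include_intercept: bool = True,
                           zscore: bool = True) -> GroupReport:
    """OLS of beta(Guilt) on 11 covariates plus their Sex interactions.

    ``covariates`` needs a ``sex`` column ("male"/"female" or 1/0 with
    men = 1) and the 11 columns of :data:`REGRESSION_COVARIATES`.  Main
    covariates enter for everyone; interactions multiply by the men
    indicator.  The published equation carries no main Sex term and no
    explicit intercept; the default keeps an intercept (standard practice)
    and omits main Sex, both toggleable.  Covariates are z-scored by default
    so coefficients are comparable across scales.

    Listwise deletion is applied to missing rows; a high design condition
    number triggers a collinearity warning naming the worst columns.
    """
    df = covariates.copy()
    sex = df["sex"]
    male = (sex.map({"male": 1, "female": 0}) if sex.dtype == object
            else sex.astype(int)).to_numpy()
    y = np.asarray(beta_guilt, dtype=float)
    missing = [c for c in REGRESSION_COVARIATES if c not in df.columns]
    if missing:
        raise ValueError(f"covariates table missing columns: {missing}")
    Xmain = df[REGRESSION_COVARIATES].to_numpy(float)
    keep = np.isfinite(Xmain).all(axis=1) & np.isfinite(y)
    Xmain, male, y = Xmain[keep], male[keep], y[keep]
    if zscore:
        Xmain = (Xmain - Xmain.mean(axis=0)) / Xmain.std(axis=0, ddof=1)
    cols = list(REGRESSION_COVARIATES)
    blocks = [Xmain]
    if include_main_sex:
        blocks.append(male[:, None].astype(float))
        cols.append("sex")
    blocks.append(Xmain * male[:, None])
    cols += [f"sex_x_{c}" for c in REGRESSION_COVARIATES]
    X = np.column_stack(blocks)
    exog = pd.DataFrame(X, columns=cols)
    if include_intercept:
        exog = sm.add_constant(exog)
    model = sm.OLS(y, exog)
    fit = model.fit()
    if np.linalg.cond(model.exog) > 1e8:
        corr = np.corrcoef(X, rowvar=False)
        iu = np.triu_indices(len(cols), k=1)
        worst = int(np.argmax(np.abs(corr[iu])))
        warnings.warn(
            f"ill-conditioned regression design (cond="
            f"{np.linalg.cond(model.exog):.2e}); most collinear pair: "
            f"{cols[iu[0][worst]]} / {cols[iu[1][worst]]}"
        )
    table = pd.DataFrame({
        "coefficient": fit.params,
        "std_error": fit.bse,
        "t": fit.tvalues,
        "pvalue": fit.pvalues,
    })
    return GroupReport(regression=table,
                       adj_r_squared=float(fit.rsquared_adj),
                       n_obs=int(fit.nobs))


@dataclass(frozen=True)
class PathEstimate:
    coefficient: float
    std_error: float
    pvalue: float


@dataclass
class MediationResult:
    """Three-variable mediation X -> M -> Y with bootstrap indirect effect."""

    path_a: PathEstimate       # X -> M
    path_b: PathEstimate       # M -> Y controlling X
    path_c: PathEstimate       # total X -> Y
    path_c_prime: PathEstimate  # direct X -> Y controlling M
    indirect: float            # a * b
    indirect_ci: tuple[float, float]
    indirect_pvalue: float
    n_boot: int
    seed: int
    ci_method: str = "percentile"

    @property
    def three_test_significant(self) -> bool:
        """The convention requiring a, b and a*b all significant at 0.05."""
        return (self.path_a.pvalue < 0.05 and self.path_b.pvalue < 0.05
                and self.indirect_pvalue < 0.05)


def _ols_paths(X, M, Y):
    """Point estimates and SEs of all four paths via OLS."""
    one = np.ones_like(X)
    fit_a = sm.OLS(M, np.column_stack([one, X])).fit()
    fit_c = sm.OLS(Y, np.column_stack([one, X])).fit()
    fit_bc = sm.OLS(Y, np.column_stack([one, X, M])).fit()
    a = PathEstimate(float(fit_a.params[1]), float(fit_a.bse[1]), float(fit_a.pvalues[1]))
    c = PathEstimate(float(fit_c.params[1]), float(fit_c.bse[1]), float(fit_c.pvalues[1]))
    c_prime = PathEstimate(float(fit_bc.params[1]), float(fit_bc.bse[1]), float(fit_bc.pvalues[1]))
    b = PathEstimate(float(fit_bc.params[2]), float(fit_bc.bse[2]), float(fit_bc.pvalues[2]))
    return a, b, c, c_prime


def _indirect_batch(X, M, Y, idx):
    """Vectorized a*b over bootstrap index matrix (B, n)."""
    Xb, Mb, Yb = X[idx], M[idx], Y[idx]
    n = idx.shape[1]
    # a: slope of M on X
    Xc = Xb - Xb.mean(axis=1, keepdims=True)
    Mc = Mb - Mb.mean(axis=1, keepdims=True)
    Yc = Yb - Yb.mean(axis=1, keepdims=True)
    var_x = np.einsum("bi,bi->b", Xc, Xc)
    a = np.einsum("bi,bi->b", Xc, Mc) / var_x
    # b: partial slope of Y on M given X (FWL: residualize M and Y on X)
    Mr = Mc - (np.einsum("bi,bi->b", Xc, Mc) / var_x)[:, None] * Xc
    Yr = Yc - (np.einsum("bi,bi->b", Xc, Yc) / var_x)[:, None] * Xc
    denom = np.einsum("bi,bi->b", Mr, Mr)
    b = np.einsum("bi,bi->b", Mr, Yr) / denom
    return a * b


def mediate(X, M, Y, n_boot: int = 10000, seed: int = 0,
            ci_level: float = 0.95, ci_method: str = "percentile") -> MediationResult:
    """Mediation analysis with bootstrap inference on the indirect effect.

    ``X`` is the group indicator (e.g. men = 1 for the guilt contrast),
    ``M`` the scalar mediator, ``Y`` the behavioral outcome.  Paths are OLS;
    the indirect effect a*b gets a case-resampling bootstrap CI and a
    two-sided bootstrap p-value (smallest level at which the CI excludes 0).
    ``ci_method`` is "percentile" (default) or "bca" (bias-corrected and
    accelerated).  Deterministic given seed.
    """
    X = np.asarray(X, dtype=float)
    M = np.asarray(M, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = len(X)
    if not (len(M) == len(Y) == n):
        raise ValueError("X, M, Y must have equal length")
    if n < 10:
        raise ValueError("mediation needs at least 10 observations")
    if np.var(M) == 0 or np.var(Y) == 0:
        raise ValueError("zero-variance mediator or outcome")
    if ci_method not in ("percentile", "bca"):
        raise ValueError("ci_method must be 'percentile' or 'bca'")
    a, b, c, c_prime = _ols_paths(X, M, Y)
    indirect = a.coefficient * b.coefficient
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    # guard against degenerate resamples (all-equal X)
    bad = np.ptp(X[idx], axis=1) == 0
    while bad.any():
        idx[bad] = rng.integers(0, n, size=(int(bad.sum()), n))
        bad = np.ptp(X[idx], axis=1) == 0
    boots = _indirect_batch(X, M, Y, idx)
    alpha = 1.0 - ci_level
    if ci_method == "percentile":
        lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
        # fraction of bootstrap mass on the far side of zero
        p_lo = np.mean(boots <= 0)
        p_hi = np.mean(boots >= 0)
        pval = float(min(1.0, 2 * min(p_lo, p_hi)))
    else:
        lo, hi, pval = _bca(X, M, Y, boots, indirect, alpha)
    return MediationResult(
        path_a=a, path_b=b, path_c=c, path_c_prime=c_prime,
        indirect=float(indirect), indirect_ci=(float(lo), float(hi)),
        indirect_pvalue=pval, n_boot=n_boot, seed=seed, ci_method=ci_method,
    )


def _bca(X, M, Y, boots, theta_hat, alpha):
    """Bias-corrected and accelerated interval for the indirect effect."""
    n = len(X)
    z0 = stats.norm.ppf(np.clip(np.mean(boots < theta_hat), 1e-9, 1 - 1e-9))
    # jackknife for acceleration
    jack = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        a_i, b_i, *_ = _ols_paths(X[mask], M[mask], Y[mask])
        jack[i] = a_i.coefficient * b_i.coefficient
        mask[i] = True
    d = jack.mean() - jack
    accel = np.sum(d**3) / (6 * np.sum(d**2) ** 1.5 + 1e-300)

    def adj(q):
        z = stats.norm.ppf(q)
        return stats.norm.cdf(z0 + (z0 + z) / (1 - accel * (z0 + z)))

    lo, hi = np.quantile(boots, [adj(alpha / 2), adj(1 - alpha / 2)])
    # p-value: smallest alpha at which the BCa interval excludes zero
    grid = np.linspace(1e-4, 0.9999, 400)
    pval = 1.0
    for g in grid:
        l, h = np.quantile(boots, [adj(g / 2), adj(1 - g / 2)])
        if l > 0 or h < 0:
            pval = float(g)
            break
    return float(lo), float(hi), pval


def group_analysis(fits: pd.DataFrame, covariates: pd.DataFrame,
                   questionnaire_method: str = "pearson") -> GroupReport:
    """Sex contrasts and questionnaire correlations for a fitted cohort.

    ``fits`` is the per-participant fit table (pid, beta_guilt,
    beta_inequity, ...) and ``covariates`` the cohort covariate table (pid,
    sex, q_a, q_b, q_c, ...).  Welch contrasts are oriented per the
    analyses' coding: men - women for guilt, women - men for inequity.
    """
    merged = fits.merge(covariates, on="pid", validate="one_to_one")
    men = merged[merged["sex"] == "male"]
    women = merged[merged["sex"] == "female"]
    report = GroupReport()
    report.welch["beta_guilt_men_vs_women"] = welch_test(
        men["beta_guilt"], women["beta_guilt"])
    if merged["beta_inequity"].notna().all():
        report.welch["beta_inequity_women_vs_men"] = welch_test(
            women["beta_inequity"], men["beta_inequity"])
    items = [c for c in ("q_a", "q_b", "q_c") if c in merged.columns]
    if items:
        report.questionnaire = questionnaire_correlation(
            merged["beta_guilt"], merged[items], method=questionnaire_method)
    report.n_obs = len(merged)
    return report
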