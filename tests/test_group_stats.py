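"""Welch contrasts, questionnaire correlations, covariate regression and
bootstrap mediation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import guiltgame as gg


# --- Welch test -------------------------------------------------------------

def test_welch_matches_hand_formula():
    a = np.array([1.1, 2.9, 4.0])
    b = np.array([2.0, 6.5, 9.5])
    res = gg.welch_test(a, b)
    va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / 2 + vb ** 2 / 2)
    p = 2 * stats.t.sf(abs(t), df)
    assert res.statistic == pytest.approx(t, abs=1e-10)
    assert res.df == pytest.approx(df, abs=1e-10)
    assert res.pvalue == pytest.approx(p, abs=1e-10)


def test_welch_identical_groups():
    res = gg.welch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.statistic == pytest.approx(0.0)
    assert res.pvalue == pytest.approx(1.0)


def test_welch_satterthwaite_df_bounds_and_equal_variance_limit():
    res = gg.welch_test([1.0, 2.0, 3.0, 4.0], [11.0, 12.0, 13.0, 14.0])
    assert res.df == pytest.approx(6.0)      # equal variance, equal n: 2n-2
    a = np.array([0.0, 0.1, 0.2])
    b = np.array([0.0, 5.0, 10.0, 15.0, 20.0])
    res2 = gg.welch_test(a, b)
    assert min(len(a), len(b)) - 1 <= res2.df <= len(a) + len(b) - 2


def test_welch_needs_two_per_group():
    with pytest.raises(ValueError):
        gg.welch_test([1.0], [1.0, 2.0])


# --- questionnaire correlations --------------------------------------------

def test_questionnaire_correlation_both_methods():
    rng = np.random.default_rng(0)
    beta = rng.standard_normal(80)
    items = pd.DataFrame({
        "q_a": np.clip(np.round(3 + beta + 0.5 * rng.standard_normal(80)), 1, 5),
        "q_b": rng.integers(1, 6, 80).astype(float),
    })
    out = gg.questionnaire_correlation(beta, items)
    r_ref, p_ref = stats.pearsonr(beta, items["q_a"])
    assert out["q_a"] == pytest.approx((r_ref, p_ref))
    out_s = gg.questionnaire_correlation(beta, items, method="spearman")
    r_s = stats.spearmanr(beta, items["q_a"]).statistic
    assert out_s["q_a"][0] == pytest.approx(r_s)
    with pytest.raises(ValueError):
        gg.questionnaire_correlation(beta, items, method="kendall")


# --- covariate interaction regression ---------------------------------------

def _fitted_cohort(design, cfg):
    records = gg.simulate_cohort(design, cfg)
    choices, covariates = gg.cohort_frames(records)
    fits = gg.fit_cohort(choices, design)
    return fits.merge(covariates, on="pid", validate="one_to_one")


def test_interaction_regression_recovers_agreeableness_effect(canonical_design):
    """A cohort whose guilt sensitivity depends only on Agreeableness should
    yield a clearly positive Agreeableness coefficient on true log gamma."""
    cfg = gg.CohortConfig(
        n_per_sex=300, seed=11,
        agreeableness_effect=0.3, conscientiousness_effect_men=0.0,
        mediation=gg.MediationConfig(b=0.0),
    )
    records = gg.simulate_cohort(canonical_design, cfg)
    _, covariates = gg.cohort_frames(records)
    y = np.log(covariates["true_gamma"])
    report = gg.interaction_regression(covariates, y)
    table = report.regression
    assert table.loc["agreeableness", "coefficient"] > 0
    assert table.loc["agreeableness", "pvalue"] < 0.01
    assert table.loc["sex_x_conscientiousness", "pvalue"] > 0.01
    assert report.n_obs == 600


def test_interaction_regression_detects_male_conscientiousness_effect(canonical_design):
    """Men-only Conscientiousness effect loads on the Sex interaction term."""
    cfg = gg.CohortConfig(
        n_per_sex=400, seed=12,
        agreeableness_effect=0.0, conscientiousness_effect_men=0.4,
        mediation=gg.MediationConfig(b=0.0),
    )
    records = gg.simulate_cohort(canonical_design, cfg)
    _, covariates = gg.cohort_frames(records)
    y = np.log(covariates["true_gamma"])
    report = gg.interaction_regression(covariates, y)
    table = report.regression
    assert table.loc["sex_x_conscientiousness", "coefficient"] > 0
    assert table.loc["sex_x_conscientiousness", "pvalue"] < 0.05


def test_interaction_regression_estimated_betas_table_shape(canonical_design):
    merged = _fitted_cohort(canonical_design, gg.CohortConfig(n_per_sex=40, seed=13))
    report = gg.interaction_regression(merged, merged["beta_guilt"],
                                       include_main_sex=True)
    # intercept + 11 mains + sex + 11 interactions
    assert len(report.regression) == 24
    assert report.adj_r_squared is not None


def test_interaction_regression_null_cohort_type_one_rate(canonical_design):
    """With no configured covariate effects, the 22-term table should show
    roughly the nominal false-positive count."""
    cfg = gg.CohortConfig(
        n_per_sex=250, seed=14,
        agreeableness_effect=0.0, conscientiousness_effect_men=0.0,
        mediation=gg.MediationConfig(b=0.0),
    )
    records = gg.simulate_cohort(canonical_design, cfg)
    _, covariates = gg.cohort_frames(records)
    rng = np.random.default_rng(0)
    y = rng.standard_normal(len(covariates))     # pure noise outcome
    report = gg.interaction_regression(covariates, y)
    n_sig = int((report.regression["pvalue"].drop("const", errors="ignore") < 0.05).sum())
    assert n_sig <= 5       # E = 22 * 0.05 = 1.1; generous upper bound


def test_interaction_regression_missing_column(canonical_design, small_cohort):
    _, _, covariates = small_cohort
    with pytest.raises(ValueError, match="missing columns"):
        gg.interaction_regression(covariates.drop(columns=["openness"]),
                                  np.zeros(len(covariates)))


# --- mediation ---------------------------------------------------------------

def _mediation_data(n=52, a=1.0, b=1.0, c_prime=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.repeat([1.0, 0.0], n // 2)
    M = a * X + 0.5 * rng.standard_normal(n)
    Y = b * M + c_prime * X + 0.5 * rng.standard_normal(n)
    return X, M, Y


def test_mediation_decomposition_identity():
    """c - c' equals a*b exactly on any fixed dataset (OLS identity)."""
    for seed in range(5):
        X, M, Y = _mediation_data(seed=seed, c_prime=0.4)
        res = gg.mediate(X, M, Y, n_boot=50, seed=0)
        assert (res.path_c.coefficient - res.path_c_prime.coefficient
                == pytest.approx(res.indirect, abs=1e-12))


def test_mediation_reproducible_given_seed():
    X, M, Y = _mediation_data()
    r1 = gg.mediate(X, M, Y, n_boot=500, seed=3)
    r2 = gg.mediate(X, M, Y, n_boot=500, seed=3)
    assert r1.indirect_ci == r2.indirect_ci
    assert r1.indirect_pvalue == r2.indirect_pvalue


def test_complete_mediation_detected():
    """a and b real, c' zero: the indirect path is significant while the
    direct path is not, in most replicates."""
    three_sig = cp_ns = 0
    for rep in range(25):
        X, M, Y = _mediation_data(seed=100 + rep)
        res = gg.mediate(X, M, Y, n_boot=1000, seed=rep)
        three_sig += res.three_test_significant
        cp_ns += res.path_c_prime.pvalue >= 0.05
    assert three_sig >= 20
    assert cp_ns >= 18


def test_null_indirect_effect_covers_zero():
    covered = 0
    for rep in range(30):
        rng = np.random.default_rng(200 + rep)
        X = np.repeat([1.0, 0.0], 26)
        M = X + 0.5 * rng.standard_normal(52)
        Y = 0.5 * X + 0.5 * rng.standard_normal(52)   # direct effect only
        res = gg.mediate(X, M, Y, n_boot=500, seed=rep)
        covered += res.indirect_ci[0] <= 0 <= res.indirect_ci[1]
    assert covered >= 24


def test_mediation_bca_interval_runs():
    X, M, Y = _mediation_data(seed=1)
    res = gg.mediate(X, M, Y, n_boot=500, seed=0, ci_method="bca")
    assert res.ci_method == "bca"
    assert res.indirect_ci[0] < res.indirect < res.indirect_ci[1]


def test_mediation_input_validation():
    X, M, Y = _mediation_data()
    with pytest.raises(ValueError, match="zero-variance"):
        gg.mediate(X, np.ones_like(M), Y, n_boot=10)
    with pytest.raises(ValueError, match="at least 10"):
        gg.mediate(X[:8], M[:8], Y[:8], n_boot=10)
    with pytest.raises(ValueError, match="equal length"):
        gg.mediate(X, M[:-1], Y, n_boot=10)


# --- cohort-level driver -----------------------------------------------------

def test_group_analysis_bundles_contrasts_and_correlations(canonical_design):
    merged_src = gg.simulate_cohort(canonical_design,
                                    gg.CohortConfig(n_per_sex=15, seed=21))
    choices, covariates = gg.cohort_frames(merged_src)
    fits = gg.fit_cohort(choices, canonical_design)
    report = gg.group_analysis(fits, covariates)
    assert "beta_guilt_men_vs_women" in report.welch
    assert "beta_inequity_women_vs_men" in report.welch
    assert set(report.questionnaire) == {"q_a", "q_b", "q_c"}
    assert report.n_obs == 30
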