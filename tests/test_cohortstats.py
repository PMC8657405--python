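"""Cohort statistics: scoring, gated tests, regression, matching."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ventriflow.cohortstats import (
    ChadsVascInput,
    chads_vasc,
    compare_groups,
    normality_gate,
    pearson_corr,
    pct_change,
    propensity_match,
    regression_fit,
    ttest_from_summary,
)
from ventriflow.phantom import make_two_group_cohort


# -- CHA2DS2-VASc ------------------------------------------------------------


@pytest.mark.parametrize(
    "kwargs, expected",
    [
        (dict(age_years=77, sex="F"), 3),  # age>=75 (2) + female (1)
        (dict(age_years=66, sex="F", hypertension=True), 3),
        (dict(age_years=40, sex="M"), 0),
        (dict(age_years=75, sex="M"), 2),
        (dict(age_years=74, sex="M"), 1),
        (dict(age_years=64, sex="M"), 0),
        (dict(age_years=80, sex="F", chf_lv_dysfunction=True, hypertension=True,
              diabetes=True, stroke_tia=True, vascular_disease=True), 9),
    ],
)
def test_chads_vasc_scoring(kwargs, expected):
    assert chads_vasc(ChadsVascInput(**kwargs)) == expected


def test_chads_vasc_rejects_bad_input():
    with pytest.raises(ValueError):
        ChadsVascInput(age_years=-1, sex="F")
    with pytest.raises(ValueError):
        ChadsVascInput(age_years=50, sex="x")


# -- normality gate ----------------------------------------------------------


def test_gate_level_on_normal_samples():
    rng = np.random.default_rng(7)
    passed = sum(normality_gate(rng.normal(size=50))[0] for _ in range(1000))
    assert passed >= 900


def test_gate_power_on_exponential_samples():
    rng = np.random.default_rng(8)
    rejected = sum(not normality_gate(rng.exponential(size=50))[0] for _ in range(1000))
    assert rejected >= 950


def test_gate_constant_sample_degenerate():
    is_normal, w, p, degenerate = normality_gate([2.0] * 10)
    assert not is_normal and degenerate


# -- group comparison --------------------------------------------------------


def sex_table():
    rows = [("control", "F")] * 10 + [("control", "M")] * 20
    rows += [("PAF", "F")] * 16 + [("PAF", "M")] * 34
    return pd.DataFrame(rows, columns=["group", "sex"])


def test_chi_square_sex_counts():
    """10/30 vs 16/50 female counts: chi2 = 0.0152, p = 0.902 (no Yates)."""
    res = compare_groups(sex_table(), "sex", kind="categorical")
    assert res.statistic == pytest.approx(0.0152, abs=2e-4)
    assert res.p_two_sided == pytest.approx(0.902, abs=0.002)


def test_gated_style_selection():
    rng = np.random.default_rng(2)
    normal = pd.DataFrame({
        "group": ["a"] * 40 + ["b"] * 40,
        "v": np.r_[rng.normal(0, 1, 40), rng.normal(0.2, 1, 40)],
    })
    res = compare_groups(normal, "v")
    assert res.test_name == "t-pooled" and res.summary_style == "mean±sd"
    skewed = pd.DataFrame({
        "group": ["a"] * 40 + ["b"] * 40,
        "v": np.r_[rng.exponential(1, 40), rng.exponential(1.1, 40)],
    })
    res = compare_groups(skewed, "v")
    assert res.test_name == "mann-whitney"
    assert res.summary_style == "median[Q1–Q3]"
    assert "median" in res.group_summaries["a"]


def test_mwu_identical_groups_p_one():
    x = np.random.default_rng(0).exponential(1.0, 30)  # fails the gate
    t = pd.DataFrame({"group": ["a"] * 30 + ["b"] * 30, "v": np.r_[x, x]})
    res = compare_groups(t, "v")
    assert res.test_name == "mann-whitney"
    assert res.p_two_sided == pytest.approx(1.0, abs=1e-9)


def test_type_one_error_calibration():
    """Null rejection rate of the full gated comparison at alpha=0.05 over
    1000 seeded replicates (n=30/50) stays within [0.03, 0.07]."""
    rng = np.random.default_rng(42)
    rejections = 0
    for _ in range(1000):
        v = np.r_[rng.normal(0, 1, 30), rng.normal(0, 1, 50)]
        t = pd.DataFrame({"group": ["a"] * 30 + ["b"] * 50, "v": v})
        if compare_groups(t, "v").p_two_sided < 0.05:
            rejections += 1
    assert 0.03 <= rejections / 1000 <= 0.07


# -- summary-statistic t-tests ----------------------------------------------


def test_summary_ttest_direct_flow_row():
    res = ttest_from_summary(50.0, 12.2, 30, 44.5, 11.2, 50, "pooled")
    assert res.p_two_sided == pytest.approx(0.042, abs=0.005)
    assert res.df == 78


def test_summary_ttest_age_row_welch():
    res = ttest_from_summary(50, 8, 30, 56, 12, 50, "welch")
    assert res.p_two_sided == pytest.approx(0.009, abs=0.002)
    assert abs(res.statistic) == pytest.approx(2.68, abs=0.01)


def test_summary_ttest_equal_means():
    res = ttest_from_summary(5.0, 1.0, 10, 5.0, 1.0, 10)
    assert res.statistic == 0.0 and res.p_two_sided == 1.0


def test_summary_ttest_self_consistent_with_raw():
    rng = np.random.default_rng(5)
    a, b = rng.normal(0, 1, 25), rng.normal(0.4, 1.2, 35)
    raw_t, raw_p = stats.ttest_ind(a, b, equal_var=True)
    res = ttest_from_summary(a.mean(), a.std(ddof=1), 25, b.mean(), b.std(ddof=1), 35)
    assert res.statistic == pytest.approx(raw_t, rel=1e-12)
    assert res.p_two_sided == pytest.approx(raw_p, rel=1e-12)


def test_pct_change():
    assert pct_change(44.5, 50.0) == -11
    assert pct_change(21.6, 18.6) == 16
    assert pct_change(7.0, 7.0) == 0
    with pytest.raises(ValueError):
        pct_change(1.0, 0.0)


# -- correlation and regression ----------------------------------------------


def test_pearson_perfect_and_near_perfect():
    x = np.linspace(0, 1, 30)
    r, _ = pearson_corr(x, x)
    assert r == pytest.approx(1.0)
    rng = np.random.default_rng(1)
    r, p = pearson_corr(x, -x + rng.normal(0, 1e-4, 30))
    assert r == pytest.approx(-1.0, abs=1e-4)
    assert p < 1e-10


def test_pearson_null_distribution():
    rng = np.random.default_rng(10)
    inside = sum(
        abs(pearson_corr(rng.normal(size=80), rng.normal(size=80))[0]) < 0.22
        for _ in range(1000)
    )
    assert 0.92 <= inside / 1000 <= 0.98


def test_pearson_zero_variance_rejected():
    with pytest.raises(ValueError):
        pearson_corr([1.0] * 10, list(range(10)))


def test_regression_slope_recovery():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, 50)
    y = 2.0 * x + rng.normal(0, 0.1, 50)
    res = regression_fit(y, x[:, None])
    assert abs(res.coefficients[1] - 2.0) < 2 * res.bse[1]
    assert res.r_squared > 0.95
    assert "F (1, 48)" in res.format_f()


def test_regression_constant_response():
    res = regression_fit(np.ones(20), np.arange(20.0)[:, None])
    assert res.r_squared == 0.0 and res.f_statistic == 0.0


def test_regression_null_r_squared_expectation():
    """Pure-noise response on 4 covariates with n=51: E[R^2] = p/(n-1)."""
    rng = np.random.default_rng(17)
    r2 = [
        regression_fit(rng.normal(size=51), rng.normal(size=(51, 4))).r_squared
        for _ in range(1000)
    ]
    assert np.mean(r2) == pytest.approx(4 / 50, abs=0.02)


def test_regression_rank_deficiency_named():
    x = np.arange(30.0)
    X = pd.DataFrame({"a": x, "b": 2 * x})
    with pytest.raises(ValueError, match="collinear"):
        regression_fit(np.random.default_rng(0).normal(size=30), X)


# -- propensity matching -----------------------------------------------------


def test_matching_identical_covariates_matches_all():
    n = 12
    t = pd.DataFrame({
        "group": ["control"] * n + ["PAF"] * 20,
        "age_years": [50.0] * (n + 20),
        "weight_kg": [70.0] * (n + 20),
    })
    res = propensity_match(t, ["age_years", "weight_kg"], rng_seed=0,
                           treated_value="PAF")
    assert res.n_matched == n  # every comparison subject claimed


def test_matching_fully_separated_matches_none():
    t = pd.DataFrame({
        "group": ["control"] * 15 + ["PAF"] * 15,
        "age_years": list(np.linspace(20, 30, 15)) + list(np.linspace(70, 80, 15)),
    })
    res = propensity_match(t, ["age_years"], rng_seed=0, treated_value="PAF")
    assert res.n_matched == 0
    assert res.matched.empty


def test_matching_never_reuses_subjects():
    tab = make_two_group_cohort(rng_seed=2)
    res = propensity_match(tab, ["age_years", "weight_kg", "bsa_m2"], rng_seed=2,
                           treated_value="PAF")
    treated = [p[0] for p in res.pairs]
    controls = [p[1] for p in res.pairs]
    assert len(set(treated)) == len(treated)
    assert len(set(controls)) == len(controls)


def test_matching_improves_worst_covariate():
    tab = make_two_group_cohort(rng_seed=6)
    covs = ["age_years", "weight_kg", "bsa_m2"]
    res = propensity_match(tab, covs, rng_seed=6, treated_value="PAF")
    worst = max(res.smd_before, key=lambda c: abs(res.smd_before[c]))
    assert abs(res.smd_after[worst]) <= abs(res.smd_before[worst])


def test_matching_balance_monte_carlo():
    """On a shifted synthetic cohort at Monte-Carlo scale (10x the study
    group sizes) every post-match standardized mean difference is < 0.1."""
    tab = make_two_group_cohort(n_control=300, n_paf=500, rng_seed=0)
    res = propensity_match(tab, ["age_years", "weight_kg", "bsa_m2"], rng_seed=0,
                           treated_value="PAF")
    assert res.n_matched > 200
    assert all(abs(v) < 0.1 for v in res.smd_after.values())
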