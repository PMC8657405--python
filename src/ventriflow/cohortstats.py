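"""Two-group cohort statistics for flow-component tables.

Implements the statistical pipeline used to compare flow-component and
volumetric variables between healthy controls and patients with paroxysmal
atrial fibrillation (PAF): Shapiro-Wilk normality gating that selects
between the independent-samples t-test (mean +- SD reporting) and the
Mann-Whitney U test (median [Q1-Q3] reporting), Pearson chi-square for
categorical variables, Pearson correlation, ordinary multiple linear
regression, 1:1 nearest-neighbour propensity-score matching with a logit
caliper, and CHA2DS2-VASc stroke-risk scoring.

Summary-statistic t-tests (:func:`ttest_from_summary`) allow printed group
means and SDs to be re-tested without raw data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "TestResult",
    "ChadsVascInput",
    "chads_vasc",
    "normality_gate",
    "compare_groups",
    "ttest_from_summary",
    "pct_change",
    "regression_fit",
    "pearson_corr",
    "propensity_match",
    "MatchResult",
    "RegressionResult",
]


@dataclass
class TestResult:
    test_name: str  # t-pooled | t-welch | mann-whitney | chi-square | pearson
    statistic: float
    p_two_sided: float
    df: Optional[float] = None
    summary_style: Optional[str] = None  # "mean±sd" | "median[Q1–Q3]"
    group_summaries: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_two_sided <= 1.0 or np.isnan(self.p_two_sided)):
            raise ValueError("p-value outside [0, 1]")


# ---------------------------------------------------------------------------
# CHA2DS2-VASc
# ---------------------------------------------------------------------------


@dataclass
class ChadsVascInput:
    age_years: float
    sex: str  # "F" | "M"
    chf_lv_dysfunction: bool = False
    hypertension: bool = False
    diabetes: bool = False
    stroke_tia: bool = False
    vascular_disease: bool = False

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise ValueError("age must be non-negative")
        if self.sex not in ("F", "M"):
            raise ValueError("sex must be 'F' or 'M'")


def chads_vasc(inp: ChadsVascInput) -> int:
    """CHA2DS2-VASc stroke-risk score, 0-9.

    Congestive heart failure / LV dysfunction (1), hypertension (1),
    age >= 75 (2), diabetes (1), prior stroke/TIA (2), vascular disease (1),
    age 65-74 (1), female sex (1).
    """
    score = 0
    score += int(inp.chf_lv_dysfunction)
    score += int(inp.hypertension)
    if inp.age_years >= 75:
        score += 2
    elif inp.age_years >= 65:
        score += 1
    score += int(inp.diabetes)
    score += 2 * int(inp.stroke_tia)
    score += int(inp.vascular_disease)
    score += int(inp.sex == "F")
    return score


# ---------------------------------------------------------------------------
# normality gate and group comparison
# ---------------------------------------------------------------------------


def normality_gate(sample: Sequence[float], alpha: float = 0.05):
    """Shapiro-Wilk gate: (is_normal, W statistic, p, degenerate flag).

    ``is_normal`` iff the Shapiro-Wilk p-value is at least ``alpha``.
    Constant samples are degenerate and reported as not normal.
    """
    x = np.asarray(sample, dtype=np.float64)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError("normality test needs n >= 3")
    if np.ptp(x) == 0:
        return False, float("nan"), float("nan"), True
    w, p = stats.shapiro(x)
    return bool(p >= alpha), float(w), float(p), False


def _summaries(x: np.ndarray, style: str) -> dict:
    if style == "mean±sd":
        return {"mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1)), "n": x.size}
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3), "n": x.size}


def compare_groups(
    table: pd.DataFrame,
    variable: str,
    kind: str = "continuous",
    group_col: str = "group",
    t_variant: str = "pooled",
    alpha_normality: float = 0.05,
) -> TestResult:
    """Normality-gated two-group comparison of one variable.

    Continuous variables: when both groups pass the Shapiro-Wilk gate, an
    independent-samples t-test (pooled by default, Welch optional) with
    mean +- SD summaries; otherwise a Mann-Whitney U test (normal
    approximation with tie correction; exact for n <= 12 without ties) with
    median [Q1-Q3] summaries. Categorical variables: Pearson chi-square on
    the contingency table, without continuity correction. Two-sided
    throughout.
    """
    groups = [g for g, _ in table.groupby(group_col, sort=True)]
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, found {groups}")
    ga = table[table[group_col] == groups[0]][variable]
    gb = table[table[group_col] == groups[1]][variable]
    if ga.dropna().empty or gb.dropna().empty:
        raise ValueError(f"variable {variable!r} is all-missing in one group")

    if kind == "categorical":
        contingency = pd.crosstab(table[group_col], table[variable])
        chi2, p, dof, _ = stats.chi2_contingency(contingency.values, correction=False)
        return TestResult(
            "chi-square", float(chi2), float(p), df=float(dof),
            group_summaries={
                str(g): contingency.loc[g].to_dict() for g in contingency.index
            },
        )
    if kind != "continuous":
        raise ValueError("kind must be 'continuous' or 'categorical'")

    xa = ga.dropna().to_numpy(dtype=float)
    xb = gb.dropna().to_numpy(dtype=float)
    norm_a, *_ = normality_gate(xa, alpha_normality)
    norm_b, *_ = normality_gate(xb, alpha_normality)
    if norm_a and norm_b:
        equal_var = t_variant == "pooled"
        t, p = stats.ttest_ind(xa, xb, equal_var=equal_var)
        if equal_var:
            df = xa.size + xb.size - 2.0
            name = "t-pooled"
        else:
            df = _welch_df(xa.var(ddof=1), xa.size, xb.var(ddof=1), xb.size)
            name = "t-welch"
        style = "mean±sd"
        result = TestResult(name, float(t), float(p), df=df, summary_style=style)
    else:
        method = "exact" if max(xa.size, xb.size) <= 12 else "asymptotic"
        try:
            u, p = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
        except ValueError:  # exact method refuses ties
            u, p = stats.mannwhitneyu(xa, xb, alternative="two-sided", method="asymptotic")
        style = "median[Q1–Q3]"
        result = TestResult("mann-whitney", float(u), float(p), summary_style=style)
    result.group_summaries = {
        str(groups[0]): _summaries(xa, style),
        str(groups[1]): _summaries(xb, style),
    }
    return result


def _welch_df(v1: float, n1: int, v2: float, n2: int) -> float:
    a, b = v1 / n1, v2 / n2
    return (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))


def ttest_from_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variant: str = "pooled",
) -> TestResult:
    """Independent-samples t-test from printed group summaries.

    ``variant="pooled"`` assumes equal variances (df = n1 + n2 - 2);
    ``variant="welch"`` uses the Welch-Satterthwaite approximation.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    equal_var = variant == "pooled"
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var)
    if equal_var:
        df = float(n1 + n2 - 2)
    else:
        df = _welch_df(sd1**2, n1, sd2**2, n2)
    return TestResult(f"t-{variant}", float(t), float(p), df=df, summary_style="mean±sd")


def pct_change(mean_case: float, mean_control: float) -> int:
    """Relative difference of group means, rounded to the nearest percent."""
    if mean_control == 0:
        raise ValueError("control mean must be non-zero")
    return int(round(100.0 * (mean_case - mean_control) / mean_control))


# ---------------------------------------------------------------------------
# correlation and regression
# ---------------------------------------------------------------------------


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with its two-sided t-distributed p-value."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size < 3 or ya.size != xa.size:
        raise ValueError("need equal-length samples with n >= 3")
    if np.var(xa) == 0 or np.var(ya) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(xa, ya)
    return float(r), float(p)


@dataclass
class RegressionResult:
    f_statistic: float
    df_model: int
    df_resid: int
    r_squared: float
    p_value: float
    coefficients: np.ndarray  # intercept first
    bse: np.ndarray

    def format_f(self) -> str:
        """'F (k, n-k-1) = ..., p = ..., R^2 = ...' reporting string."""
        return (
            f"F ({self.df_model}, {self.df_resid}) = {self.f_statistic:.3f}, "
            f"p = {self.p_value:.3f}, R² = {self.r_squared:.3f}"
        )


def regression_fit(response: Sequence[float], covariates) -> RegressionResult:
    """Ordinary least squares with intercept; overall F-test and R^2.

    Raises on rank-deficient designs, naming the collinear columns.
    """
    y = np.asarray(response, dtype=float)
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[0] != y.size:
            X = X.T
        names = [f"x{i}" for i in range(X.shape[1])]
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        bad = [
            names[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(Xc, j + 1, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    fit = sm.OLS(y, Xc).fit()
    if np.allclose(np.var(y), 0.0):
        fstat, pval, r2 = 0.0, 1.0, 0.0
    else:
        fstat, pval, r2 = float(fit.fvalue), float(fit.f_pvalue), float(fit.rsquared)
    return RegressionResult(
        f_statistic=fstat,
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        r_squared=r2,
        p_value=pval,
        coefficients=np.asarray(fit.params),
        bse=np.asarray(fit.bse),
    )


# ---------------------------------------------------------------------------
# propensity matching
# ---------------------------------------------------------------------------


@dataclass
class MatchResult:
    matched: pd.DataFrame
    n_matched: int
    caliper_logit: float
    smd_before: dict
    smd_after: dict
    pairs: list[tuple]  # (treated index, control index)


def _smd(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized mean difference with the pooled-variance denominator."""
    denom = np.sqrt((np.var(a, ddof=1) + np.var(b, ddof=1)) / 2.0)
    if denom == 0:
        return 0.0
    return float((np.mean(a) - np.mean(b)) / denom)


def propensity_match(
    table: pd.DataFrame,
    covariates: Sequence[str],
    caliper_sd_logit: float = 0.2,
    rng_seed: int = 0,
    group_col: str = "group",
    treated_value: Optional[str] = None,
) -> MatchResult:
    """1:1 nearest-neighbour propensity matching without replacement.

    A logistic regression of group membership on the covariates yields the
    propensity logit; treated subjects, visited in seed-randomized order,
    each claim the nearest unclaimed comparison subject within a caliper of
    ``caliper_sd_logit`` x SD(logit) (0.2 by convention). Returns the
    matched subset and standardized mean differences before and after.
    """
    groups = sorted(table[group_col].unique())
    if len(groups) != 2:
        raise ValueError("need exactly two groups")
    if treated_value is None:
        treated_value = groups[0] if (table[group_col] == groups[0]).sum() >= (
            table[group_col] == groups[1]
        ).sum() else groups[1]
    data = table.dropna(subset=list(covariates)).reset_index(drop=True)
    y = (data[group_col] == treated_value).to_numpy(dtype=float)
    X = data[list(covariates)].to_numpy(dtype=float)
    varying = X.std(axis=0) > 0  # constant covariates carry no information
    if varying.any():
        Xv = X[:, varying]
        Xs = (Xv - Xv.mean(axis=0)) / Xv.std(axis=0)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, sm.add_constant(Xs)).fit(disp=0, maxiter=200)
            logit = np.asarray(sm.add_constant(Xs) @ fit.params)
        except Exception:  # perfect separation and friends
            logit = np.where(y == 1, 50.0, -50.0)
        logit = np.clip(logit, -50.0, 50.0)
    else:
        logit = np.zeros(y.size)

    sd = float(np.std(logit, ddof=1))
    caliper = caliper_sd_logit * sd
    t_idx = np.nonzero(y == 1)[0]
    c_idx = np.nonzero(y == 0)[0]
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(t_idx)
    available = set(c_idx.tolist())
    pairs: list[tuple] = []
    for ti in order:
        if not available:
            break
        cand = np.fromiter(available, dtype=np.int64)
        d = np.abs(logit[cand] - logit[ti])
        j = int(np.argmin(d))
        if d[j] <= caliper:
            pairs.append((int(ti), int(cand[j])))
            available.remove(int(cand[j]))

    covs = list(covariates)
    smd_before = {
        c: _smd(X[y == 1][:, k], X[y == 0][:, k]) for k, c in enumerate(covs)
    }
    if pairs:
        ti = [p[0] for p in pairs]
        ci = [p[1] for p in pairs]
        matched = data.loc[ti + ci].reset_index(drop=True)
        smd_after = {
            c: _smd(
                data.loc[ti, c].to_numpy(dtype=float),
                data.loc[ci, c].to_numpy(dtype=float),
            )
            for c in covs
        }
    else:
        matched = data.iloc[0:0]
        smd_after = {c: float("nan") for c in covs}
    return MatchResult(
        matched=matched,
        n_matched=len(pairs),
        caliper_logit=caliper,
        smd_before=smd_before,
        smd_after=smd_after,
        pairs=pairs,
    )
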