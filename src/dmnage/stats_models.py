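"""Group-level inference for connectivity outcomes.

Implements the diagnosis-by-age interaction regression (OLS with sex,
education, site dummies and head motion as covariates), within-group
age--outcome correlations with the Fisher r-to-z test for comparing
correlations between independent groups, partial correlations for clinical
associations, a two-level ANCOVA, a Spearman heteroscedasticity diagnostic
with log-refit, and the summary-statistic tests (pooled two-sample t,
2x2 chi-square) used for cohort demographics.

Coding conventions, fixed and reported in outputs: diagnosis MDD = 0,
HC = 1; sex male = 0, female = 1; the site dummy reference level is the
lexicographically first site id. Standardized coefficients follow the
beta_std_j = b_j * SD(x_j) / SD(y) convention for every non-intercept term,
dummies included. All tests are two-tailed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

__all__ = [
    "RegressionResult",
    "CorrelationComparison",
    "HeteroscedasticityCheck",
    "fit_interaction_model",
    "group_age_correlation",
    "compare_independent_correlations",
    "heteroscedasticity_check",
    "log_transform_refit",
    "partial_correlation",
    "ancova_binary",
    "pooled_t_from_summary",
    "chi_square_2x2",
]

DIAGNOSIS_CODE = {"MDD": 0.0, "HC": 1.0}
SEX_CODE = {"male": 0.0, "female": 1.0}


@dataclass
class RegressionResult:
    """Fitted OLS interaction model for one outcome."""

    outcome_name: str
    terms: list[str]
    b: np.ndarray
    beta_std: np.ndarray  # NaN for the intercept
    t: np.ndarray
    p: np.ndarray
    residuals: np.ndarray
    n: int
    log_transformed: bool = False

    def coef(self, term: str) -> float:
        return float(self.b[self.terms.index(term)])

    def tstat(self, term: str) -> float:
        return float(self.t[self.terms.index(term)])

    def pvalue(self, term: str) -> float:
        return float(self.p[self.terms.index(term)])

    def beta(self, term: str) -> float:
        return float(self.beta_std[self.terms.index(term)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"term": self.terms, "b": self.b, "beta_std": self.beta_std,
             "t": self.t, "p": self.p}
        )


@dataclass(frozen=True)
class CorrelationComparison:
    r1: float
    n1: int
    r2: float
    n2: int
    z: float
    p: float


@dataclass(frozen=True)
class HeteroscedasticityCheck:
    rho: float
    p: float


def _design_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Build the interaction design: intercept, diagnosis, age,
    diagnosis x centered age, sex, education, site dummies, mean_fd."""
    required = ["diagnosis", "age", "sex", "education", "site", "mean_fd"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"metrics table lacks model columns: {missing}")
    sub = table[required]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(f"missing values in model columns: {bad}")
    dx = table["diagnosis"].map(DIAGNOSIS_CODE)
    if dx.isna().any():
        raise ValueError("diagnosis must be 'MDD' or 'HC'")
    sex = table["sex"].map(SEX_CODE)
    if sex.isna().any():
        raise ValueError("sex must be 'male' or 'female'")
    age = table["age"].astype(float)
    x = pd.DataFrame(index=table.index)
    x["intercept"] = 1.0
    x["diagnosis"] = dx.astype(float)
    x["age"] = age
    x["diagnosis_x_age"] = dx.astype(float) * (age - age.mean())
    x["sex"] = sex.astype(float)
    x["education"] = table["education"].astype(float)
    sites = sorted(table["site"].astype(str).unique())
    for s in sites[1:]:  # first site is the reference level
        x[f"site[{s}]"] = (table["site"].astype(str) == s).astype(float)
    x["mean_fd"] = table["mean_fd"].astype(float)
    return x, list(x.columns)


def _collinear_columns(x: pd.DataFrame) -> list[str]:
    """Names of the columns past the numerical rank under pivoted QR."""
    from scipy.linalg import qr

    mat = x.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank >= mat.shape[1]:
        return []
    _, r, piv = qr(mat, pivoting=True, mode="economic")
    return [x.columns[i] for i in sorted(piv[rank:])]


def fit_interaction_model(table: pd.DataFrame, outcome: str) -> RegressionResult:
    """OLS fit of outcome ~ diagnosis + age + diagnosis x age + covariates.

    The interaction regressor is diagnosis times mean-centered age; with both
    main effects in the model the interaction t and p do not depend on that
    centering choice. Standardized betas use the b * SD(x) / SD(y) convention.

    Raises
    ------
    ValueError : missing model columns/values, rank deficiency (the error
        names the collinear columns), or n <= number of terms.
    """
    if outcome not in table.columns:
        raise ValueError(f"outcome column {outcome!r} not in table")
    y = table[outcome].astype(float)
    if y.isna().any():
        raise ValueError(f"missing values in outcome {outcome!r}")
    x, terms = _design_matrix(table)
    if len(y) <= len(terms):
        raise ValueError(f"n={len(y)} too small for {len(terms)} model terms")
    bad = _collinear_columns(x)
    if bad:
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    fit = sm.OLS(y.to_numpy(), x.to_numpy()).fit()
    sd_y = float(np.std(y, ddof=1))
    beta_std = np.full(len(terms), np.nan)
    for j, term in enumerate(terms):
        if term == "intercept":
            continue
        beta_std[j] = fit.params[j] * float(np.std(x[term], ddof=1)) / sd_y
    return RegressionResult(
        outcome_name=outcome,
        terms=terms,
        b=np.asarray(fit.params),
        beta_std=beta_std,
        t=np.asarray(fit.tvalues),
        p=np.asarray(fit.pvalues),
        residuals=np.asarray(fit.resid),
        n=int(fit.nobs),
    )


def group_age_correlation(table: pd.DataFrame, outcome: str, group: str) -> float:
    """Pearson r between age and the outcome within one diagnostic group."""
    sub = table[table["diagnosis"] == group]
    if len(sub) < 4:
        raise ValueError(f"need >= 4 subjects in group {group!r}, have {len(sub)}")
    age = sub["age"].astype(float).to_numpy()
    y = sub[outcome].astype(float).to_numpy()
    if np.std(age) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in age or outcome within group")
    return float(st.pearsonr(age, y).statistic)


def compare_independent_correlations(
    r1: float, n1: int, r2: float, n2: int
) -> CorrelationComparison:
    """Fisher r-to-z test for two correlations from independent samples.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), two-tailed
    normal p.
    """
    if not (abs(r1) < 1 and abs(r2) < 1):
        raise ValueError("|r| must be < 1")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("each sample size must exceed 3")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * st.norm.sf(abs(z))
    return CorrelationComparison(r1=r1, n1=n1, r2=r2, n2=n2, z=float(z), p=float(p))


def heteroscedasticity_check(
    result: RegressionResult, moderator: Sequence[float]
) -> HeteroscedasticityCheck:
    """Spearman rank correlation between a moderator and absolute residuals."""
    mod = np.asarray(moderator, dtype=float)
    if mod.shape[0] != result.residuals.shape[0]:
        raise ValueError("moderator length must match residuals")
    if np.unique(mod).size < 2:
        raise ValueError("moderator must take at least 2 distinct values")
    abs_res = np.abs(result.residuals)
    if np.unique(abs_res).size < 2:
        raise ValueError("constant |residuals|: rank correlation undefined")
    rho, p = st.spearmanr(mod, abs_res)
    return HeteroscedasticityCheck(rho=float(rho), p=float(p))


def log_transform_refit(table: pd.DataFrame, outcome: str) -> RegressionResult:
    """Refit the interaction model on the natural log of the outcome.

    Requires strictly positive outcome values; no silent shifting is applied.
    """
    y = table[outcome].astype(float)
    if (y <= 0).any():
        raise ValueError(
            f"log transform undefined: outcome {outcome!r} has values <= 0 "
            "(no shift is applied)"
        )
    work = table.copy()
    log_name = f"log_{outcome}"
    work[log_name] = np.log(y)
    res = fit_interaction_model(work, log_name)
    res.outcome_name = outcome
    res.log_transformed = True
    return res


def partial_correlation(
    x: Sequence[float], y: Sequence[float], covariates: Optional[np.ndarray] = None
) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given covariate columns.

    Both variables are residualized on the covariates plus an intercept by
    OLS; r is the Pearson correlation of the residuals and p comes from the
    t distribution with df = n - 2 - k.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        k = 0
        rx, ry = x - x.mean(), y - y.mean()
    else:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        k = c.shape[1]
        design = np.column_stack([np.ones(n), c])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("rank-deficient covariate matrix")
        coef_x, *_ = np.linalg.lstsq(design, x, rcond=None)
        coef_y, *_ = np.linalg.lstsq(design, y, rcond=None)
        rx = x - design @ coef_x
        ry = y - design @ coef_y
    if n <= k + 3:
        raise ValueError(f"need n > k + 3 (n={n}, k={k})")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    r_ = min(max(r, -1 + 1e-15), 1 - 1e-15)
    tval = r_ * np.sqrt(df / (1.0 - r_ * r_))
    p = float(2.0 * st.t.sf(abs(tval), df))
    return r, p


def ancova_binary(
    table: pd.DataFrame, outcome: str, factor: str, covariates: Sequence[str]
) -> tuple[float, float]:
    """ANCOVA for a two-level factor: F = t^2 of the factor term in OLS.

    Categorical covariates (e.g. site, sex, diagnosis) are dummy-coded with
    the lexicographically first level as reference.
    """
    levels = sorted(table[factor].dropna().astype(str).unique())
    if len(levels) != 2:
        raise ValueError(f"factor {factor!r} must have exactly 2 levels, found {levels}")
    sub = table.dropna(subset=[outcome, factor]).copy()
    y = sub[outcome].astype(float).to_numpy()
    cols = {"intercept": np.ones(len(sub))}
    cols[factor] = (sub[factor].astype(str) == levels[1]).astype(float).to_numpy()
    for c in covariates:
        vals = sub[c]
        if vals.dtype == object or str(vals.dtype) in ("category", "string"):
            lv = sorted(vals.astype(str).unique())
            for l in lv[1:]:
                cols[f"{c}[{l}]"] = (vals.astype(str) == l).astype(float).to_numpy()
        else:
            cols[c] = vals.astype(float).to_numpy()
    xmat = np.column_stack(list(cols.values()))
    fit = sm.OLS(y, xmat).fit()
    j = list(cols).index(factor)
    tval = float(fit.tvalues[j])
    return tval * tval, float(fit.pvalues[j])


def pooled_t_from_summary(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> tuple[float, int, float]:
    """Pooled-variance two-sample t test from group summary statistics."""
    if sd1 < 0 or sd2 < 0 or n1 < 2 or n2 < 2:
        raise ValueError("need sd >= 0 and n >= 2 in each group")
    if sd1 == 0 and sd2 == 0 and m1 == m2:
        raise ValueError("undefined t: both SDs zero with equal means")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = float(2.0 * st.t.sf(abs(t), df))
    return float(t), df, p


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (df = 1, no continuity correction) for a 2x2 table."""
    tab = np.array([[a, b], [c, d]])
    if np.any(tab < 0) or tab.sum(axis=0).min() == 0 or tab.sum(axis=1).min() == 0:
        raise ValueError("counts must be non-negative with all margins > 0")
    chi2, p, _, _ = st.chi2_contingency(tab, correction=False)
    return float(chi2), float(p)
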