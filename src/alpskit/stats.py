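"""Cohort statistics: classification, ANCOVA, effect sizes, standardized
regression, Mann-Whitney U and WMH transforms.

Models are solved directly via least squares (numpy) with classical
t-distribution inference; standardized betas come from z-scoring the outcome
and every continuous regressor (binary 0/1 regressors are left as coded).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    CollinearityWarning,
    DataValidationError,
    InsufficientDesignError,
)

__all__ = [
    "GroupDiffResult",
    "RegressionResult",
    "classify_subjects",
    "ancova_group",
    "cohens_d",
    "cohens_d_from_summary",
    "linreg_standardized",
    "mann_whitney_u",
    "log_transform_wmh",
    "dichotomize",
]

VALID_CDR = (0.0, 0.5, 1.0, 2.0, 3.0)


def classify_subjects(
    table: pd.DataFrame,
    cutoff: float,
    cdr_col: str = "cdr_global",
    ratio_col: str = "abeta_ratio",
) -> pd.Series:
    """AD iff CDR >= 0.5 and amyloid ratio <= cutoff (inclusive, amyloid
    positive); HC iff CDR = 0 and ratio > cutoff; anything else unclassified
    (pd.NA).  Missing ratios are reconstructed from abeta42/abeta40 when
    possible; rows still missing data stay unclassified.
    """
    cdr = table[cdr_col]
    ratio = table[ratio_col].copy() if ratio_col in table else pd.Series(np.nan, index=table.index)
    if {"abeta42", "abeta40"}.issubset(table.columns):
        fallback = table["abeta42"] / table["abeta40"]
        ratio = ratio.fillna(fallback)

    labels = pd.Series(pd.NA, index=table.index, dtype="object")
    ok = cdr.notna() & ratio.notna()
    labels[ok & (cdr >= 0.5) & (ratio <= cutoff)] = "AD"
    labels[ok & (cdr == 0) & (ratio > cutoff)] = "HC"
    return labels


def cohens_d(x, y) -> float:
    """Pooled-SD Cohen's d, (mean_x - mean_y) / s_pooled, (n-1)-weighted."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDesignError("each group needs n >= 2")
    return cohens_d_from_summary(
        x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
    )


def cohens_d_from_summary(m1, s1, n1, m2, s2, n2) -> float:
    """Cohen's d from group summary statistics (means, SDs, sizes)."""
    pooled_var = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    if pooled_var <= 0:
        raise DataValidationError("pooled SD is zero; d undefined")
    return float((m1 - m2) / math.sqrt(pooled_var))


def _ols(X: np.ndarray, y: np.ndarray):
    """Least squares with classical covariance; returns (beta, se, t, p, dof, r2)."""
    n, p = X.shape
    if n <= p:
        raise InsufficientDesignError(f"n={n} too small for {p} parameters")
    if np.linalg.matrix_rank(X) < p:
        raise InsufficientDesignError("design matrix is rank deficient")
    if np.linalg.cond(X) > 1e8:
        warnings.warn("design matrix is ill-conditioned", CollinearityWarning)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - p
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pvals = 2 * sps.t.sf(np.abs(t), dof)
    tss = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - (resid @ resid) / tss if tss > 0 else 1.0
    return beta, se, t, pvals, dof, r2


@dataclass
class GroupDiffResult:
    """Covariate-adjusted group difference plus raw descriptives."""

    mean_ad: float
    sd_ad: float
    n_ad: int
    mean_hc: float
    sd_hc: float
    n_hc: int
    coef: float  # adjusted AD-vs-HC coefficient
    t: float
    p: float
    cohens_d: float  # raw (unadjusted), AD minus HC


def ancova_group(
    table: pd.DataFrame,
    outcome: str,
    covariates=("age", "sex"),
    group_col: str = "group",
    ad_label: str = "AD",
    hc_label: str = "HC",
) -> GroupDiffResult:
    """Linear model ``outcome ~ group + covariates`` with a two-sided t test
    on the group (AD vs HC) coefficient; Cohen's d is computed on the raw
    group values, matching the convention of reporting raw means +/- SD.
    """
    cols = [outcome, group_col, *covariates]
    df = table[cols].dropna()
    df = df[df[group_col].isin([ad_label, hc_label])]
    x_ad = df.loc[df[group_col] == ad_label, outcome].to_numpy(float)
    x_hc = df.loc[df[group_col] == hc_label, outcome].to_numpy(float)
    if len(x_ad) < 2 or len(x_hc) < 2:
        raise InsufficientDesignError("each group needs n >= 2 after listwise deletion")

    y = df[outcome].to_numpy(float)
    g = (df[group_col] == ad_label).to_numpy(float)
    X = np.column_stack([np.ones(len(df)), g] + [df[c].to_numpy(float) for c in covariates])
    beta, se, t, p, _, _ = _ols(X, y)
    return GroupDiffResult(
        mean_ad=float(x_ad.mean()),
        sd_ad=float(x_ad.std(ddof=1)),
        n_ad=len(x_ad),
        mean_hc=float(x_hc.mean()),
        sd_hc=float(x_hc.std(ddof=1)),
        n_hc=len(x_hc),
        coef=float(beta[1]),
        t=float(t[1]),
        p=float(p[1]),
        cohens_d=cohens_d(x_ad, x_hc),
    )


@dataclass
class RegressionResult:
    beta: float  # standardized coefficient of the predictor of interest
    se: float
    adj_r2: float
    p: float
    n: int


def _is_binary(v: np.ndarray) -> bool:
    u = np.unique(v[~np.isnan(v)])
    return len(u) <= 2 and set(u).issubset({0.0, 1.0})


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise DataValidationError("cannot z-score a constant column")
    return (v - v.mean()) / sd


def linreg_standardized(
    table: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates=(),
) -> RegressionResult:
    """Multiple linear regression with standardized outcome/predictor.

    Continuous variables are z-scored; binary 0/1 regressors enter as coded.
    Reports beta, SE and p for the predictor of interest and the model's
    adjusted R-squared with the n actually used (listwise deletion).
    """
    cols = [outcome, predictor, *covariates]
    df = table[cols].dropna()
    n = len(df)
    if n <= len(cols):  # fewer rows than parameters: hopeless before z-scoring
        raise InsufficientDesignError(f"n={n} too small for {len(cols)} model columns")
    arrays = {}
    for c in cols:
        v = df[c].to_numpy(float)
        arrays[c] = v if (c != outcome and _is_binary(v)) else _zscore(v)
    y = arrays[outcome]
    X = np.column_stack([np.ones(n)] + [arrays[c] for c in cols[1:]])
    beta, se, t, p, dof, r2 = _ols(X, y)
    n_params = X.shape[1] - 1  # regressors excluding the intercept
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)
    return RegressionResult(beta=float(beta[1]), se=float(se[1]), adj_r2=float(adj_r2), p=float(p[1]), n=n)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U (for ``x``) with midrank ties.

    Two-sided p is exact (full enumeration of labelings) for tie-free samples
    with n_x + n_y <= 12; otherwise a normal approximation with tie and
    continuity corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise DataValidationError("both samples must be non-empty")
    nx, ny = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    u = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)

    has_ties = len(np.unique(combined)) < nx + ny
    if nx + ny <= 12 and not has_ties:
        # enumerate every assignment of nx ranks out of nx+ny
        all_ranks = np.arange(1, nx + ny + 1)
        min_sum = nx * (nx + 1) / 2.0
        us = np.array(
            [sum(c) - min_sum for c in itertools.combinations(all_ranks, nx)]
        )
        total = len(us)
        p_low = np.count_nonzero(us <= u) / total
        p_high = np.count_nonzero(us >= u) / total
        p = min(1.0, 2.0 * min(p_low, p_high))
        return u, float(p)

    mean_u = nx * ny / 2.0
    n = nx + ny
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var_u = nx * ny / 12.0 * (n + 1 - tie_term)
    if var_u <= 0:
        return u, 1.0
    z = (u - mean_u - math.copysign(0.5, u - mean_u)) / math.sqrt(var_u) if u != mean_u else 0.0
    return u, float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def log_transform_wmh(volumes_mm3) -> np.ndarray:
    """log10(v + 1); rejects negative volumes."""
    v = np.asarray(volumes_mm3, dtype=float)
    if np.any(v < 0):
        raise DataValidationError("WMH volumes must be non-negative")
    return np.log10(v + 1.0)


DICHOTOMY_RULES = {
    # printed boundary handling: MMSE >= 27 is "high"; CDR > 0 is "high"
    "mmse27": lambda v: np.where(v >= 27, "high", "low"),
    "cdr0": lambda v: np.where(v > 0, "high", "low"),
}


def dichotomize(table: pd.DataFrame, variable: str, rule: str) -> pd.Series:
    """Label rows high/low according to a named clinical split rule."""
    if rule not in DICHOTOMY_RULES:
        raise DataValidationError(f"unknown dichotomy rule {rule!r}; known: {sorted(DICHOTOMY_RULES)}")
    if variable not in table:
        raise DataValidationError(f"variable {variable!r} not in table")
    return pd.Series(DICHOTOMY_RULES[rule](table[variable].to_numpy(float)), index=table.index)
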