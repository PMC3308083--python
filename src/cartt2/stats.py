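"""Covariate-adjusted group comparisons for cohort tables.

Linear models for continuous T2 parameters, logistic models for lesion
prevalence, partial correlations for ordinal-vs-continuous associations, a
standardized group difference, and the demographic Pearson chi-square.

Sign conventions (documented because they are easy to get backwards):

* ``adjusted_group_difference`` reports the *control minus incidence*
  coefficient (incidence is the reference level), so an elevated incidence
  group yields a negative coefficient — matching the reporting convention of
  the comparison tables this mirrors.
* ``logistic_prevalence_or`` reports the odds ratio of the *incidence* group
  relative to control (control is the reference level).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .exceptions import DegenerateDataError, InputError

__all__ = [
    "ComparisonResult",
    "OddsRatioResult",
    "adjusted_group_difference",
    "logistic_prevalence_or",
    "partial_correlation",
    "standardized_difference",
    "chi_square_2x2",
]

_DEFAULT_COVARIATES = ("age", "sex", "bmi")


@dataclass
class ComparisonResult:
    outcome: str
    coefficient: float          # control minus incidence (adjusted)
    ci_low: float
    ci_high: float
    p_adjusted: float
    p_unadjusted: float
    mean_incidence: float
    sd_incidence: float
    mean_control: float
    sd_control: float


@dataclass
class OddsRatioResult:
    outcome: str
    odds_ratio: float           # incidence vs control
    ci_low: float
    ci_high: float
    p_value: float


def _design(table: pd.DataFrame, covariates: Sequence[str],
            group_col: str, reference: str) -> pd.DataFrame:
    X = pd.DataFrame(index=table.index)
    X["group_ind"] = (table[group_col] != reference).astype(float)
    for cov in covariates:
        if cov == "sex":
            X["sex_female"] = (table["sex"].astype(str).str.upper() == "F").astype(float)
        else:
            X[cov] = pd.to_numeric(table[cov])
    return sm.add_constant(X, has_constant="add")


def _check_groups(table: pd.DataFrame, group_col: str) -> None:
    groups = set(table[group_col].unique())
    if not {"incidence", "control"} <= groups:
        raise InputError(f"both groups must be present, found {sorted(groups)}")


def adjusted_group_difference(table: pd.DataFrame, outcome: str,
                              covariates: Sequence[str] = _DEFAULT_COVARIATES,
                              group_col: str = "group") -> ComparisonResult:
    """OLS ``outcome ~ group + covariates`` with Wald 95% CI on the group term.

    The group coefficient is control minus incidence (incidence elevated →
    negative). Also fits the unadjusted two-group model for ``p_unadjusted``.
    """
    data = table.dropna(subset=[outcome, group_col, *covariates])
    _check_groups(data, group_col)
    if len(data) < len(covariates) + 3:
        raise InputError("too few complete rows for the adjusted model")
    y = pd.to_numeric(data[outcome])
    X = _design(data, covariates, group_col, reference="incidence")
    rank = np.linalg.matrix_rank(X.values)
    if rank < X.shape[1]:
        # identify an offending column by dropping one at a time
        for col in X.columns:
            if col == "const":
                continue
            if np.linalg.matrix_rank(X.drop(columns=col).values) == rank:
                raise DegenerateDataError(f"singular design matrix (column '{col}')")
        raise DegenerateDataError("singular design matrix")
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int().loc["group_ind"]
    fit0 = sm.OLS(y, _design(data, (), group_col, "incidence")).fit()
    inc = y[data[group_col] == "incidence"]
    ctl = y[data[group_col] == "control"]
    return ComparisonResult(
        outcome=outcome,
        coefficient=float(fit.params["group_ind"]),
        ci_low=float(ci[0]), ci_high=float(ci[1]),
        p_adjusted=float(fit.pvalues["group_ind"]),
        p_unadjusted=float(fit0.pvalues["group_ind"]),
        mean_incidence=float(inc.mean()), sd_incidence=float(inc.std(ddof=1)),
        mean_control=float(ctl.mean()), sd_control=float(ctl.std(ddof=1)),
    )


def logistic_prevalence_or(table: pd.DataFrame, indicator: str,
                           covariates: Sequence[str] = (),
                           group_col: str = "group") -> OddsRatioResult:
    """Logistic ``indicator ~ group + covariates``; Wald CI on exp(group coef).

    Reports the incidence-vs-control odds ratio. With no covariates this
    reduces to the 2x2 cross-product ratio.
    """
    data = table.dropna(subset=[indicator, group_col, *covariates])
    _check_groups(data, group_col)
    y = data[indicator].astype(float)
    if y.nunique() < 2:
        raise DegenerateDataError("lesion indicator takes a single value")
    X = _design(data, covariates, group_col, reference="control")
    try:
        fit = sm.Logit(y, X).fit(disp=0)
    except Exception as exc:  # perfect separation raises inside statsmodels
        raise DegenerateDataError(f"logistic fit failed: {exc}") from exc
    if not np.isfinite(fit.bse["group_ind"]):
        raise DegenerateDataError("separation: group coefficient unbounded")
    coef = float(fit.params["group_ind"])
    ci = fit.conf_int().loc["group_ind"]
    return OddsRatioResult(
        outcome=indicator,
        odds_ratio=float(np.exp(coef)),
        ci_low=float(np.exp(ci[0])), ci_high=float(np.exp(ci[1])),
        p_value=float(fit.pvalues["group_ind"]),
    )


def partial_correlation(table: pd.DataFrame, x: str, y: str,
                        covariates: Sequence[str] = _DEFAULT_COVARIATES,
                        group_col: str | None = "group") -> tuple[float, float]:
    """Correlation of OLS residuals of x and y on the covariates; two-sided p.

    When ``group_col`` is given, group membership is included among the
    controls (pooled-cohort analyses control for group).
    """
    cols = [x, y, *covariates] + ([group_col] if group_col else [])
    data = table.dropna(subset=cols)
    if len(data) < len(covariates) + 3:
        raise InputError("too few complete rows for partial correlation")
    if group_col:
        _check_groups(data, group_col)
        X = _design(data, covariates, group_col, reference="control")
    else:
        X = _design(data.assign(_g="control"), covariates, "_g", reference="control")
        X = X.drop(columns="group_ind")
    rx = sm.OLS(pd.to_numeric(data[x]), X).fit().resid
    ry = sm.OLS(pd.to_numeric(data[y]), X).fit().resid
    if rx.std() == 0 or ry.std() == 0:
        raise DegenerateDataError("zero residual variance")
    r = float(np.corrcoef(rx, ry)[0, 1])
    k = X.shape[1] - 1  # controls (excluding intercept)
    dof = len(data) - 2 - k
    t = r * np.sqrt(dof / max(1e-300, 1.0 - r * r))
    p = float(2 * sps.t.sf(abs(t), dof))
    return r, p


def standardized_difference(mean_ig: float, mean_cg: float,
                            sd_ig: float, sd_cg: float) -> float:
    """Group difference in units of the average of the two group SDs."""
    if sd_ig <= 0 or sd_cg <= 0:
        raise InputError("group SDs must be > 0")
    return (mean_ig - mean_cg) / ((sd_ig + sd_cg) / 2.0)


def chi_square_2x2(counts) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) for a 2x2 table."""
    t = np.asarray(counts, dtype=float)
    if t.shape != (2, 2):
        raise InputError("counts must be a 2x2 table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DegenerateDataError("2x2 table has a zero margin")
    stat, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), float(p)
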