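"""Conventional inference: GLM treatment contrasts, BH-FDR, chi-squared.

GLMs are fitted with statsmodels (IRLS); the quasi-Poisson family is a
Poisson fit whose covariance is scaled by the Pearson dispersion estimate.
Pairwise contrasts are reported on the link scale as the effect of the
second level relative to the first (the R summary-coefficient convention:
a label "control_5pct - none" carries eta(none) - eta(control_5pct)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .errors import DegenerateGroupError, DesignError

FAMILIES = ("gaussian", "quasipoisson")


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


@dataclass
class ChiSquareResult:
    """Pearson chi-squared test of homogeneity on a contingency table."""

    chi2: float
    df: int
    p: float
    df_residual: int  # n - 1, logged for comparability with residual-df reports
    yates: bool


def chisq_mortality(table: Sequence[Sequence[float]], yates: bool = True) -> ChiSquareResult:
    """Chi-squared homogeneity test on a 2 x k count table.

    Yates' continuity correction is applied only to 2 x 2 tables (and only
    when requested). The conventional (r-1)(c-1) df is reported; the
    sample-size-based residual df (n - 1) is carried alongside.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("expected an r x k table with r, k >= 2")
    if np.any(counts < 0) or np.any(counts != np.floor(counts)):
        raise ValueError("counts must be nonnegative integers")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise DegenerateGroupError("table has an all-zero row or column")
    correction = yates and counts.shape == (2, 2)
    chi2, p, df, _ = scipy.stats.chi2_contingency(counts, correction=correction)
    return ChiSquareResult(
        chi2=float(chi2),
        df=int(df),
        p=float(p),
        df_residual=int(counts.sum()) - 1,
        yates=correction,
    )


@dataclass
class GLMContrastTable:
    """Pairwise treatment contrasts plus the omnibus treatment F-test."""

    table: pd.DataFrame  # contrast, estimate, se, t, p_raw, p_adj
    family: str
    response: str
    dispersion: float
    df_resid: int
    f_value: float
    f_df: tuple[int, int]
    f_p: float
    n: int


def _design_matrix(levels: pd.Series, ordered_levels: list[str]) -> np.ndarray:
    x = np.ones((len(levels), len(ordered_levels)))
    for j, lev in enumerate(ordered_levels[1:], start=1):
        x[:, j] = (levels == lev).to_numpy(dtype=float)
    return x


def fit_treatment_glm(
    data: pd.DataFrame,
    response: str,
    family: str,
    factor: str = "yeast",
    level_order: Sequence[str] | None = None,
    adjust: bool = True,
) -> GLMContrastTable:
    """One-factor GLM with all pairwise level contrasts on the link scale.

    ``family`` is ``"gaussian"`` (identity link) or ``"quasipoisson"``
    (log link, covariance scaled by the Pearson dispersion). Contrast rows
    are labelled ``"a - b"`` and carry eta(b) - eta(a); t statistics use the
    residual df and p-values are BH-adjusted within the table.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    df = data.dropna(subset=[response, factor]).copy()
    present = [
        lev
        for lev in (level_order or sorted(df[factor].unique()))
        if (df[factor] == lev).any()
    ]
    if len(present) < 2:
        raise DesignError(f"factor {factor!r} has fewer than 2 levels in this cell")
    y = df[response].to_numpy(dtype=float)
    if family == "quasipoisson":
        if np.any(y < 0):
            raise ValueError("quasi-Poisson responses must be nonnegative counts")
        if np.all(y == 0):
            raise DegenerateGroupError("all counts are zero")
    x = _design_matrix(df[factor], present)

    sm_family = (
        sm.families.Gaussian() if family == "gaussian" else sm.families.Poisson()
    )
    model = sm.GLM(y, x, family=sm_family)
    fit = model.fit(scale="X2")  # Pearson dispersion for both families
    if family == "quasipoisson":
        unscaled = model.fit()
        assert np.allclose(
            np.asarray(fit.bse), np.asarray(unscaled.bse) * np.sqrt(fit.scale)
        ), "quasi-Poisson SEs must be Poisson SEs scaled by sqrt(dispersion)"
    null_fit = sm.GLM(y, np.ones((len(y), 1)), family=sm_family).fit()
    dispersion = float(fit.scale)
    df_resid = int(fit.df_resid)

    cov = np.asarray(fit.cov_params())
    params = np.asarray(fit.params)
    rows = []
    for i in range(len(present)):
        for j in range(i + 1, len(present)):
            c = np.zeros(len(present))
            # eta(level_j) - eta(level_i); baseline level has coefficient 0
            if j > 0:
                c[j] += 1.0
            if i > 0:
                c[i] -= 1.0
            est = float(c @ params)
            se = float(np.sqrt(c @ cov @ c))
            t = est / se if se > 0 else np.nan
            p = 2.0 * scipy.stats.t.sf(abs(t), df_resid) if se > 0 else np.nan
            rows.append(
                {
                    "contrast": f"{present[i]} - {present[j]}",
                    "estimate": est,
                    "se": se,
                    "t": t,
                    "p_raw": p,
                }
            )
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p_raw"].to_numpy()) if adjust else table["p_raw"]

    df_num = len(present) - 1
    f_value = float(
        (null_fit.deviance - fit.deviance) / df_num / dispersion
    )
    f_p = float(scipy.stats.f.sf(f_value, df_num, df_resid))
    return GLMContrastTable(
        table=table,
        family=family,
        response=response,
        dispersion=dispersion,
        df_resid=df_resid,
        f_value=f_value,
        f_df=(df_num, df_resid),
        f_p=f_p,
        n=len(y),
    )


def fit_interaction_glm(
    data: pd.DataFrame,
    response: str,
    factor_a: str = "sex",
    factor_b: str = "yeast",
    family: str = "gaussian",
) -> pd.DataFrame:
    """Two-factor GLM with interaction; returns the full coefficient table.

    Used for the sex-by-treatment interaction on relativized body mass and
    analogous contrasts. Rows labelled ``"a:b"`` are interaction terms.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    df = data.dropna(subset=[response, factor_a, factor_b]).copy()
    levels_a = sorted(df[factor_a].unique())
    levels_b = sorted(df[factor_b].unique())
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise DesignError("both factors need >= 2 levels for an interaction model")
    cols: list[np.ndarray] = [np.ones(len(df))]
    names = ["intercept"]
    a_dummies = {lev: (df[factor_a] == lev).to_numpy(float) for lev in levels_a[1:]}
    b_dummies = {lev: (df[factor_b] == lev).to_numpy(float) for lev in levels_b[1:]}
    for lev, col in a_dummies.items():
        cols.append(col)
        names.append(str(lev))
    for lev, col in b_dummies.items():
        cols.append(col)
        names.append(str(lev))
    for la, ca in a_dummies.items():
        for lb, cb in b_dummies.items():
            cols.append(ca * cb)
            names.append(f"{la}:{lb}")
    x = np.column_stack(cols)
    y = df[response].to_numpy(dtype=float)
    sm_family = (
        sm.families.Gaussian() if family == "gaussian" else sm.families.Poisson()
    )
    fit = sm.GLM(y, x, family=sm_family).fit(scale="X2")
    params = np.asarray(fit.params)
    ses = np.asarray(fit.bse)
    t = params / ses
    p = 2.0 * scipy.stats.t.sf(np.abs(t), int(fit.df_resid))
    return pd.DataFrame(
        {
            "term": names,
            "estimate": params,
            "se": ses,
            "t": t,
            "p": p,
            "df_resid": int(fit.df_resid),
        }
    )
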