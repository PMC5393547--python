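"""Correlative layer: OLS regressions on lake means and the random-intercept
mixed model for chlorophyll vs nutrients.

All variables are natural-log transformed before fitting, matching the
field study's presentation of nutrient and biomass relationships. The mixed
model is fitted by maximum likelihood and the fixed slope is tested with a
likelihood-ratio chi-square (df = 1) against the intercept-only model; the
original report quotes "d.f. = 1,18" alongside its chi-square, which mixes
F-test and LRT bookkeeping — here the LRT df of 1 is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RegressionResult",
    "LmmResult",
    "fit_ols",
    "fit_lmm_random_intercept",
    "correlative_suite",
]


@dataclass(frozen=True)
class RegressionResult:
    """Simple linear regression with the F-test of the slope."""

    slope: float
    intercept: float
    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    r_squared: float


@dataclass(frozen=True)
class LmmResult:
    """Random-intercept mixed model: ML fit and slope likelihood-ratio test.

    ``flag`` is non-None when the fit is degenerate (e.g. the random-
    intercept variance collapsed to zero or the optimizer did not converge);
    the estimates are still returned.
    """

    fixed_slope: float
    chi2: float
    df: int
    p_value: float
    random_intercept_variance: float
    flag: Optional[str] = None


def fit_ols(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on x with the slope F-test, df (1, n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-d sequences, length >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; the slope is not estimable")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        f_stat=float(res.fvalue),
        df_num=1,
        df_den=int(res.df_resid),
        p_value=float(res.f_pvalue),
        r_squared=float(res.rsquared),
    )


def fit_lmm_random_intercept(
    y: Sequence[float], x: Sequence[float], lake_id: Sequence
) -> LmmResult:
    """ML random-intercept model of per-visit y on a per-lake covariate x.

    The chi-square is the likelihood-ratio statistic for dropping the fixed
    slope, keeping the lake random intercept in both models.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    groups = np.asarray(lake_id)
    if not (len(y) == len(x) == len(groups)):
        raise ValueError("y, x and lake_id must have equal length")
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least 2 lakes")

    flag = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.MixedLM(y, sm.add_constant(x), groups=groups).fit(reml=False)
        null = sm.MixedLM(y, np.ones((len(y), 1)), groups=groups).fit(reml=False)
    if not (full.converged and null.converged):
        flag = "optimizer did not converge"
    re_var = float(np.asarray(full.cov_re)[0, 0])
    if re_var < 1e-8:
        flag = flag or "random-intercept variance collapsed to zero (singular fit)"
    chi2 = max(0.0, 2.0 * (full.llf - null.llf))
    return LmmResult(
        fixed_slope=float(full.fe_params[1]),
        chi2=float(chi2),
        df=1,
        p_value=float(stats.chi2.sf(chi2, df=1)),
        random_intercept_variance=re_var,
        flag=flag,
    )


def correlative_suite(
    lakes: pd.DataFrame,
    series: pd.DataFrame,
    exclude_lakes: Sequence[str] = (),
) -> pd.DataFrame:
    """The standard battery of lake-survey relationships, one row per test.

    OLS on per-lake values: log nutrients (totN, totP, TOC) vs vegetation
    cover, and lake-mean log zooplankton vs lake-mean log chlorophyll.
    Mixed models on per-visit values: log chlorophyll vs log totP and vs
    log totN with a lake random intercept.
    """
    excl = {str(e) for e in exclude_lakes}
    lakes = lakes[~lakes["lake_id"].astype(str).isin(excl)].reset_index(drop=True)
    series = series[series["lake_id"].astype(str).isin(set(lakes["lake_id"].astype(str)))]

    veg = lakes["veg_cover"].to_numpy(dtype=float)
    rows = []
    for name, col in [
        ("log_totn~veg_cover", "tot_n"),
        ("log_totp~veg_cover", "tot_p"),
        ("log_toc~veg_cover", "toc"),
    ]:
        r = fit_ols(veg, np.log(lakes[col].to_numpy(dtype=float)))
        rows.append(
            {
                "test": name,
                "kind": "ols",
                "statistic": r.f_stat,
                "df": f"{r.df_num},{r.df_den}",
                "p_value": r.p_value,
                "estimate": r.slope,
                "r_squared": r.r_squared,
                "random_intercept_variance": np.nan,
                "flag": "",
            }
        )

    merged = series.merge(lakes[["lake_id", "tot_p", "tot_n"]], on="lake_id")
    for name, col in [("log_chla~log_totp", "tot_p"), ("log_chla~log_totn", "tot_n")]:
        r = fit_lmm_random_intercept(
            np.log(merged["chla_obs"].to_numpy(dtype=float)),
            np.log(merged[col].to_numpy(dtype=float)),
            merged["lake_id"].to_numpy(),
        )
        rows.append(
            {
                "test": name,
                "kind": "lmm_lrt",
                "statistic": r.chi2,
                "df": str(r.df),
                "p_value": r.p_value,
                "estimate": r.fixed_slope,
                "r_squared": np.nan,
                "random_intercept_variance": r.random_intercept_variance,
                "flag": r.flag or "",
            }
        )

    means = series.groupby("lake_id")[["chla_obs", "zoop_obs"]].mean()
    r = fit_ols(np.log(means["chla_obs"]), np.log(means["zoop_obs"]))
    rows.append(
        {
            "test": "log_zoop_mean~log_chla_mean",
            "kind": "ols",
            "statistic": r.f_stat,
            "df": f"{r.df_num},{r.df_den}",
            "p_value": r.p_value,
            "estimate": r.slope,
            "r_squared": r.r_squared,
            "random_intercept_variance": np.nan,
            "flag": "",
        }
    )
    return pd.DataFrame(rows)
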