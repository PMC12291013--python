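"""Drought impact, post-drought recovery, and flux-climate regressions.

Impact compares drought-window annual means of ET, ET/P, GPP, NEP, uWUE
and MI against the pre-drought average (disturbance years excluded).
Recovery pairs the first post-drought growing year with the pre-drought
year of most similar MI.  Flux-climate fits are ordinary least squares of
annual flux sums on a water-availability predictor, pooled across sites
and per site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger("fluxdrought")

IMPACT_VARIABLES = ("ET", "ET_over_P", "GPP", "NEP", "uWUE", "MI", "ER")


@dataclass
class PeriodComparison:
    """Pre-drought vs drought-window comparison for one variable."""

    site: str
    variable: str
    pre_mean: float
    drought_mean: float
    pct_change: float
    abs_change: float
    sign_change: bool


def _period_rows(gy_df: pd.DataFrame, years) -> pd.DataFrame:
    return gy_df.loc[[y for y in years if y in gy_df.index]]


def drought_impact(gy_df: pd.DataFrame, window, exclusions=(), site: str = "",
                   variables=IMPACT_VARIABLES) -> pd.DataFrame:
    """Per-variable pre-drought vs drought-window comparison.

    Parameters
    ----------
    gy_df : per-growing-year index table (see ``growing_year_indices``)
    window : (first, last) growing-year labels of the drought, inclusive
    exclusions : growing-year labels removed from the pre-drought baseline
        (fires and other disturbances)

    ``pct_change`` uses ``100·(drought − pre)/|pre|``; where the variable
    changes sign through zero the absolute change is the robust summary and
    ``sign_change`` is flagged.
    """
    first, last = int(window[0]), int(window[-1])
    drought_years = [y for y in gy_df.index if first <= y <= last]
    pre_years = [y for y in gy_df.index if y < first and y not in set(exclusions)]
    if len(pre_years) < 2:
        raise ValueError("need at least two pre-drought growing years after exclusions")
    if not drought_years:
        raise ValueError("drought window not covered by data")

    pre = _period_rows(gy_df, pre_years)
    dro = _period_rows(gy_df, drought_years)
    rows = []
    for var in variables:
        if var == "ET_over_P":
            pre_vals = pre["ET"] / pre["P"]
            dro_vals = dro["ET"] / dro["P"]
        else:
            if var not in gy_df.columns:
                continue
            pre_vals, dro_vals = pre[var], dro[var]
        p, d = float(pre_vals.mean()), float(dro_vals.mean())
        sign_change = (p > 0 > d) or (p < 0 < d)
        pct = 100.0 * (d - p) / abs(p) if p != 0 else np.nan
        rows.append(PeriodComparison(site, var, p, d, pct, d - p, sign_change))
    return pd.DataFrame([r.__dict__ for r in rows])


@dataclass
class AnalogueMatch:
    """Pre-drought growing year most similar in MI to a post-drought year."""

    site: str
    post_year: int
    matched_pre_year: int
    mi_distance: float


def match_analogue_year(post_year_mi: float, pre_years, site: str = "",
                        post_year: int = -1) -> AnalogueMatch:
    """Pick the pre-drought year minimising |ΔMI|; ties take the most recent."""
    pre_years = list(pre_years)
    if not pre_years:
        raise ValueError("need at least one pre-drought year")
    dist = [(abs(mi - post_year_mi), label) for label, mi in pre_years]
    best_d = min(d for d, _ in dist)
    tied = [lab for d, lab in dist if np.isclose(d, best_d)]
    if len(tied) > 1:
        logger.info("analogue-year MI tie among %s; using most recent", sorted(tied))
    return AnalogueMatch(site=site, post_year=int(post_year),
                         matched_pre_year=int(max(tied)), mi_distance=float(best_d))


def recovery_comparison(gy_df: pd.DataFrame, match: AnalogueMatch,
                        variables=("GPP", "ER", "NEP")) -> pd.DataFrame:
    """Paired post-drought vs analogue-year fluxes and their ratios."""
    for y in (match.post_year, match.matched_pre_year):
        if y not in gy_df.index:
            raise ValueError(f"growing year {y} missing from index table")
    rows = []
    for var in variables:
        if var not in gy_df.columns:
            continue
        post = float(gy_df.loc[match.post_year, var])
        ana = float(gy_df.loc[match.matched_pre_year, var])
        ratio = post / ana if ana != 0 else np.nan
        rows.append({"site": match.site, "variable": var, "post": post,
                     "analogue": ana, "ratio": ratio,
                     "post_year": match.post_year,
                     "analogue_year": match.matched_pre_year})
    return pd.DataFrame(rows)


@dataclass
class FluxClimateFit:
    """OLS fit of an annual flux sum on a water-availability predictor."""

    predictor: str
    response: str
    scope: str  # "pooled" or site id
    slope: float
    intercept: float
    r_squared: float
    n: int
    slope_se: float = np.nan
    pvalue: float = np.nan
    results: object = field(default=None, repr=False, compare=False)

    def summary(self) -> str:
        return (f"{self.response} ~ {self.predictor} [{self.scope}]: "
                f"slope={self.slope:.4g} (se {self.slope_se:.3g}), "
                f"intercept={self.intercept:.4g}, R²={self.r_squared:.3f}, n={self.n}")


def _ols(x: np.ndarray, y: np.ndarray, predictor: str, response: str,
         scope: str) -> FluxClimateFit:
    if np.ptp(x) == 0:
        return FluxClimateFit(predictor, response, scope, np.nan, np.nan,
                              np.nan, len(x))
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    return FluxClimateFit(predictor, response, scope,
                          slope=float(res.params[1]), intercept=float(res.params[0]),
                          r_squared=float(res.rsquared), n=int(res.nobs),
                          slope_se=float(res.bse[1]), pvalue=float(res.pvalues[1]),
                          results=res)


def fit_flux_climate(annual: pd.DataFrame, predictor: str, response: str,
                     scope: str = "pooled", min_years: int = 3) -> list[FluxClimateFit]:
    """Regress annual flux sums on a climate index.

    Parameters
    ----------
    annual : DataFrame with columns ``site``, the predictor and the response,
        one row per site-growing-year.
    scope : {"pooled", "per_site", "both"}

    Returns a list of :class:`FluxClimateFit` (pooled first when "both");
    per-site fits with fewer than ``min_years`` years are omitted.
    """
    sub = annual[["site", predictor, response]].dropna()
    fits = []
    if scope in ("pooled", "both"):
        if len(sub) < min_years:
            raise ValueError("need at least three site-years for a pooled fit")
        fits.append(_ols(sub[predictor].to_numpy(), sub[response].to_numpy(),
                         predictor, response, "pooled"))
    if scope in ("per_site", "both"):
        for site, grp in sub.groupby("site"):
            if len(grp) < min_years:
                logger.info("site %s: only %d years, per-site fit omitted", site, len(grp))
                continue
            fits.append(_ols(grp[predictor].to_numpy(), grp[response].to_numpy(),
                             predictor, response, str(site)))
    return fits
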