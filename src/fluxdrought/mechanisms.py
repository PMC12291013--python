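"""Temporal diagnostics: moving averages, Z-scores, lag correlations,
and diurnal flux centroids.

The lag machinery attributes drought-driven productivity loss to leaf
shedding versus stomatal closure by cross-correlating smoothed moisture
index anomalies against GPP and LAI anomalies: the lag of the correlation
peak measures how quickly each response follows the climate driver.

The diurnal-centroid machinery detects non-stomatal photosynthetic
limitation: under pure stomatal control, demand-adjusted transpiration
(ET/VPD^0.5) and GPP shift together through the day, so a drought-period
shift of the ET/VPD^0.5 centroid relative to the GPP centroid signals a
decoupling of water loss from carbon gain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("fluxdrought")

#: austral calendar seasons, keyed by month
SEASON_OF_MONTH = {12: "DJF", 1: "DJF", 2: "DJF", 3: "MAM", 4: "MAM", 5: "MAM",
                   6: "JJA", 7: "JJA", 8: "JJA", 9: "SON", 10: "SON", 11: "SON"}
SEASONS = ("DJF", "MAM", "JJA", "SON")


def moving_average(values, window: int, centered: bool = True) -> pd.Series:
    """Arithmetic moving average with masked (NaN) incomplete edge windows.

    Output has the same length/index as the input; centred windows span
    ±⌊window/2⌋ around each point.
    """
    s = pd.Series(values)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(s):
        raise ValueError(f"window {window} exceeds series length {len(s)}")
    return s.rolling(window, center=centered, min_periods=window).mean()


def monthly_zscore(series: pd.Series, baseline: tuple | None = None) -> pd.Series:
    """Standardise a monthly series against a baseline interval.

    ``baseline`` is an inclusive (start, end) pair of timestamps; by default
    the whole series is the baseline.  The baseline must contain at least
    12 non-missing months and have nonzero variance.
    """
    s = pd.Series(series, dtype=float)
    if baseline is not None:
        start, end = pd.Timestamp(baseline[0]), pd.Timestamp(baseline[1])
        base = s.loc[(s.index >= start) & (s.index <= end)]
    else:
        base = s
    base = base.dropna()
    if len(base) < 12:
        raise ValueError("baseline must contain at least 12 months")
    mu, sd = base.mean(), base.std(ddof=1)
    if sd == 0 or np.isnan(sd):
        raise ValueError("baseline has zero variance")
    return (s - mu) / sd


@dataclass
class LagCorrelation:
    """Peak cross-correlation between a driver and a lagged response."""

    driver: str
    response: str
    peak_r: float
    lag: int  # months; positive = response follows the driver
    analysis_window: tuple
    r_by_lag: pd.Series = field(default=None, repr=False, compare=False)

    @property
    def physiologically_meaningful(self) -> bool:
        """Negative lags (response leading its driver) are flagged spurious."""
        return self.lag >= 0


def cross_correlation_lag(driver: pd.Series, response: pd.Series,
                          max_lag: int = 12, window: tuple | None = None,
                          driver_name: str = "MI", response_name: str = "response"
                          ) -> LagCorrelation:
    """Pearson correlation at each integer lag in [−max_lag, +max_lag].

    Positive lag means the response trails the driver by that many steps.
    Both series are standardised over the analysis window before
    correlating.  Returns the lag of the strongest |r|; ties prefer the
    smaller |lag| (logged).
    """
    d = pd.Series(driver, dtype=float)
    r = pd.Series(response, dtype=float)
    if window is not None:
        start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
        d = d.loc[(d.index >= start) & (d.index <= end)]
        r = r.loc[(r.index >= start) & (r.index <= end)]
    joined = pd.concat({"d": d, "r": r}, axis=1).dropna()
    if len(joined) < max_lag + 6:
        raise ValueError(
            f"need at least max_lag+6={max_lag + 6} overlapping steps, got {len(joined)}")
    dz = (joined["d"] - joined["d"].mean()) / joined["d"].std(ddof=1)
    rz = (joined["r"] - joined["r"].mean()) / joined["r"].std(ddof=1)

    lags = np.arange(-max_lag, max_lag + 1)
    rs = {}
    dv, rv = dz.to_numpy(), rz.to_numpy()
    n = len(dv)
    for lag in lags:
        if lag >= 0:
            a, b = dv[: n - lag] if lag else dv, rv[lag:]
        else:
            a, b = dv[-lag:], rv[: n + lag]
        if len(a) < 3 or np.std(a) == 0 or np.std(b) == 0:
            rs[lag] = np.nan
            continue
        rs[lag] = float(np.corrcoef(a, b)[0, 1])
    table = pd.Series(rs)
    best_abs = table.abs().max()
    tied = table.index[np.isclose(table.abs(), best_abs)]
    peak_lag = int(min(tied, key=lambda l: (abs(l), l)))
    if len(tied) > 1:
        logger.info("lag tie among %s; using %d", list(tied), peak_lag)
    win = (joined.index.min(), joined.index.max())
    return LagCorrelation(driver_name, response_name, float(table.loc[peak_lag]),
                          peak_lag, win, table)


def lag_attribution(mi: pd.Series, response: pd.Series, baseline: tuple,
                    window: tuple, max_lag: int = 12, smooth_months: int = 12,
                    response_name: str = "GPP") -> LagCorrelation:
    """Z-score → centred 12-month moving average → windowed cross-correlation.

    This is the full attribution chain applied to monthly MI against GPP or
    LAI; ``baseline`` scales the Z-scores, ``window`` bounds the transition
    period over which correlations are formed.
    """
    mi_z = monthly_zscore(mi, baseline)
    resp_z = monthly_zscore(response, baseline)
    mi_s = moving_average(mi_z, smooth_months, centered=True)
    resp_s = moving_average(resp_z, smooth_months, centered=True)
    return cross_correlation_lag(mi_s, resp_s, max_lag=max_lag, window=window,
                                 driver_name="MI", response_name=response_name)


def diurnal_centroid(values, hours=None, daytime=(6.0, 18.0),
                     min_steps: int = 6) -> float:
    """Flux-weighted mean time of day (decimal hours) for one day of data.

    ``values`` is one day of half-hourly fluxes; ``hours`` the step-midpoint
    local times (defaults to a full 48-step day).  Negative fluxes are
    floored at zero; days with fewer than ``min_steps`` valid daytime steps
    or non-positive total flux return NaN (skipped).
    """
    v = np.asarray(values, dtype=float)
    if hours is None:
        if len(v) != 48:
            raise ValueError("hours must be given unless values has 48 half-hour steps")
        hours = np.arange(48) * 0.5 + 0.25
    hours = np.asarray(hours, dtype=float)
    day = (hours >= daytime[0]) & (hours < daytime[1])
    valid = day & ~np.isnan(v)
    if valid.sum() < min_steps:
        return np.nan
    w = np.maximum(v[valid], 0.0)
    total = w.sum()
    if total <= 0:
        return np.nan
    return float(np.sum(hours[valid] * w) / total)


def _daily_centroids(df: pd.DataFrame, col: str, daytime) -> pd.Series:
    """Per-day centroid series for one column of a half-hourly frame."""
    hours = df.index.hour + df.index.minute / 60.0 + 0.25
    sub = pd.DataFrame({"v": df[col].to_numpy(), "h": hours}, index=df.index)
    out = {}
    for day, grp in sub.groupby(sub.index.floor("D")):
        out[day] = diurnal_centroid(grp["v"].to_numpy(), grp["h"].to_numpy(), daytime)
    return pd.Series(out)


def centroid_divergence(halfhourly, drought_window: tuple,
                        daytime: tuple = (6.0, 18.0), min_days: int = 20,
                        seasons=SEASONS) -> pd.DataFrame:
    """Seasonal divergence of demand-adjusted-ET vs GPP diurnal timing.

    For each season and period (pre-drought vs drought), computes the mean
    daily centroid of ET/VPD^0.5 and of GPP, then::

        divergence = (ET_c − GPP_c)_drought − (ET_c − GPP_c)_pre

    Negative divergence means ET shifted earlier in the day relative to
    GPP during the drought — the non-stomatal-limitation signal.  Seasons
    with fewer than ``min_days`` valid days in either period are NaN.
    """
    data = getattr(halfhourly, "data", halfhourly)
    for col in ("ET", "VPD", "GPP"):
        if col not in data.columns:
            raise ValueError(f"half-hourly series lacks {col}")
    start, end = pd.Timestamp(drought_window[0]), pd.Timestamp(drought_window[1])

    vpd = data["VPD"].where(data["VPD"] > 0)  # mask non-positive VPD steps
    work = pd.DataFrame({
        "ETd": data["ET"] / np.sqrt(vpd),
        "GPP": data["GPP"],
    }, index=data.index)

    et_c = _daily_centroids(work, "ETd", daytime)
    gpp_c = _daily_centroids(work, "GPP", daytime)
    days = et_c.index
    period = pd.Series(np.where(days < start, "pre",
                       np.where(days <= end, "drought", "post")), index=days)
    season = pd.Series([SEASON_OF_MONTH[m] for m in days.month], index=days)

    rows = []
    for ssn in seasons:
        row = {"season": ssn}
        ok = True
        for per in ("pre", "drought"):
            sel = (season == ssn) & (period == per)
            ec, gc = et_c[sel].dropna(), gpp_c[sel].dropna()
            both = ec.index.intersection(gc.index)
            row[f"n_days_{per}"] = len(both)
            if len(both) < min_days:
                ok = False
                row[f"et_centroid_{per}"] = np.nan
                row[f"gpp_centroid_{per}"] = np.nan
            else:
                row[f"et_centroid_{per}"] = float(ec[both].mean())
                row[f"gpp_centroid_{per}"] = float(gc[both].mean())
        if ok:
            row["divergence_h"] = ((row["et_centroid_drought"] - row["gpp_centroid_drought"])
                                   - (row["et_centroid_pre"] - row["gpp_centroid_pre"]))
        else:
            row["divergence_h"] = np.nan
            logger.info("season %s: fewer than %d valid days in a period", ssn, min_days)
        rows.append(row)
    return pd.DataFrame(rows).set_index("season")
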