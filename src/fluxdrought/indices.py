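"""Water-availability indices, growing-year machinery, and drought severity.

The three indices, computed over a growing year of monthly records:

* ``X_i = P_i − PET_i`` — monthly available water (mm),
* ``WAI = Σ X_i`` — water availability index, the net annual balance,
* ``MWDI = Σ_{X_i<0} X_i`` — monthly water deficit index, exposure to
  periodic dry conditions; always ≤ 0 and ≤ WAI,
* ``MI = ΣP / ΣPET`` — moisture index over period totals.

A growing year starts in the month of lowest mean NEP so that growing
seasons are not split across annual boundaries; if that month falls before
July the growing year keeps the same calendar-year label, otherwise it is
labelled with the following calendar year (a year starting October 2017 is
growing year 2018).

Drought severity is classed from the relative MI decline between a
pre-drought baseline and the drought window: ≤ −30 % severe, in
(−30, −10] % moderate, otherwise none.  Boundaries are inclusive toward
the more severe class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("fluxdrought")

SEVERE_THRESHOLD_PCT = -30.0
MODERATE_THRESHOLD_PCT = -10.0


def available_water(P, PET):
    """Monthly available water X = P − PET (mm).  Inputs must be ≥ 0."""
    P = np.asarray(P, dtype=float)
    PET = np.asarray(PET, dtype=float)
    if np.any(P < 0) or np.any(PET < 0):
        raise ValueError("P and PET must be non-negative")
    return P - PET


def wai(x, allow_partial: bool = False, min_months: int = 12):
    """Water availability index: sum of monthly X over one growing year."""
    x = np.asarray(x, dtype=float)
    valid = ~np.isnan(x)
    if not allow_partial and (len(x) != 12 or not valid.all()):
        raise ValueError("wai requires the 12 complete months of one growing year")
    if allow_partial and valid.sum() < min_months:
        return np.nan
    return float(np.nansum(x))


def mwdi(x, allow_partial: bool = False, min_months: int = 12):
    """Monthly water deficit index: sum of the negative monthly X only (≤ 0)."""
    x = np.asarray(x, dtype=float)
    valid = ~np.isnan(x)
    if not allow_partial and (len(x) != 12 or not valid.all()):
        raise ValueError("mwdi requires the 12 complete months of one growing year")
    if allow_partial and valid.sum() < min_months:
        return np.nan
    return float(np.nansum(np.where(x < 0, x, 0.0)))


def moisture_index(P_total, PET_total):
    """Moisture index MI = P/PET over period totals (dimensionless)."""
    P_total = np.asarray(P_total, dtype=float)
    PET_total = np.asarray(PET_total, dtype=float)
    if np.any(PET_total <= 0):
        raise ValueError("MI undefined for PET_total <= 0")
    return P_total / PET_total


def uwue(GPP, VPD, ET):
    """Underlying water use efficiency, GPP·VPD^0.5/ET (gC kPa^0.5 mm⁻¹).

    ET = 0 yields NaN (masked, not an error) so series-level use can carry on.
    """
    GPP = np.asarray(GPP, dtype=float)
    VPD = np.asarray(VPD, dtype=float)
    ET = np.asarray(ET, dtype=float)
    if np.any(VPD < 0):
        raise ValueError("VPD must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = GPP * np.sqrt(VPD) / ET
    return np.where(ET > 0, out, np.nan)


@dataclass(frozen=True)
class GrowingYearSpec:
    """Start month of the growing year and how annual labels are assigned."""

    start_month: int
    tie: bool = False

    def __post_init__(self):
        if not 1 <= self.start_month <= 12:
            raise ValueError("start_month must be in 1..12")


def growing_year_label(timestamp, start_month: int) -> int:
    """Calendar-year label of the growing year containing ``timestamp``.

    Start months January–June label the growing year with the calendar year
    it starts in; July–December label it with the following calendar year.
    """
    ts = pd.Timestamp(timestamp)
    if start_month <= 6:
        return ts.year if ts.month >= start_month else ts.year - 1
    return ts.year + 1 if ts.month >= start_month else ts.year


def growing_year_span(label: int, start_month: int) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Half-open [start, end) span of the labelled growing year."""
    start_year = label if start_month <= 6 else label - 1
    start = pd.Timestamp(year=start_year, month=start_month, day=1)
    return start, start + pd.DateOffset(months=12)


def define_growing_year(monthly_nep_climatology) -> GrowingYearSpec:
    """Growing-year start = month (1..12) of minimum mean NEP; earliest on ties."""
    clim = np.asarray(monthly_nep_climatology, dtype=float)
    if len(clim) != 12:
        raise ValueError("need 12 monthly NEP means")
    if np.isnan(clim).all():
        raise ValueError("all-missing NEP climatology")
    lowest = np.nanmin(clim)
    minima = np.flatnonzero(np.isclose(clim, lowest, equal_nan=False))
    tie = len(minima) > 1
    start = int(minima[0]) + 1
    if tie:
        logger.info("growing-year start tie among months %s; using %d",
                    [int(m) + 1 for m in minima], start)
    return GrowingYearSpec(start_month=start, tie=tie)


@dataclass
class DroughtAssessment:
    """Severity classification of a drought window relative to baseline MI."""

    site: str
    drought_window: tuple
    mi_pre: float
    mi_drought: float
    delta_mi_pct: float
    severity: str
    delta_p_pct: float = np.nan


def classify_delta_mi(delta_mi_pct: float) -> str:
    """Map a relative MI change (%) to a severity class."""
    if delta_mi_pct <= SEVERE_THRESHOLD_PCT:
        return "severe"
    if delta_mi_pct <= MODERATE_THRESHOLD_PCT:
        return "moderate"
    return "none"


def classify_drought(mi_pre: float, mi_drought: float, site: str = "",
                     drought_window: tuple = (), delta_p_pct: float = np.nan
                     ) -> DroughtAssessment:
    """Classify drought severity from baseline and drought-window MI."""
    if mi_pre <= 0:
        raise ValueError("pre-drought MI must be positive")
    delta = 100.0 * (mi_drought - mi_pre) / mi_pre
    return DroughtAssessment(site=site, drought_window=tuple(drought_window),
                             mi_pre=mi_pre, mi_drought=mi_drought,
                             delta_mi_pct=delta, severity=classify_delta_mi(delta),
                             delta_p_pct=delta_p_pct)


def growing_year_indices(monthly, gy_spec: GrowingYearSpec,
                         uwue_timescale: str = "annual") -> pd.DataFrame:
    """Per-growing-year index table from a monthly series.

    Parameters
    ----------
    monthly : FluxTimeSeries or DataFrame
        Monthly resolution with at least P and PET; flux columns optional.
    gy_spec : GrowingYearSpec
    uwue_timescale : {"annual", "monthly"}
        ``annual``: uWUE from growing-year GPP and ET sums with mean VPD;
        ``monthly``: monthly uWUE averaged over the growing year.

    Returns
    -------
    DataFrame indexed by growing-year label with columns P, PET, MI, WAI,
    MWDI and (where inputs exist) GPP, NEP, ER, ET, VPD, uWUE.
    Only complete (12-month, fully observed P and PET) growing years appear.
    """
    data = getattr(monthly, "data", monthly)
    if not {"P", "PET"}.issubset(data.columns):
        raise ValueError("monthly table must provide P and PET")
    labels = np.array([growing_year_label(ts, gy_spec.start_month) for ts in data.index])
    rows = {}
    for lab, sub in pd.DataFrame(data).groupby(labels):
        if len(sub) != 12 or sub["P"].isna().any() or sub["PET"].isna().any():
            continue
        x = available_water(sub["P"].to_numpy(), sub["PET"].to_numpy())
        row = {
            "P": sub["P"].sum(),
            "PET": sub["PET"].sum(),
            "MI": moisture_index(sub["P"].sum(), sub["PET"].sum()),
            "WAI": wai(x),
            "MWDI": mwdi(x),
        }
        for col in ("GPP", "NEP", "ER", "ET"):
            if col in sub:
                row[col] = sub[col].sum(min_count=12)
        if "VPD" in sub:
            row["VPD"] = sub["VPD"].mean()
        if {"GPP", "ET", "VPD"}.issubset(sub.columns):
            if uwue_timescale == "annual":
                row["uWUE"] = float(uwue(row.get("GPP", np.nan), sub["VPD"].mean(),
                                         row.get("ET", np.nan)))
            else:
                row["uWUE"] = float(np.nanmean(uwue(sub["GPP"], sub["VPD"], sub["ET"])))
        rows[int(lab)] = row
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = "growing_year"
    return out


def window_mi(gy_df: pd.DataFrame, years) -> float:
    """MI over a set of growing years, from period totals ΣP/ΣPET."""
    sub = gy_df.loc[[y for y in years if y in gy_df.index]]
    if sub.empty:
        raise ValueError(f"no growing years {list(years)} in index table")
    return float(moisture_index(sub["P"].sum(), sub["PET"].sum()))


def select_drought_window(gy_df: pd.DataFrame, candidate_windows) -> tuple:
    """Choose the candidate window with the most negative relative MI change.

    The baseline is every growing year before the earliest candidate year.
    Ties pick the earlier window.  Each candidate must be fully covered.
    """
    candidates = [tuple(int(y) for y in w) for w in candidate_windows]
    if len(candidates) < 2:
        raise ValueError("need at least two candidate windows")
    for w in candidates:
        years = list(range(w[0], w[-1] + 1))
        if not all(y in gy_df.index for y in years):
            raise ValueError(f"candidate window {w} not fully covered by data")
    first = min(w[0] for w in candidates)
    baseline_years = [y for y in gy_df.index if y < first]
    if not baseline_years:
        raise ValueError("no pre-candidate baseline years available")
    mi_pre = window_mi(gy_df, baseline_years)

    deltas = []
    for w in sorted(candidates):
        mi_w = window_mi(gy_df, range(w[0], w[-1] + 1))
        deltas.append((100.0 * (mi_w - mi_pre) / mi_pre, w))
    best = min(deltas, key=lambda t: t[0])
    tied = [w for d, w in deltas if np.isclose(d, best[0])]
    if len(tied) > 1:
        logger.info("drought-window tie among %s; using earliest %s", tied, tied[0])
        return tied[0]
    return best[1]
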