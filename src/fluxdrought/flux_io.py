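"""Reading, validating, excluding, and aggregating flux/met tables.

Input tables are delimited text with a header row.  A column map renames
file columns to canonical fields and a unit map declares the input units;
everything is converted to the canonical unit system at ingest (carbon
gC m⁻² step⁻¹, water mm step⁻¹, VPD kPa, Rn MJ m⁻² step⁻¹).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import yaml

from .containers import (
    CORE_FLUX_FIELDS,
    EXTENSIVE_FIELDS,
    FLUX_FIELDS,
    INTENSIVE_FIELDS,
    FluxTimeSeries,
    FormatError,
    SiteMeta,
    ValidationError,
)
from .indices import GrowingYearSpec, growing_year_label

logger = logging.getLogger("fluxdrought")

#: latent heat of vaporisation, MJ kg⁻¹ (FAO standard value)
LAMBDA_MJ_PER_KG = 2.45

#: grams of carbon per mole of CO2-C
GC_PER_UMOL = 12.011e-6

_RESOLUTION_SECONDS = {"halfhourly": 1800.0, "daily": 86400.0}


def _step_seconds(index: pd.DatetimeIndex, resolution: str) -> np.ndarray:
    if resolution in _RESOLUTION_SECONDS:
        return np.full(len(index), _RESOLUTION_SECONDS[resolution])
    if resolution == "monthly":
        return index.days_in_month.to_numpy(dtype=float) * 86400.0
    raise FormatError(f"rate units cannot be converted at {resolution} resolution")


def _convert(values: pd.Series, field: str, unit: str, index: pd.DatetimeIndex,
             resolution: str) -> pd.Series:
    """Convert ``values`` of ``field`` declared in ``unit`` to canonical units."""
    unit = unit.strip()
    if unit == "canonical":
        return values
    canonical = {
        "ET": {"mm"}, "P": {"mm"}, "PET": {"mm"},
        "NEP": {"gC/m2"}, "GPP": {"gC/m2"}, "ER": {"gC/m2"},
        "VPD": {"kPa"}, "Ta": {"degC", "C"}, "RH": {"%", "percent"},
        "u": {"m/s"}, "Rn": {"MJ/m2"}, "LAI": {"m2/m2"},
    }
    if unit in canonical.get(field, {unit}):
        return values
    if field in {"ET", "P", "PET"}:
        if unit in {"W/m2", "Wm-2"}:  # mean latent-heat flux over the step
            sec = _step_seconds(index, resolution)
            return values * sec * 1e-6 / LAMBDA_MJ_PER_KG
        if unit in {"MJ/m2", "MJm-2"}:
            return values / LAMBDA_MJ_PER_KG
    if field in {"NEP", "GPP", "ER"} and unit in {"umol/m2/s", "umolm-2s-1"}:
        sec = _step_seconds(index, resolution)
        return values * sec * GC_PER_UMOL
    if field == "VPD" and unit == "hPa":
        return values / 10.0
    if field == "RH" and unit in {"frac", "fraction"}:
        return values * 100.0
    if field == "Rn" and unit in {"W/m2", "Wm-2"}:
        sec = _step_seconds(index, resolution)
        return values * sec * 1e-6
    raise FormatError(f"no conversion from {unit!r} to canonical units for {field}")


def load_column_config(path) -> dict:
    """Load a YAML ingest config with keys ``column_map``, ``units``, ``resolution``."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if "column_map" not in cfg:
        raise FormatError("ingest config must define 'column_map'")
    cfg.setdefault("units", {})
    return cfg


def read_flux_table(path, column_map: dict, resolution: str, units: dict | None = None,
                    site_id: str = "site", sep: str = ",") -> FluxTimeSeries:
    """Read a delimited flux/met table into a validated :class:`FluxTimeSeries`.

    Parameters
    ----------
    column_map : dict
        Maps file column names to canonical field names; must include a
        mapping onto ``"timestamp"`` and at least one flux field.
    units : dict, optional
        Maps canonical field names to the unit the file holds them in;
        unlisted fields are assumed already canonical.
    """
    units = units or {}
    inverse = {v: k for k, v in column_map.items()}
    if "timestamp" not in inverse:
        raise FormatError("column_map must map a file column onto 'timestamp'")
    if not any(f in inverse for f in CORE_FLUX_FIELDS + ["P", "VPD"]):
        raise FormatError("column_map must cover at least one flux field")

    raw = pd.read_csv(path, sep=sep)
    missing_cols = set(column_map) - set(raw.columns)
    if missing_cols:
        raise FormatError(f"file lacks mapped columns: {sorted(missing_cols)}")

    ts = pd.to_datetime(raw[inverse["timestamp"]])
    if ts.isna().any():
        raise FormatError("unparseable timestamps present")
    index = pd.DatetimeIndex(ts.values)
    if len(index) > 1 and (np.diff(index.asi8) <= 0).any():
        bad = int(np.argmax(np.diff(index.asi8) <= 0)) + 1
        raise ValidationError(f"non-monotonic timestamp at row {bad} ({index[bad]})")

    data = pd.DataFrame(index=index, columns=FLUX_FIELDS, dtype=float)
    for field in FLUX_FIELDS + ["PET"]:
        if field in inverse:
            col = pd.to_numeric(raw[inverse[field]], errors="coerce")
            col.index = index
            data[field] = _convert(col, field, units.get(field, "canonical"), index, resolution)
    return FluxTimeSeries(site_id, resolution, data)


def write_flux_table(series: FluxTimeSeries, path, sep: str = ",") -> None:
    """Write the canonical CSV: ISO-8601 timestamps, fixed field names,
    and one ``<field>_missing`` sidecar mask column per field."""
    out = series.data.copy()
    for col in list(out.columns):
        out[f"{col}_missing"] = out[col].isna().astype(int)
    out.index.name = "timestamp"
    out.to_csv(path, sep=sep, float_format="%.10g")


def _merge_windows(windows):
    """Merge overlapping/touching (start, end) windows."""
    if not windows:
        return []
    ordered = sorted((pd.Timestamp(s), pd.Timestamp(e)) for s, e, *_ in windows)
    merged = [list(ordered[0])]
    for s, e in ordered[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(w) for w in merged]


def apply_exclusions(series: FluxTimeSeries, meta: SiteMeta) -> FluxTimeSeries:
    """Blank carbon/water flux fields inside the site's disturbance windows.

    Record count is unchanged; overlapping windows are merged.  Idempotent.
    """
    out = series.copy()
    merged = _merge_windows(meta.exclusion_windows)
    n_masked = 0
    for start, end in merged:
        if series.resolution == "growing_year":
            sel = (out.data.index >= start.year) & (out.data.index <= end.year)
        else:
            sel = (out.data.index >= start) & (out.data.index <= end)
        cols = [c for c in CORE_FLUX_FIELDS if c in out.data.columns]
        out.data.loc[sel, cols] = np.nan
        n_masked += int(sel.sum())
    if merged:
        logger.info("site %s: masked %d records over %d exclusion window(s)",
                    meta.site_id, n_masked, len(merged))
    return out


_COARSENESS = {"halfhourly": 0, "daily": 1, "monthly": 2, "growing_year": 3}


def _period_labels(index: pd.DatetimeIndex, target: str, gy_spec: GrowingYearSpec | None):
    if target == "daily":
        return index.floor("D")
    if target == "monthly":
        return index.to_period("M").to_timestamp()
    if target == "growing_year":
        if gy_spec is None:
            raise ValidationError("growing_year aggregation requires gy_spec")
        return np.array([growing_year_label(ts, gy_spec.start_month) for ts in index])
    raise ValidationError(f"cannot aggregate to {target!r}")


def _expected_steps(target: str, labels, resolution: str) -> pd.Series:
    """Total number of source steps each aggregate period should contain."""
    uniq = pd.Index(labels).unique()
    if target == "daily":
        n = 48.0
        return pd.Series(n, index=uniq)
    if target == "monthly":
        days = pd.DatetimeIndex(uniq).days_in_month.to_numpy(dtype=float)
        n = days * (48.0 if resolution == "halfhourly" else 1.0)
        return pd.Series(n, index=uniq)
    # growing_year: 365/366 days or 12 months
    out = {}
    for lab in uniq:
        if resolution == "monthly":
            out[lab] = 12.0
        else:
            # number of days in that growing year is label-dependent; use the
            # actual span of calendar days covered by the label
            out[lab] = np.nan  # filled by caller from calendar arithmetic
    return pd.Series(out)


def aggregate(series: FluxTimeSeries, target: str,
              gy_spec: GrowingYearSpec | None = None,
              min_coverage: float = 0.8) -> FluxTimeSeries:
    """Aggregate to a coarser resolution.

    Extensive fields (NEP, GPP, ER, ET, P, Rn, PET) are summed, intensive
    fields (VPD, Ta, RH, u, LAI) averaged.  An aggregate whose fraction of
    non-missing source steps falls below ``min_coverage`` is marked missing.
    For ``growing_year``, only complete growing years (full calendar
    coverage of the 12-month window) are emitted.
    """
    if _COARSENESS.get(target, -1) <= _COARSENESS[series.resolution]:
        raise ValidationError(f"target {target!r} not coarser than {series.resolution!r}")

    labels = _period_labels(series.data.index, target, gy_spec)
    grouped = series.data.groupby(labels)

    sums = grouped.sum(min_count=1)
    means = grouped.mean()
    counts = grouped.count()

    out = pd.DataFrame(index=sums.index, columns=series.data.columns, dtype=float)
    for col in series.data.columns:
        out[col] = sums[col] if col in EXTENSIVE_FIELDS else means[col]

    # coverage relative to the full period, not just observed rows
    if target == "growing_year":
        spans = {}
        for lab in out.index:
            start = pd.Timestamp(year=int(lab) if gy_spec.start_month < 7 else int(lab) - 1,
                                 month=gy_spec.start_month, day=1)
            end = start + pd.DateOffset(months=12)
            if series.resolution == "monthly":
                spans[lab] = 12.0
            else:
                ndays = (end - start).days
                spans[lab] = ndays * (48.0 if series.resolution == "halfhourly" else 1.0)
            # drop growing years not fully inside the record span
            if start < series.data.index.min().normalize() or \
               end > series.data.index.max() + _span_step(series.resolution):
                spans[lab] = np.inf
        expected = pd.Series(spans)
    else:
        expected = _expected_steps(target, labels, series.resolution)

    coverage = counts.div(expected, axis=0)
    out = out.where(coverage >= min_coverage)
    if target == "growing_year":
        keep = ~out.isna().all(axis=1)
        out = out.loc[keep]
        out.index = out.index.astype(int)
        if out.empty:
            logger.warning("site %s: no complete growing year in record", series.site_id)
    return FluxTimeSeries(series.site_id, target, out, validate=False)


def _span_step(resolution: str) -> pd.Timedelta:
    return {"halfhourly": pd.Timedelta(minutes=30),
            "daily": pd.Timedelta(days=1),
            "monthly": pd.Timedelta(days=31)}[resolution]
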