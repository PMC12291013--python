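"""Study orchestration: one config, per-site analyses, pooled regressions.

``run_study`` sequences, for every site: ingest (file or synthetic
scenario) → disturbance exclusions → PET (computed when absent) → monthly
and growing-year aggregation → water indices → drought window selection
and severity classification → impact and recovery comparisons → temporal
diagnostics (smoothed MI / ET-PET / NEP series and MI→GPP/LAI lag
attribution); afterwards it pools all site-years into flux-climate
regressions.  All outputs are tidy CSVs plus a JSON manifest carrying the
config hash and seed, so a run can be reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import FluxTimeSeries, SiteMeta
from .flux_io import aggregate, apply_exclusions, read_flux_table
from .indices import (
    DroughtAssessment,
    GrowingYearSpec,
    classify_drought,
    define_growing_year,
    growing_year_indices,
    growing_year_span,
    select_drought_window,
    window_mi,
)
from .mechanisms import lag_attribution, moving_average
from .pet import penman_pet, windfree_pet
from .response import drought_impact, fit_flux_climate, match_analogue_year, recovery_comparison
from .synthetic import SiteScenario, generate_site, scenario_from_preset

logger = logging.getLogger("fluxdrought")

REGRESSION_PREDICTORS = ("P", "MI", "WAI", "MWDI")


@dataclass
class StudyConfig:
    """Everything a study run needs, loadable from one YAML file."""

    sites: list = field(default_factory=list)
    output_dir: str = "fluxdrought_out"
    seed: int = 0
    min_coverage: float = 0.8
    candidate_windows: list = field(default_factory=lambda: [(2018, 2019), (2019, 2020)])
    max_lag: int = 12
    uwue_timescale: str = "annual"
    zscore_baseline: tuple | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for entry in cfg.sites:
            if "path" in entry and not Path(entry["path"]).exists():
                raise FileNotFoundError(f"site input missing: {entry['path']}")
        return cfg

    def canonical_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["candidate_windows"] = [list(map(int, w)) for w in self.candidate_windows]
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _ingest_site(entry: dict, config: StudyConfig, index: int) -> tuple[FluxTimeSeries, SiteMeta, dict]:
    """Return (monthly series with PET, meta, ground truth or {})."""
    site_id = entry.get("site_id", f"site_{index}")
    meta = SiteMeta(site_id=site_id, group=entry.get("group", "dry"),
                    exclusion_windows=[tuple(w) for w in entry.get("exclusions", [])])
    if "scenario" in entry:
        params = dict(entry["scenario"])
        preset = params.pop("preset", "dry")
        params.setdefault("site_id", site_id)
        params.setdefault("seed", config.seed * 1000 + index)
        scenario = scenario_from_preset(preset, **params)
        bundle = generate_site(scenario)
        monthly = apply_exclusions(bundle["monthly"], meta)
        return monthly, meta, bundle["truth"]

    series = read_flux_table(entry["path"], entry["column_map"],
                             entry.get("resolution", "daily"),
                             units=entry.get("units"), site_id=site_id)
    series = apply_exclusions(series, meta)
    if "PET" not in series.data.columns or series.data["PET"].isna().all():
        series.data["PET"] = _pet_column(series)
    if series.resolution != "monthly":
        series = aggregate(series, "monthly", min_coverage=config.min_coverage)
    return series, meta, {}


def _pet_column(series: FluxTimeSeries) -> pd.Series:
    """Fill PET from met fields: Penman when wind exists, else wind-free."""
    d = series.data
    ndays = 1.0
    if series.resolution == "monthly":
        ndays = d.index.days_in_month.to_numpy(dtype=float)
    rn_daily = d["Rn"] / ndays
    if "u" in d.columns and d["u"].notna().any():
        pet_daily = penman_pet(d["Ta"], d["RH"], d["u"].fillna(2.0), rn_daily)
    else:
        pet_daily = windfree_pet(d["Ta"], d["RH"], rn_daily)
    return pd.Series(pet_daily * ndays, index=d.index)


def _analyse_site(monthly: FluxTimeSeries, meta: SiteMeta, entry: dict,
                  config: StudyConfig) -> dict:
    data = monthly.data
    if entry.get("gy_start_month"):
        gy_spec = GrowingYearSpec(int(entry["gy_start_month"]))
    else:
        clim = data["NEP"].groupby(data.index.month).mean()
        gy_spec = define_growing_year(clim.reindex(range(1, 13)).to_numpy())

    gy_df = growing_year_indices(monthly, gy_spec, uwue_timescale=config.uwue_timescale)
    if len(gy_df) < 4:
        raise ValueError("fewer than four complete growing years")

    covered = [tuple(w) for w in config.candidate_windows
               if all(int(y) in gy_df.index for y in range(int(w[0]), int(w[-1]) + 1))]
    if len(covered) >= 2:
        window = select_drought_window(gy_df, covered)
    elif covered:
        window = covered[0]
    else:
        raise ValueError("no candidate drought window covered by data")

    pre_years = [y for y in gy_df.index if y < window[0]]
    mi_pre = window_mi(gy_df, pre_years)
    mi_dro = window_mi(gy_df, range(window[0], window[-1] + 1))
    p_pre = gy_df.loc[pre_years, "P"].mean()
    p_dro = gy_df.loc[[y for y in gy_df.index if window[0] <= y <= window[-1]], "P"].mean()
    assessment = classify_drought(mi_pre, mi_dro, site=meta.site_id,
                                  drought_window=window,
                                  delta_p_pct=100.0 * (p_dro - p_pre) / p_pre)

    impact = drought_impact(gy_df, window, exclusions=entry.get("impact_exclusions", ()),
                            site=meta.site_id)

    recovery = pd.DataFrame()
    post_year = window[-1] + 1
    if post_year in gy_df.index and pre_years:
        match = match_analogue_year(float(gy_df.loc[post_year, "MI"]),
                                    [(y, float(gy_df.loc[y, "MI"])) for y in pre_years],
                                    site=meta.site_id, post_year=post_year)
        recovery = recovery_comparison(gy_df, match)
    else:
        logger.warning("site %s: no post-drought growing year; recovery skipped",
                       meta.site_id)

    # temporal diagnostics: smoothed MI, ET/PET, NEP (stored-water signature)
    diag = pd.DataFrame({
        "MI": data["P"] / data["PET"],
        "ET_over_PET": data["ET"] / data["PET"],
        "NEP": data["NEP"],
    }, index=data.index)
    if monthly.resolution == "daily":
        diag = diag.apply(lambda s: moving_average(s, 30, centered=True))

    # lag attribution over the transition into drought
    w_start, _ = growing_year_span(window[0], gy_spec.start_month)
    _, w_end = growing_year_span(window[-1], gy_spec.start_month)
    trans = (w_start - pd.DateOffset(months=12), w_end)
    baseline = config.zscore_baseline or (data.index.min(), data.index.max())
    lags = []
    for var in ("GPP", "LAI"):
        if var not in data.columns or data[var].isna().all():
            continue
        try:
            lc = lag_attribution(diag["MI"] if monthly.resolution == "monthly"
                                 else data["P"] / data["PET"],
                                 data[var], baseline=baseline, window=trans,
                                 max_lag=config.max_lag, response_name=var)
            lags.append({"site": meta.site_id, "response": var,
                         "peak_r": lc.peak_r, "lag_months": lc.lag,
                         "meaningful": lc.physiologically_meaningful})
        except ValueError as exc:
            logger.warning("site %s: lag attribution for %s skipped (%s)",
                           meta.site_id, var, exc)

    return {"gy_spec": gy_spec, "gy_df": gy_df, "assessment": assessment,
            "impact": impact, "recovery": recovery, "diagnostics": diag,
            "lags": pd.DataFrame(lags)}


def _assessment_row(a: DroughtAssessment, gy_spec: GrowingYearSpec, group: str) -> dict:
    return {"site": a.site, "group": group,
            "delta_P_pct": a.delta_p_pct,
            "delta_MI": a.mi_drought - a.mi_pre,
            "delta_MI_pct": a.delta_mi_pct,
            "gy_start_month": gy_spec.start_month,
            "window_first": a.drought_window[0], "window_last": a.drought_window[-1],
            "severity": a.severity}


def run_study(config: StudyConfig, write: bool = True) -> dict:
    """Execute the full study; returns a report bundle of tidy tables.

    Sites failing a stage are reported and skipped; pooled stages run on
    the survivors.  ``report["n_failed"]`` counts failures.
    """
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    results, failures = {}, {}
    for i, entry in enumerate(config.sites):
        site_id = entry.get("site_id", f"site_{i}")
        try:
            monthly, meta, truth = _ingest_site(entry, config, i)
            res = _analyse_site(monthly, meta, entry, config)
            res["meta"], res["truth"] = meta, truth
            results[site_id] = res
        except Exception as exc:  # noqa: BLE001 — per-site isolation is the contract
            logger.error("site %s failed: %s", site_id, exc)
            failures[site_id] = str(exc)

    classification = pd.DataFrame([
        _assessment_row(r["assessment"], r["gy_spec"], r["meta"].group)
        for r in results.values()])
    impact = pd.concat([r["impact"] for r in results.values()],
                       ignore_index=True) if results else pd.DataFrame()
    recovery = pd.concat([r["recovery"] for r in results.values()
                          if len(r["recovery"])], ignore_index=True) \
        if any(len(r["recovery"]) for r in results.values()) else pd.DataFrame()
    lags = pd.concat([r["lags"] for r in results.values() if len(r["lags"])],
                     ignore_index=True) if results else pd.DataFrame()

    annual = pd.concat(
        [r["gy_df"].assign(site=sid) for sid, r in results.items()]
    ).reset_index() if results else pd.DataFrame()

    regressions = pd.DataFrame()
    if len(annual) >= 3:
        fits = []
        for predictor in REGRESSION_PREDICTORS:
            for response in ("GPP", "NEP", "ER"):
                if response not in annual.columns:
                    continue
                fits.extend(fit_flux_climate(annual, predictor, response, scope="both"))
        regressions = pd.DataFrame([
            {k: getattr(f, k) for k in ("predictor", "response", "scope", "slope",
                                        "intercept", "r_squared", "n")}
            for f in fits])

    report = {
        "classification": classification, "impact": impact, "recovery": recovery,
        "lags": lags, "annual": annual, "regressions": regressions,
        "sites": results, "failures": failures, "n_failed": len(failures),
    }

    if write:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("classification", "impact", "recovery", "lags", "annual",
                     "regressions"):
            report[name].to_csv(out / f"{name}.csv", index=False,
                                float_format="%.10g")
        diag_dir = out / "diagnostics"
        diag_dir.mkdir(exist_ok=True)
        for sid, r in results.items():
            r["diagnostics"].to_csv(diag_dir / f"{sid}_timeseries.csv",
                                    index_label="timestamp", float_format="%.10g")
        from . import __version__ as pkg_version

        manifest = {
            "config_hash": config.config_hash(),
            "config": config.canonical_dict(),
            "seed": config.seed,
            "package_version": pkg_version,
            "n_sites": len(results),
            "n_failed": len(failures),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    if config.sites and not results:
        raise RuntimeError("all sites failed")
    return report
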