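# Methods

This document records the formulations, parameter choices, and numerical
conventions implemented in `fluxdrought`, and the rationale for each design
decision left open by the problem statement.

## 1. Canonical data model

`FluxTimeSeries` wraps a pandas DataFrame indexed by strictly increasing,
uniformly spaced timestamps at one of four resolutions: `halfhourly`,
`daily`, `monthly`, `growing_year`. Canonical units per step:

| Field | Unit | Notes |
|---|---|---|
| NEP, GPP, ER | gC m⁻² | NEP ≡ GPP − ER enforced to 1e-6 |
| ET, P, PET | mm | extensive (summed on aggregation) |
| VPD | kPa | intensive (averaged) |
| Ta | °C; RH % ; u m s⁻¹; Rn MJ m⁻² | met drivers |
| LAI | m² m⁻² | intensive |

Missing data are `NaN` and stay in place — gaps are masked, never dropped,
so time arithmetic is always valid. The ingest layer converts common tower
units (latent heat W m⁻² → mm via λ = 2.45 MJ kg⁻¹; µmol CO₂ m⁻² s⁻¹ →
gC via 12.011·10⁻⁶ g µmol⁻¹ times step seconds; hPa → kPa; RH fraction →
percent). Aggregation to a coarser resolution sums extensive and averages
intensive fields and masks any target period with < `min_coverage` (default
0.8) valid steps; growing-year aggregation keeps only complete years.
Disturbance windows (fires, management) blank the four core flux fields but
leave met fields intact; overlapping windows are merged, and the operation
is idempotent.

## 2. Potential evapotranspiration

Two variants, both in mm d⁻¹, with all constants frozen in `pet.py`:

**Penman (Shuttleworth transcription).**
PET = Δ/(Δ+γ) · Rn/λ + γ/(Δ+γ) · 6.43·(1 + 0.536·u₂) · D/λ
with Tetens saturation vapour pressure
e_s = 0.6108·exp(17.27·T/(T+237.3)) kPa, slope Δ = 4098·e_s/(T+237.3)²,
psychrometric constant γ = 0.000665·101.3 kPa °C⁻¹ (sea-level default),
vapour pressure deficit D = e_s·(1 − RH/100), λ = 2.45 MJ kg⁻¹.

**Wind-free variant** for sites without anemometry: the same radiative term
plus the simplified aerodynamic term 0.09·(Ta + 20)·(1 − RH/100), a
published approximation of the Penman wind function that needs no wind
speed. On a mild-climate grid (Ta 10–30 °C, RH 30–90 %, u 1–3 m s⁻¹) the
two variants agree within 25 % (13.7 % worst case observed), which bounds
the error of using the wind-free form as a fallback.

*Rationale for the variant choice:* the analysis only needs a demand index
that is monotone in radiation and VPD and comparable across sites; the
Shuttleworth transcription is the standard open-water Penman with
well-documented constants, and the wind-free form keeps sparse sites in the
study rather than dropping them. Passing `u=None` to `penman_pet` raises
with a pointer to `windfree_pet` rather than silently assuming a wind
climatology. Negative computed PET (possible at RH ≈ 100, Rn ≈ 0 with the
simplified aerodynamic term) is floored at zero.

## 3. Water indices and drought classification

For month *j* of period *i*: available water **X_ij = P_ij − PET_ij** (mm).
Over a 12-month growing year:

- **WAI = Σ_j X_ij** — net water availability, either sign;
- **MWDI = Σ_{X<0} X_ij** — deficit-month sum only, hence MWDI ≤ 0 and
  MWDI ≤ WAI always (surplus months cannot erase deficit exposure);
- **MI = ΣP / ΣPET** — a *ratio of period sums*, not a mean of monthly
  ratios: the sums form weights months by their actual water amounts and is
  stable when PET is small in single months.

Both annual indices require 12 complete months (`allow_partial` overrides
explicitly). **uWUE = GPP·√VPD/ET** is computed at the annual timescale by
default — annual GPP and ET sums with the growing-year mean VPD — because
annual sums are robust to the noise and gap structure of monthly flux data;
a `daily` option forms the ratio per step first and averages, which weights
all days equally but inherits step-level noise. The default is the
aggregate-first convention; both are exposed and documented so the choice
is visible in results.

**Growing year.** The 12-month analysis window starts at the month of
minimum climatological mean NEP (the seasonal carbon-uptake trough, so a
growing season is never split). A growing year starting in months 1–6 keeps
its calendar-year label; one starting in months 7–12 takes the label of the
following calendar year (an October-start growing year 2018 runs Oct 2017 –
Sep 2018). Ties in the NEP climatology take the earliest month and are
logged.

**Severity.** With ΔMI% = 100·(MI_drought − MI_pre)/MI_pre over the pre vs
drought windows: ΔMI% ≤ −30 → `severe`; −30 < ΔMI% ≤ −10 → `moderate`;
otherwise `none`. Boundary values classify toward the more severe class
(thresholds are inclusive). The drought window is selected from a candidate
list as the one with the most negative ΔMI% against the pre-candidate
baseline; ties take the earlier window (logged).

## 4. Impact, recovery, and flux–climate regression

**Impact** compares pre-drought vs drought-window annual means of ET, ET/P,
GPP, NEP, ER, uWUE, MI. Relative change is 100·(drought − pre)/|pre|; when
a variable crosses zero (typically NEP flipping sink → source) the
percentage is still reported but `sign_change` is flagged and the absolute
change is the robust summary. At least two pre-drought years are required;
disturbance years can be excluded from the baseline.

**Recovery** pairs the first post-drought growing year with the pre-drought
*analogue year* of most similar MI (ties take the most recent, logged) and
reports paired flux ratios (post/analogue) for GPP, ER, NEP — a
like-for-like moisture comparison rather than a comparison against the
(possibly wetter) pre-drought mean.

**Flux–climate fits** are ordinary least squares (statsmodels) of annual
flux sums on P, MI, WAI or MWDI, pooled across all site-years and per site
(≥ 3 years, else omitted and logged). The test suite pins the OLS against a
closed-form normal-equations oracle.

## 5. Temporal mechanisms

**Lag attribution** (leaf shedding vs stomatal closure): monthly driver
(MI) and response (GPP or LAI) are Z-scored against a baseline period
(≥ 12 months, nonzero variance), smoothed with a centred 12-month moving
average (incomplete edge windows masked, not shortened), then correlated at
every integer lag in [−max_lag, +max_lag] (default 12) over the analysis
window. The reported lag maximises |r|; ties prefer the smaller |lag|
(logged); negative lags (response leading its driver) are flagged
physically meaningless rather than silently reported. Standardisation
happens *within the analysis window* so level shifts between baseline and
window do not masquerade as correlation. At least `max_lag + 6` overlapping
steps are required.

**Diurnal centroid**: C = Σ(t·F)/ΣF over daytime steps (06:00–18:00 local,
half-hour midpoints), with negative fluxes floored at zero (storage and
u*-filter artefacts would otherwise shift the centroid) and days with < 6
valid daytime steps or non-positive total skipped. The drought signal is
the seasonal **divergence**
(C_ET/√VPD − C_GPP)_drought − (C_ET/√VPD − C_GPP)_pre: under pure stomatal
control both centroids move together and the divergence is ≈ 0; a negative
divergence (water loss shifted earlier relative to carbon gain) indicates
non-stomatal limitation. Seasons with < 20 valid days in either period are
masked. ET is demand-adjusted by √VPD per the uWUE convention; because VPD
enters both periods, its own diurnal cycle bias cancels to < 1 minute for
the amplitudes the generator produces (verified analytically and in tests).

## 6. Synthetic generator

The generator produces monthly site records with known ground truth, so
every estimator above can be validated against imposed structure.

Chain: sinusoidal seasonal P and PET with multiplicative lognormal noise
(mean-one) → drought forcing as per-growing-year multipliers on P (and 1.1
on PET) → a monthly soil bucket → carbon coupling → optional diurnal
disaggregation.

**Bucket.** With storage S (mm), stress factor β = min(1, S/S_crit):
ET = min(PET·β·transport_cap, S + P); overflow above S_max leaves as
runoff. Mass balance S′ − S = P − ET − runoff is exact to machine
precision by construction and asserted in tests (criterion: < 1e-9).

**Carbon.** GPP = uWUE_target·ET/√VPD, optionally capped by a light ceiling
(energy-limited forests); ER = r₀ + r₁·GPP; NEP = GPP − ER exactly; additive
Gaussian noise on GPP and ER only. LAI = base + gain·⟨MI⟩₃ lagged by
`lai_lag` months (⟨·⟩₃ = 3-month centred mean) — the imposed truth the lag
estimator must recover.

**Diurnal disaggregation** distributes daily ET/GPP over a half-sine
daylight template (07:00–17:00); on drought days the ET template starts
`centroid_shift_drought` hours earlier, displacing the ET centroid by
exactly that amount while conserving daily totals; VPD gets a mild cosine
cycle (amplitude 0.3, peak 15:00) whose daily mean equals the daily value.

**Presets** (`grass`, `very_dry`, `dry`, `seasonally_wet`, `wet`) encode the
five ecosystem groups of the 2018–19 south-east Australian drought study
layout: annual rainfall means from the published site-characteristics
table, per-group drought rainfall multipliers from the published per-group
rainfall anomalies (grass 0.50, very dry 0.40, dry 0.77, seasonally wet
0.63, wet 1.0), shallow buckets and no light cap for water-governed
grass/arid sites, deep buckets with light caps for forests, and the wet
preset's cap above the seasonally-wet cap so energy-limited wet forests are
the most productive and *least* rainfall-sensitive group. The 14-site
`ensemble_scenarios` pairs each published site rainfall with a realistic
site-level PET (wet-site MI ≥ 1). These settings were fixed from the study
description before the acceptance checks were frozen; with them, periodic
deficit exposure (MWDI) out-predicts raw rainfall for pooled GPP across
every seed tried, with per-site R² high for grass/arid groups and near zero
for wet forests — the qualitative ordering the study reports.

**Scope and limits.** The generator is a test harness, not a land-surface
model: no energy balance, no snow, no interception, no CO₂ or temperature
response of photosynthesis, monthly-resolution water dynamics only, and
diurnal structure imposed by template rather than emergent. Conclusions
about real sites should come from real data through the same pipeline.

**Determinism.** Every stochastic draw comes from
`numpy.random.default_rng([seed, stream])` with fixed per-purpose stream
ids (climate 1, fluxes 2, LAI 3, helper series 7, ensemble 11), so adding a
new consumer never perturbs existing draws and identical seeds reproduce
identical sites bit for bit. Pipeline outputs contain no timestamps or
machine identifiers; `manifest.json` carries a SHA-256 config hash, so two
runs with the same config and seed are byte-identical.

## 7. Problem sizes and runtime

Typical scales: 14 sites × 12 years × 12 months ≈ 2,000 site-months per
study; half-hourly mechanism analysis ≈ 35,000 steps per site-year. The
full synthetic study (generation, indices, classification, impact,
recovery, lags, regressions, outputs) runs in ≈ 1 s; the acceptance script
(1,000 index tables, 500 lag series, 1,000 bucket scenarios, two full
ensemble pipeline runs) in ≈ 5 s; the test suite in ≈ 10 s. All numerics
are float64; no iterative solvers are involved, so the only tolerances are
the validation bounds stated above (NEP identity 1e-6, bucket closure
1e-9, OLS at statsmodels/LAPACK precision).
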