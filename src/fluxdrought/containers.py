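"""Canonical in-memory containers for flux/meteorology time series.

A :class:`FluxTimeSeries` wraps a pandas DataFrame indexed by interval-start
timestamps (half-open intervals) at one of four resolutions.  All values are
kept in canonical units: carbon fluxes in gC m⁻² per step, water in mm per
step, VPD in kPa, Ta in °C, RH in %, wind in m s⁻¹, net radiation in
MJ m⁻² per step, LAI in m² m⁻².  Missing values are NaN; the missing-value
mask is simply ``data.isna()``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical field order; PET is a derived column admitted alongside these
FLUX_FIELDS = ["NEP", "GPP", "ER", "ET", "VPD", "P", "Ta", "RH", "u", "Rn", "LAI"]

#: per-step quantities that sum under aggregation
EXTENSIVE_FIELDS = {"NEP", "GPP", "ER", "ET", "P", "Rn", "PET"}

#: state-like quantities that average under aggregation
INTENSIVE_FIELDS = {"VPD", "Ta", "RH", "u", "LAI"}

#: carbon/water flux fields blanked by disturbance exclusions
CORE_FLUX_FIELDS = ["NEP", "GPP", "ER", "ET"]

RESOLUTIONS = ("halfhourly", "daily", "monthly", "growing_year")

_STEP = {"halfhourly": pd.Timedelta(minutes=30), "daily": pd.Timedelta(days=1)}


class ValidationError(ValueError):
    """Raised when a series violates a structural or physical invariant."""


class FormatError(ValueError):
    """Raised when an input table cannot be interpreted."""


def _check_uniform_index(index: pd.Index, resolution: str) -> None:
    if resolution == "growing_year":
        if not index.is_monotonic_increasing or index.has_duplicates:
            raise ValidationError("growing-year labels must be strictly increasing")
        return
    if not isinstance(index, pd.DatetimeIndex):
        raise ValidationError(f"{resolution} series requires a DatetimeIndex")
    if len(index) > 1:
        diffs = np.diff(index.asi8)
        if (diffs <= 0).any():
            bad = int(np.argmax(diffs <= 0)) + 1
            raise ValidationError(
                f"timestamps not strictly increasing at row {bad} ({index[bad]})"
            )
        if resolution in _STEP:
            step = _STEP[resolution].value
            if (diffs != step).any():
                bad = int(np.argmax(diffs != step)) + 1
                raise ValidationError(
                    f"non-uniform {resolution} step at row {bad} ({index[bad]})"
                )
        elif resolution == "monthly":
            periods = index.to_period("M")
            gaps = np.diff(periods.asi8)
            if (gaps != 1).any():
                bad = int(np.argmax(gaps != 1)) + 1
                raise ValidationError(f"non-consecutive month at row {bad} ({index[bad]})")


def _check_physical_ranges(data: pd.DataFrame) -> None:
    bounds = {"ET": (0, None), "P": (0, None), "VPD": (0, None),
              "RH": (0, 100), "LAI": (0, None), "PET": (0, None)}
    for col, (lo, hi) in bounds.items():
        if col not in data:
            continue
        vals = data[col].dropna()
        if lo is not None and (vals < lo - 1e-9).any():
            raise ValidationError(f"{col} below {lo} in non-missing entries")
        if hi is not None and (vals > hi + 1e-9).any():
            raise ValidationError(f"{col} above {hi} in non-missing entries")


def _check_nep_identity(data: pd.DataFrame, tol: float = 1e-6) -> None:
    if not {"NEP", "GPP", "ER"}.issubset(data.columns):
        return
    sub = data[["NEP", "GPP", "ER"]].dropna()
    if len(sub):
        resid = (sub["NEP"] - (sub["GPP"] - sub["ER"])).abs()
        if (resid > tol).any():
            raise ValidationError(
                f"NEP != GPP - ER beyond {tol} (max residual {resid.max():.3g})"
            )


@dataclass
class FluxTimeSeries:
    """A validated flux/meteorology series at one resolution.

    Parameters
    ----------
    site_id : str
    resolution : {"halfhourly", "daily", "monthly", "growing_year"}
    data : DataFrame
        Indexed by interval-start timestamps (or integer growing-year labels
        for ``growing_year`` resolution); columns a subset of
        :data:`FLUX_FIELDS` plus optionally ``PET``.  NaN marks missing.
    """

    site_id: str
    resolution: str
    data: pd.DataFrame
    validate: dataclasses.InitVar[bool] = True

    def __post_init__(self, validate: bool) -> None:
        if self.resolution not in RESOLUTIONS:
            raise ValidationError(f"unknown resolution {self.resolution!r}")
        known = set(FLUX_FIELDS) | {"PET"}
        extra = set(self.data.columns) - known
        if extra:
            raise ValidationError(f"unknown fields: {sorted(extra)}")
        self.data = self.data.astype(float)
        if validate:
            _check_uniform_index(self.data.index, self.resolution)
            _check_physical_ranges(self.data)
            _check_nep_identity(self.data)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missing-value mask (True = missing)."""
        return self.data.isna()

    def __len__(self) -> int:
        return len(self.data)

    def copy(self) -> "FluxTimeSeries":
        return FluxTimeSeries(self.site_id, self.resolution, self.data.copy(), validate=False)


@dataclass
class SiteMeta:
    """Site metadata: ecosystem group, location, and disturbance exclusions."""

    site_id: str
    group: str = "dry"
    latitude: float = np.nan
    longitude: float = np.nan
    utc_offset: float = 0.0
    record_span: tuple | None = None
    exclusion_windows: list = field(default_factory=list)  # (start, end, reason)

    GROUPS = ("grass", "very_dry", "dry", "seasonally_wet", "wet")

    def __post_init__(self) -> None:
        if self.group not in self.GROUPS:
            raise ValidationError(f"group must be one of {self.GROUPS}, got {self.group!r}")
        norm = []
        for w in self.exclusion_windows:
            start, end = pd.Timestamp(w[0]), pd.Timestamp(w[1])
            if end < start:
                raise ValidationError(f"exclusion window ends before it starts: {w}")
            reason = w[2] if len(w) > 2 else ""
            norm.append((start, end, reason))
        self.exclusion_windows = norm
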