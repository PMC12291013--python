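"""Potential evapotranspiration from site meteorology.

Two estimators are provided:

``penman_pet``
    Penman (1948) open-water evaporation in the Shuttleworth (1993)
    transcription::

        PET = Δ/(Δ+γ) · Rn/λ  +  γ/(Δ+γ) · 6.43·(1 + 0.536·u) · D / λ

    with Δ the slope of the saturation vapour-pressure curve (kPa °C⁻¹),
    γ the psychrometric constant, Rn daily net radiation (MJ m⁻² d⁻¹),
    u wind speed at 2 m (m s⁻¹), D the vapour pressure deficit (kPa) and
    λ = 2.45 MJ kg⁻¹.

``windfree_pet``
    A Valiantzas-type simplification whose aerodynamic component,
    0.09·(Ta + 20)·(1 − RH/100) mm d⁻¹, absorbs the γ/(Δ+γ) weighting and
    a reference wind speed near 2 m s⁻¹, so no wind record is needed.

Both return mm d⁻¹ and are floored at zero.  All psychrometric constants
live in this module and nowhere else.
"""

from __future__ import annotations

import numpy as np

#: latent heat of vaporisation, MJ kg⁻¹
LAMBDA = 2.45

#: Tetens saturation vapour pressure coefficients (kPa, °C)
SVP_A, SVP_B, SVP_C = 0.6108, 17.27, 237.3

#: psychrometric constant per unit pressure, kPa °C⁻¹ kPa⁻¹ (= cp / (ε λ))
GAMMA_PER_KPA = 0.000665

#: Penman 1948 open-water wind function, MJ m⁻² d⁻¹ kPa⁻¹
WIND_A, WIND_B = 6.43, 0.536

#: Valiantzas aerodynamic regression coefficient, mm d⁻¹ °C⁻¹
VALIANTZAS_AERO = 0.09

DEFAULT_PRESSURE_KPA = 101.3


def saturation_vapour_pressure(Ta):
    """Saturation vapour pressure (kPa) at air temperature Ta (°C), Tetens form."""
    Ta = np.asarray(Ta, dtype=float)
    return SVP_A * np.exp(SVP_B * Ta / (Ta + SVP_C))


def svp_slope(Ta):
    """Slope Δ of the saturation vapour-pressure curve, kPa °C⁻¹."""
    Ta = np.asarray(Ta, dtype=float)
    return 4098.0 * saturation_vapour_pressure(Ta) / (Ta + SVP_C) ** 2


def psychrometric_constant(pressure=DEFAULT_PRESSURE_KPA):
    """Psychrometric constant γ, kPa °C⁻¹, at the given air pressure (kPa)."""
    return GAMMA_PER_KPA * np.asarray(pressure, dtype=float)


def vpd_from_rh(Ta, RH):
    """Vapour pressure deficit (kPa) from temperature (°C) and RH (%)."""
    RH = np.asarray(RH, dtype=float)
    if np.any((RH < 0) | (RH > 100)):
        raise ValueError("RH must lie in [0, 100]")
    return saturation_vapour_pressure(Ta) * (1.0 - RH / 100.0)


def penman_pet(Ta, RH, u, Rn, pressure=DEFAULT_PRESSURE_KPA):
    """Daily Penman PET, mm d⁻¹.

    Parameters
    ----------
    Ta : air temperature, °C
    RH : relative humidity, %
    u : wind speed at 2 m, m s⁻¹ (required; see :func:`windfree_pet`)
    Rn : net radiation, MJ m⁻² d⁻¹
    pressure : air pressure, kPa
    """
    if u is None:
        raise ValueError("wind speed is required; use windfree_pet when u is unavailable")
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("wind speed must be non-negative")
    Rn = np.asarray(Rn, dtype=float)
    delta = svp_slope(Ta)
    gamma = psychrometric_constant(pressure)
    D = vpd_from_rh(Ta, RH)
    radiative = delta / (delta + gamma) * Rn / LAMBDA
    aerodynamic = gamma / (delta + gamma) * WIND_A * (1.0 + WIND_B * u) * D / LAMBDA
    return np.maximum(radiative + aerodynamic, 0.0)


def windfree_pet(Ta, RH, Rn, pressure=DEFAULT_PRESSURE_KPA):
    """Daily wind-speed-free Penman PET (Valiantzas-type), mm d⁻¹."""
    Ta = np.asarray(Ta, dtype=float)
    RH = np.asarray(RH, dtype=float)
    if np.any((RH < 0) | (RH > 100)):
        raise ValueError("RH must lie in [0, 100]")
    Rn = np.asarray(Rn, dtype=float)
    delta = svp_slope(Ta)
    gamma = psychrometric_constant(pressure)
    radiative = delta / (delta + gamma) * Rn / LAMBDA
    aerodynamic = VALIANTZAS_AERO * (Ta + 20.0) * (1.0 - RH / 100.0)
    return np.maximum(radiative + aerodynamic, 0.0)
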