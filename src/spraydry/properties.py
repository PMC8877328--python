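"""Thermophysical and psychrometric properties of dry/humid air and water.

Every energy term of the dryer balance goes through this layer.  The drying
gas is treated as an ideal gas, and its specific heat as linear in
temperature over the experimental range; both choices keep the overall
balance analytically transparent while staying within ~1% of tabulated
dry-air data between 300 and 500 K.

Correlation constants live in :class:`PropertyCoefficients` so they can be
swapped from a versioned config file without touching code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "R_AIR",
    "CP_VAPOR",
    "STEFAN_BOLTZMANN",
    "P_ATM",
    "PropertyCoefficients",
    "DEFAULT_COEFFICIENTS",
    "AirState",
    "WaterProperties",
    "cp_air",
    "air_density",
    "air_transport",
    "saturation_pressure",
    "saturation_mixing_ratio",
    "wet_bulb_temperature",
    "wet_bulb_from_humidity",
    "latent_heat",
    "air_state",
]

#: Specific gas constant of dry air, J·kg⁻¹·K⁻¹.
R_AIR = 287.05
#: Specific heat of water vapour (psychrometric constant-pressure value), J·kg⁻¹·K⁻¹.
CP_VAPOR = 1860.0
#: Stefan–Boltzmann constant, W·m⁻²·K⁻⁴.
STEFAN_BOLTZMANN = 5.670374419e-8
#: Reference ambient pressure, Pa.
P_ATM = 101325.0

# Validity window of the dry-air correlations, K.
_T_MIN, _T_MAX = 273.0, 600.0


@dataclass(frozen=True)
class PropertyCoefficients:
    """Correlation constants for the property layer.

    cp_a, cp_b
        Linear dry-air specific heat, cp(T) = cp_a + cp_b·T.  Fitted once by
        ordinary least squares to tabulated dry-air cp at
        {300, 350, 400, 450, 500} K = {1007, 1009, 1014, 1021, 1030} J·kg⁻¹·K⁻¹.
    cp_liquid
        Specific heat of liquid water, J·kg⁻¹·K⁻¹.
    latent_ref, latent_slope
        Linear latent heat of vaporization of water,
        λ(T) = latent_ref − latent_slope·(T − 273.15), fitted to steam-table
        values between 273 and 373 K.
    inlet_humidity
        Absolute humidity of the (dehumidified) drying air, kg water per kg
        dry air.
    """

    cp_a: float = 969.8
    cp_b: float = 0.116
    cp_liquid: float = 4186.0
    latent_ref: float = 2.501e6
    latent_slope: float = 2444.0
    inlet_humidity: float = 0.003


DEFAULT_COEFFICIENTS = PropertyCoefficients()


@dataclass(frozen=True)
class AirState:
    """Bulk state of the drying gas at one temperature and pressure (SI)."""

    temperature: float  # K
    pressure: float  # Pa
    specific_heat: float  # J·kg⁻¹·K⁻¹
    density: float  # kg·m⁻³
    dynamic_viscosity: float  # Pa·s
    thermal_conductivity: float  # W·m⁻¹·K⁻¹
    prandtl: float  # –

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        for name in ("specific_heat", "density", "dynamic_viscosity", "thermal_conductivity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class WaterProperties:
    """Liquid-water constants used by the feed term (SI)."""

    specific_heat_liquid: float  # J·kg⁻¹·K⁻¹
    latent_heat_vaporization: float  # J·kg⁻¹ at the reference temperature
    reference_temperature: float = 373.15  # K


def _check_range(T, lo: float = _T_MIN, hi: float = _T_MAX, what: str = "temperature") -> None:
    T = np.asarray(T, dtype=float)
    if np.any(T < lo) or np.any(T > hi):
        raise ValueError(f"{what} outside correlation range [{lo}, {hi}] K")


def cp_air(T, coeffs: PropertyCoefficients = DEFAULT_COEFFICIENTS):
    """Specific heat of dry air, J·kg⁻¹·K⁻¹, linear in T over 273–600 K."""
    _check_range(T)
    return coeffs.cp_a + coeffs.cp_b * np.asarray(T, dtype=float)


def air_density(T, P=P_ATM):
    """Ideal-gas density of dry air, kg·m⁻³."""
    T = np.asarray(T, dtype=float)
    P = np.asarray(P, dtype=float)
    if np.any(T <= 0) or np.any(P <= 0):
        raise ValueError("temperature and pressure must be positive")
    return P / (R_AIR * T)


def air_transport(T, coeffs: PropertyCoefficients = DEFAULT_COEFFICIENTS):
    """Transport properties of dry air at temperature T.

    Returns ``(mu, k, Pr)``: Sutherland-law dynamic viscosity (Pa·s), a cubic
    polynomial thermal-conductivity fit (W·m⁻¹·K⁻¹, valid 250–1000 K), and
    the Prandtl number consistent with :func:`cp_air`.
    """
    _check_range(T)
    T = np.asarray(T, dtype=float)
    mu = 1.716e-5 * (T / 273.15) ** 1.5 * (273.15 + 110.4) / (T + 110.4)
    k = -3.9333e-4 + 1.0184e-4 * T - 4.8574e-8 * T**2 + 1.5207e-11 * T**3
    Pr = cp_air(T, coeffs) * mu / k
    return mu, k, Pr


def air_state(T: float, P: float = P_ATM, coeffs: PropertyCoefficients = DEFAULT_COEFFICIENTS) -> AirState:
    """Assemble a full :class:`AirState` at (T, P)."""
    mu, k, Pr = air_transport(T, coeffs)
    return AirState(
        temperature=float(T),
        pressure=float(P),
        specific_heat=float(cp_air(T, coeffs)),
        density=float(air_density(T, P)),
        dynamic_viscosity=float(mu),
        thermal_conductivity=float(k),
        prandtl=float(Pr),
    )


def saturation_pressure(T):
    """Saturation vapour pressure of water, Pa (Magnus/Alduchov–Eskridge)."""
    t = np.asarray(T, dtype=float) - 273.15
    return 610.94 * np.exp(17.625 * t / (243.04 + t))


def saturation_mixing_ratio(T, P=P_ATM):
    """Saturation humidity ratio, kg water per kg dry air.

    Only meaningful below the boiling point at P (p_ws < P).
    """
    p_ws = saturation_pressure(T)
    return 0.622 * p_ws / (np.asarray(P, dtype=float) - p_ws)


def latent_heat(T, coeffs: PropertyCoefficients = DEFAULT_COEFFICIENTS):
    """Latent heat of vaporization of water, J·kg⁻¹, linear in T.

    The fit targets steam-table data on 273–373 K (the wet-bulb range);
    supercritical or sub-freezing temperatures are rejected.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 273.0) or np.any(T >= 647.0):
        raise ValueError("latent_heat valid only for 273 K < T < 647 K")
    return coeffs.latent_ref - coeffs.latent_slope * (T - 273.15)


def water_properties(T_reference: float = 373.15,
                     coeffs: PropertyCoefficients = DEFAULT_COEFFICIENTS) -> WaterProperties:
    return WaterProperties(
        specific_heat_liquid=coeffs.cp_liquid,
        latent_heat_vaporization=float(latent_heat(T_reference, coeffs)),
        reference_temperature=T_reference,
    )


# Upper bracket for the psychrometric root: just below the ambient-pressure
# boiling point, where the mixing-ratio algebra degenerates (p_ws -> P).
_T_WB_MAX = 371.0


def wet_bulb_from_humidity(T_db: float, w: float, P: float = P_ATM,
                           coeffs: PropertyCoefficients = DEFAULT_COEFFICIENTS) -> float:
    """Wet-bulb temperature (K) of air at dry-bulb T_db with humidity ratio w.

    Root of the adiabatic-saturation balance

        (cp_air + w·cp_v)·(T_db − T_wb) = (w_s(T_wb) − w)·λ(T_wb),

    the temperature a droplet reaches during constant-rate adiabatic
    evaporation.  For very hot, dry gas the root sits far below T_db.
    """
    if w < 0:
        raise ValueError("humidity ratio must be non-negative")
    cp_gas = float(cp_air(min(max(T_db, _T_MIN), _T_MAX), coeffs)) + w * CP_VAPOR

    def balance(T_wb: float) -> float:
        return cp_gas * (T_db - T_wb) - (saturation_mixing_ratio(T_wb, P) - w) * float(
            latent_heat(T_wb, coeffs)
        )

    hi = min(T_db, _T_WB_MAX)
    if hi <= 273.16 or balance(hi) >= 0.0:
        # already saturated (or at/below the triple point): no evaporative depression
        return float(min(T_db, hi))
    return float(brentq(balance, 273.16, hi, xtol=1e-8))


def wet_bulb_temperature(T_db: float, RH: float, P: float = P_ATM,
                         coeffs: PropertyCoefficients = DEFAULT_COEFFICIENTS) -> float:
    """Wet-bulb temperature (K) from dry-bulb temperature and RH in percent.

    ``T_wb <= T_db`` with equality exactly at saturation (RH = 100).
    """
    if not 0.0 <= RH <= 100.0:
        raise ValueError("RH must be within [0, 100] %")
    if RH == 100.0:
        return float(T_db)
    p_v = RH / 100.0 * float(saturation_pressure(T_db))
    if p_v >= P:
        raise ValueError("vapour pressure exceeds total pressure; RH ill-defined here")
    w = 0.622 * p_v / (P - p_v)
    return wet_bulb_from_humidity(T_db, w, P, coeffs)
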