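"""Energy terms of the spray-dryer balance and the wall-temperature inversion.

The dryer is simplified as a vertical glass cylinder.  The steady-state
balance over the whole tower reads

    Qin = Qfeed + Qloss + Qout,

with Qin/Qout the enthalpy rates of the drying gas at inlet/outlet, Qfeed
the heat spent warming the feed droplets to the wet-bulb temperature and
vaporizing the solvent fraction, and Qloss the wall loss, split into a
convection/conduction term QlossR (internal forced convection in series
with conduction through the glass) and a radiation term Qlossrad
(Stefan–Boltzmann law at the outer-wall temperature Textwall).

Given a measured outlet temperature, the balance can be inverted for the
outer-wall temperature ("label derivation"); given a wall temperature, the
implicit relation for the outlet temperature is exposed as the map
``h(Tout)`` whose fixed point is the model's prediction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .properties import (
    CP_VAPOR,
    DEFAULT_COEFFICIENTS,
    P_ATM,
    STEFAN_BOLTZMANN,
    PropertyCoefficients,
    air_density,
    air_transport,
    cp_air,
    latent_heat,
    wet_bulb_from_humidity,
)

__all__ = [
    "DryerGeometry",
    "ProcessConditions",
    "EnergyBreakdown",
    "BalanceOptions",
    "FlaggedRecordError",
    "q_in",
    "q_out",
    "q_feed",
    "internal_heat_transfer_coefficient",
    "q_loss_conv",
    "q_loss_rad",
    "textwall_from_radiation",
    "q_loss_natural_convection",
    "natural_convection_share",
    "tout_residual",
    "derive_textwall_label",
]

log = logging.getLogger(__name__)

_GRAVITY = 9.81


class FlaggedRecordError(ValueError):
    """No physically admissible wall temperature balances this record."""


@dataclass(frozen=True)
class DryerGeometry:
    """Simplified-cylinder description of the drying tower.

    Defaults are nominal benchtop (B-290 class) tower dimensions with a 4 mm
    borosilicate wall; all values are configurable.
    """

    tower_diameter: float = 0.165  # inner diameter, m
    tower_height: float = 0.60  # m
    glass_thickness: float = 0.004  # m
    glass_conductivity: float = 1.05  # W·m⁻¹·K⁻¹
    glass_emissivity: float = 0.92  # –

    def __post_init__(self) -> None:
        for name in ("tower_diameter", "tower_height", "glass_thickness", "glass_conductivity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.glass_emissivity <= 1.0:
            raise ValueError("glass_emissivity must be in (0, 1]")

    @property
    def external_diameter(self) -> float:
        return self.tower_diameter + 2.0 * self.glass_thickness

    @property
    def external_area(self) -> float:
        """Lateral area of the outer cylinder surface, m²."""
        return np.pi * self.external_diameter * self.tower_height

    @property
    def internal_area(self) -> float:
        return np.pi * self.tower_diameter * self.tower_height

    @property
    def cross_section(self) -> float:
        return np.pi * self.tower_diameter**2 / 4.0

    @property
    def conduction_resistance(self) -> float:
        """Cylindrical-wall conduction resistance, K·W⁻¹."""
        r_i = self.tower_diameter / 2.0
        r_o = r_i + self.glass_thickness
        return np.log(r_o / r_i) / (2.0 * np.pi * self.glass_conductivity * self.tower_height)


@dataclass(frozen=True)
class ProcessConditions:
    """One spray-dryer operating point.

    Flows keep the instrument's kg/h convention; temperatures are K.
    ``cfeed`` is the solids mass fraction of the feed (0 for pure water).
    """

    Tin: float  # K
    Gin: float  # drying-gas mass flow, kg/h
    Text: float  # ambient temperature, K
    RHext: float  # ambient relative humidity, %
    FR: float = 0.0  # liquid feed rate, kg/h
    cfeed: float = 0.0  # solids mass fraction, –
    atomization_pressure: float = 6.0  # bar (metadata; not in the balance)

    def __post_init__(self) -> None:
        if self.Gin <= 0:
            raise ValueError("Gin must be positive")
        if self.FR < 0:
            raise ValueError("FR must be non-negative")
        if not 0.0 <= self.cfeed < 1.0:
            raise ValueError("cfeed must be in [0, 1)")
        if not 0.0 <= self.RHext <= 100.0:
            raise ValueError("RHext must be in [0, 100] %")
        if self.Tin <= self.Text:
            raise ValueError("Tin must exceed the ambient temperature")

    @property
    def gin_kg_s(self) -> float:
        return self.Gin / 3600.0

    @property
    def fr_kg_s(self) -> float:
        return self.FR / 3600.0


@dataclass(frozen=True)
class BalanceOptions:
    """Numerical/configuration switches of the balance.

    cp_mode
        "per_stream" evaluates cp at each stream's own temperature (Tin for
        Qin, Tout for Qout); "average" uses cp at Tavg = (Tin+Tout)/2 for
        both streams.
    correlation
        Internal forced-convection Nusselt correlation: "dittus_boelter"
        (default) or "gnielinski".
    """

    cp_mode: str = "per_stream"
    correlation: str = "dittus_boelter"
    pressure: float = P_ATM
    coefficients: PropertyCoefficients = field(default_factory=PropertyCoefficients)

    def __post_init__(self) -> None:
        if self.cp_mode not in ("per_stream", "average"):
            raise ValueError("cp_mode must be 'per_stream' or 'average'")
        if self.correlation not in ("dittus_boelter", "gnielinski"):
            raise ValueError("correlation must be 'dittus_boelter' or 'gnielinski'")


DEFAULT_OPTIONS = BalanceOptions()


@dataclass(frozen=True)
class EnergyBreakdown:
    """All balance terms (W) at one operating point, plus the wall temperature."""

    Qin: float
    Qout: float
    Qfeed: float
    QlossR: float
    Qlossrad: float
    Textwall: float

    @property
    def Qloss(self) -> float:
        return self.QlossR + self.Qlossrad

    @property
    def residual(self) -> float:
        """Relative closure error of Qin = Qfeed + Qloss + Qout."""
        return abs(self.Qin - (self.Qfeed + self.Qloss + self.Qout)) / self.Qin

    def to_dict(self) -> dict:
        return {
            "Qin_W": self.Qin,
            "Qout_W": self.Qout,
            "Qfeed_W": self.Qfeed,
            "QlossR_W": self.QlossR,
            "Qlossrad_W": self.Qlossrad,
            "Qloss_W": self.Qloss,
            "Textwall_K": self.Textwall,
            "residual_rel": self.residual,
        }


# ---------------------------------------------------------------------------
# gas-stream terms


def q_in(cond: ProcessConditions, opts: BalanceOptions = DEFAULT_OPTIONS, Tout: float | None = None) -> float:
    """Enthalpy rate of the inlet drying gas, W."""
    T_eval = cond.Tin if opts.cp_mode == "per_stream" or Tout is None else 0.5 * (cond.Tin + Tout)
    return cond.gin_kg_s * float(cp_air(T_eval, opts.coefficients)) * cond.Tin


def q_out(cond: ProcessConditions, Tout: float, opts: BalanceOptions = DEFAULT_OPTIONS) -> float:
    """Enthalpy rate of the outlet drying gas, W."""
    if Tout > cond.Tin:
        warnings.warn("Tout exceeds Tin: nonphysical for this dryer", stacklevel=2)
    T_eval = Tout if opts.cp_mode == "per_stream" else 0.5 * (cond.Tin + Tout)
    return cond.gin_kg_s * float(cp_air(T_eval, opts.coefficients)) * Tout


def feed_wet_bulb(cond: ProcessConditions, opts: BalanceOptions = DEFAULT_OPTIONS) -> float:
    """Wet-bulb temperature (K) the droplets reach in the inlet drying gas."""
    return wet_bulb_from_humidity(
        cond.Tin, opts.coefficients.inlet_humidity, opts.pressure, opts.coefficients
    )


def q_feed(cond: ProcessConditions, opts: BalanceOptions = DEFAULT_OPTIONS) -> float:
    """Heat rate absorbed by the feed, W.

    Sensible heating of the droplets from ambient to the wet-bulb
    temperature plus latent vaporization of the solvent mass fraction.
    """
    if cond.FR == 0.0:
        return 0.0
    T_wb = feed_wet_bulb(cond, opts)
    c = opts.coefficients
    sensible = c.cp_liquid * (T_wb - cond.Text)
    latent = (1.0 - cond.cfeed) * float(latent_heat(T_wb, c))
    return cond.fr_kg_s * (sensible + latent)


# ---------------------------------------------------------------------------
# wall losses


def internal_heat_transfer_coefficient(
    cond: ProcessConditions,
    Tavg,
    geom: DryerGeometry,
    opts: BalanceOptions = DEFAULT_OPTIONS,
):
    """Internal forced-convection coefficient h_i (W·m⁻²·K⁻¹) at Tavg.

    The Reynolds number uses the superficial tower velocity,
    Re = 4·ṁ / (π·D·μ).  Dittus–Boelter (Nu = 0.023·Re^0.8·Pr^0.4) is the
    default; Gnielinski is available as a configuration switch.
    """
    mu, k, Pr = air_transport(Tavg, opts.coefficients)
    Re = 4.0 * cond.gin_kg_s / (np.pi * geom.tower_diameter * mu)
    if opts.correlation == "dittus_boelter":
        Nu = 0.023 * Re**0.8 * Pr**0.4
    else:  # gnielinski
        f = (0.79 * np.log(Re) - 1.64) ** -2
        Nu = (f / 8.0) * (Re - 1000.0) * Pr / (1.0 + 12.7 * np.sqrt(f / 8.0) * (Pr ** (2.0 / 3.0) - 1.0))
    return Nu * k / geom.tower_diameter


def _series_resistance(cond, Tavg, geom, opts):
    h_i = internal_heat_transfer_coefficient(cond, Tavg, geom, opts)
    return 1.0 / (h_i * geom.internal_area) + geom.conduction_resistance


def q_loss_conv(
    cond: ProcessConditions,
    Tout,
    Textwall,
    geom: DryerGeometry,
    opts: BalanceOptions = DEFAULT_OPTIONS,
):
    """Convection/conduction wall loss QlossR, W.

    Heat flows from the bulk gas at Tavg = (Tin+Tout)/2 through the internal
    forced-convection film and the glass wall (series resistances) to the
    outer surface at Textwall.
    """
    Tavg = 0.5 * (cond.Tin + np.asarray(Tout, dtype=float))
    if np.any(np.asarray(Textwall) >= Tavg):
        warnings.warn("Textwall >= Tavg: inward heat flow, QlossR <= 0", stacklevel=2)
    R = _series_resistance(cond, Tavg, geom, opts)
    return (Tavg - np.asarray(Textwall, dtype=float)) / R


def q_loss_rad(Textwall, Text, geom: DryerGeometry):
    """Radiative wall loss by the Stefan–Boltzmann law, W."""
    Tw = np.asarray(Textwall, dtype=float)
    return geom.external_area * STEFAN_BOLTZMANN * geom.glass_emissivity * (
        Tw**4 - np.asarray(Text, dtype=float) ** 4
    )


def textwall_from_radiation(Qlossrad, Text, geom: DryerGeometry):
    """Invert the Stefan–Boltzmann law for the outer-wall temperature, K."""
    Q = np.asarray(Qlossrad, dtype=float)
    if np.any(Q < 0):
        raise ValueError("Qlossrad must be non-negative")
    radicand = Q / (geom.external_area * STEFAN_BOLTZMANN * geom.glass_emissivity) + np.asarray(
        Text, dtype=float
    ) ** 4
    return radicand**0.25


def q_loss_natural_convection(Textwall: float, Text: float, geom: DryerGeometry,
                              pressure: float = P_ATM) -> float:
    """External natural-convection loss over the tower surface, W (diagnostic).

    Churchill–Chu vertical-plate correlation with the tower height as the
    characteristic length (valid for slender cylinders at these Rayleigh
    numbers).  Excluded from the balance; used only to quantify its share
    of the total wall loss.
    """
    if Textwall <= Text:
        return 0.0
    T_film = 0.5 * (Textwall + Text)
    mu, k, _ = air_transport(T_film)
    rho = float(air_density(T_film, pressure))
    nu = mu / rho
    alpha = k / (rho * float(cp_air(T_film)))
    Pr = nu / alpha
    L = geom.tower_height
    Ra = _GRAVITY * (1.0 / T_film) * (Textwall - Text) * L**3 / (nu * alpha)
    Nu = (0.825 + 0.387 * Ra ** (1.0 / 6.0) / (1.0 + (0.492 / Pr) ** (9.0 / 16.0)) ** (8.0 / 27.0)) ** 2
    h_nc = Nu * k / L
    return h_nc * geom.external_area * (Textwall - Text)


def natural_convection_share(
    cond: ProcessConditions,
    measured_Tout: float,
    geom: DryerGeometry,
    opts: BalanceOptions = DEFAULT_OPTIONS,
) -> float:
    """Natural-convection loss as a percentage of the total wall loss.

    The wall temperature is first derived from the measured outlet
    temperature, then the Churchill–Chu loss is compared with
    QlossR + Qlossrad at that wall temperature.
    """
    Tw = derive_textwall_label(cond, measured_Tout, geom, opts)
    q_nc = q_loss_natural_convection(Tw, cond.Text, geom, opts.pressure)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # label may sit above Tavg (QlossR < 0)
        q_tot = float(q_loss_conv(cond, measured_Tout, Tw, geom, opts)) + float(
            q_loss_rad(Tw, cond.Text, geom)
        )
    return 100.0 * q_nc / q_tot


# ---------------------------------------------------------------------------
# the implicit outlet-temperature relation


def tout_residual(
    Tout,
    cond: ProcessConditions,
    Textwall,
    geom: DryerGeometry,
    opts: BalanceOptions = DEFAULT_OPTIONS,
    _q_feed: float | None = None,
):
    """Evaluate the map h(Tout) whose fixed point is the model's outlet T.

    Dividing the balance by cp·Gin gives

        h(Tout) = (Qin − Qfeed − Qloss(Tout, Textwall)) / (Gin·cp(Tout)),

    with cp evaluated per stream (or at Tavg under ``cp_mode='average'``).
    Qloss depends on Tout through the average gas temperature.
    """
    Tout = np.asarray(Tout, dtype=float)
    qf = q_feed(cond, opts) if _q_feed is None else _q_feed
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ql = q_loss_conv(cond, Tout, Textwall, geom, opts) + q_loss_rad(Textwall, cond.Text, geom)
    if opts.cp_mode == "per_stream":
        qin = cond.gin_kg_s * cp_air(cond.Tin, opts.coefficients) * cond.Tin
        cp_out = cp_air(np.clip(Tout, 273.0, 600.0), opts.coefficients)
        return (qin - qf - ql) / (cond.gin_kg_s * cp_out)
    cp_avg = cp_air(np.clip(0.5 * (cond.Tin + Tout), 273.0, 600.0), opts.coefficients)
    return cond.Tin - (qf + ql) / (cond.gin_kg_s * cp_avg)


# ---------------------------------------------------------------------------
# wall-temperature label derivation (inverse problem)


def derive_textwall_label(
    cond: ProcessConditions,
    measured_Tout: float,
    geom: DryerGeometry,
    opts: BalanceOptions = DEFAULT_OPTIONS,
) -> float:
    """Wall temperature that balances the record at its measured Tout, K.

    Solves QlossR(Textwall) + Qlossrad(Textwall) = Qin − Qout − Qfeed for
    Textwall by a 1-D root find on (Text, Tin); the left side is strictly
    increasing in Textwall over that interval for this geometry, so the
    root is unique.  Most labels land below the average gas temperature
    Tavg = (Tin+Tout)/2; a label slightly above Tavg (radiation carrying
    more than the through-wall term supplies) is admitted because the
    simplified network averages a wall that is locally hotter near the
    inlet.  Records whose loss target falls outside the attainable range
    raise :class:`FlaggedRecordError` and are excluded from surrogate
    training.
    """
    opts_q = opts
    target = (
        q_in(cond, opts_q, Tout=measured_Tout)
        - q_out(cond, measured_Tout, opts_q)
        - q_feed(cond, opts_q)
    )
    Tavg = 0.5 * (cond.Tin + measured_Tout)

    def gap(Tw: float) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return (
                float(q_loss_conv(cond, measured_Tout, Tw, geom, opts_q))
                + float(q_loss_rad(Tw, cond.Text, geom))
                - target
            )

    lo, hi = cond.Text + 1e-9, cond.Tin - 1e-9
    g_lo, g_hi = gap(lo), gap(hi)
    if g_lo > 0.0:
        raise FlaggedRecordError(
            f"loss target {target:.1f} W below the convective floor {g_lo + target:.1f} W "
            f"(Tin={cond.Tin:.0f} K, Gin={cond.Gin:.1f} kg/h): no wall temperature above ambient"
        )
    if g_hi < 0.0:
        raise FlaggedRecordError(
            f"loss target {target:.1f} W exceeds the attainable loss {g_hi + target:.1f} W at "
            f"Textwall=Tin (Tin={cond.Tin:.0f} K, Gin={cond.Gin:.1f} kg/h)"
        )
    return float(brentq(gap, lo, hi, xtol=1e-7))
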