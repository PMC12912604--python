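"""Surface heat/mass exchange: convection correlations, Lewis-analogy
condensation and evaporation, soil-column conduction, heating-pipe nodes.

Convective transfer between any surface and an air zone goes through a
named correlation h = f(dT, characteristic length, wind).  The registry
ships field-typical defaults (free-convection power laws indoors, a
wind-linear law on the outside of the cover, a TARP-style law for
exterior walls, a horizontal-cylinder law for pipes); every choice is
overridable from the configuration and logged at simulation start.

Water mass transfer at a surface follows the Lewis analogy: the mass
transfer coefficient is h/(rho*cp*Le^(2/3)); condensation occurs when the
zone humidity ratio exceeds saturation at the surface temperature, and
evaporation is limited by the condensate the surface actually holds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .constants import (CP_DRY_AIR, LATENT_HEAT_VAPORIZATION, LEWIS_NUMBER)
from .moist_air import MoistAirState, humidity_ratio_from_pw, saturation_pressure

__all__ = [
    "ConvectionCorrelation",
    "CONVECTION_REGISTRY",
    "convective_coefficient",
    "convective_flux",
    "CondensateStore",
    "lewis_mass_flux",
    "SoilColumn",
    "soil_conduction_step",
    "PipeNetwork",
    "pipe_node_derivative",
]


# ---------------------------------------------------------------------------
# Convection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvectionCorrelation:
    """Named convective-coefficient law h(dT, L, wind) in W m-2 K-1."""
    name: str
    fn: Callable[[float, float, float], float]
    orientation: str = "any"

    def h(self, dT: float, L: float = 1.0, wind: float = 0.0) -> float:
        val = self.fn(dT, L, wind)
        return max(val, 0.0)


def _h_horizontal(dT: float, L: float, wind: float) -> float:
    # dT = T_surface - T_air for a surface below the air (floor-like):
    # positive dT is buoyancy-unstable, negative is stably stratified
    if dT >= 0:
        return 1.7 * dT ** (1.0 / 3.0)
    return 0.8 * abs(dT) ** 0.25


def _h_horizontal_down(dT: float, L: float, wind: float) -> float:
    # surface above the air (screen underside, roof underside):
    # cold surface below-air-temperature drives unstable convection
    if dT <= 0:
        return 1.7 * abs(dT) ** (1.0 / 3.0)
    return 0.8 * dT ** 0.25


def _h_vertical_still(dT: float, L: float, wind: float) -> float:
    return 1.42 * (abs(dT) / max(L, 0.1)) ** 0.25


def _h_roof_exterior(dT: float, L: float, wind: float) -> float:
    # wind-driven law for a Venlo roof exterior; linear at low wind
    if wind < 4.0:
        return 2.8 + 1.2 * wind
    return 2.5 * wind ** 0.8


def _h_wall_exterior_tarp(dT: float, L: float, wind: float) -> float:
    return 1.31 * abs(dT) ** (1.0 / 3.0) + 2.38 * wind ** 0.89


def _h_pipe(dT: float, L: float, wind: float) -> float:
    # free convection around a horizontal cylinder of diameter L
    return 1.28 * (abs(dT) / max(L, 0.01)) ** 0.25


def _h_cavity(dT: float, L: float, wind: float) -> float:
    # curtain-glass vertical cavity: conduction floor + convective term
    return max(1.2, 1.25 * abs(dT) ** (1.0 / 3.0))


CONVECTION_REGISTRY: dict[str, ConvectionCorrelation] = {
    "horizontal_up": ConvectionCorrelation("horizontal_up", _h_horizontal, "up"),
    "horizontal_down": ConvectionCorrelation("horizontal_down", _h_horizontal_down, "down"),
    "vertical_still": ConvectionCorrelation("vertical_still", _h_vertical_still, "vertical"),
    "roof_exterior": ConvectionCorrelation("roof_exterior", _h_roof_exterior, "exterior"),
    "wall_exterior_tarp": ConvectionCorrelation("wall_exterior_tarp",
                                                _h_wall_exterior_tarp, "exterior"),
    "pipe": ConvectionCorrelation("pipe", _h_pipe, "cylinder"),
    "cavity": ConvectionCorrelation("cavity", _h_cavity, "vertical"),
}


def convective_coefficient(correlation: str, dT: float, L: float = 1.0,
                           wind: float = 0.0) -> float:
    corr = CONVECTION_REGISTRY.get(correlation)
    if corr is None:
        raise KeyError(f"unregistered convection correlation {correlation!r}")
    return corr.h(dT, L, wind)


def convective_flux(correlation: str, area: float, T_surf: float, T_air: float,
                    L: float = 1.0, wind: float = 0.0) -> float:
    """Convective heat flow surface -> air (W), h from the named law."""
    dT = T_surf - T_air
    return convective_coefficient(correlation, dT, L, wind) * area * dT


# ---------------------------------------------------------------------------
# Lewis-analogy surface condensation / evaporation
# ---------------------------------------------------------------------------

@dataclass
class CondensateStore:
    """Liquid water held on a surface (kg) with cumulative accounting."""
    surface: str
    mass: float = 0.0
    cum_condensed: float = 0.0
    cum_evaporated: float = 0.0

    def apply(self, mass_rate: float, dt: float) -> None:
        """Integrate a condensation(+)/evaporation(-) rate over dt."""
        dm = mass_rate * dt
        if dm >= 0:
            self.cum_condensed += dm
        else:
            dm = max(dm, -self.mass)
            self.cum_evaporated += -dm
        self.mass = max(self.mass + dm, 0.0)


def lewis_mass_flux(T_surf: float, air: MoistAirState, h_conv: float,
                    area: float, store: CondensateStore | None = None,
                    evap_timescale: float = 600.0) -> float:
    """Surface water vapour exchange rate (kg s-1): condensation positive,
    evaporation negative and limited by the store content.

    Mass transfer coefficient from the Lewis analogy
    ``k_m = h / (rho * cp * Le^(2/3))`` (m s-1); driving force is the
    humidity-ratio difference between the zone air and saturation at the
    surface temperature.  When evaporating, the rate is additionally
    capped at store.mass/evap_timescale so the store drains smoothly.
    """
    rho = air.rho
    k_m = h_conv / (rho * CP_DRY_AIR * LEWIS_NUMBER ** (2.0 / 3.0))
    x_air = air.x_w
    p_sat_s = saturation_pressure(T_surf)
    if p_sat_s >= air.p:
        return 0.0
    x_sat = humidity_ratio_from_pw(p_sat_s, air.p)
    rate = area * k_m * rho * (x_air - x_sat)
    if rate < 0.0:
        available = store.mass if store is not None else 0.0
        rate = max(rate, -available / evap_timescale)
    return rate


def latent_heat_to_surface(mass_rate: float) -> float:
    """Latent heat deposited on (condensation) or taken from (evaporation)
    the surface, W."""
    return mass_rate * LATENT_HEAT_VAPORIZATION


# ---------------------------------------------------------------------------
# Soil column
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SoilColumn:
    """1-D soil column below the floor slab: layer thicknesses (m),
    conductivities (W m-1 K-1), volumetric heat capacities (J m-3 K-1) and
    a fixed deep boundary temperature (K)."""
    thicknesses: tuple[float, ...] = (0.02, 0.04, 0.08, 0.16, 0.32)
    conductivities: tuple[float, ...] = (1.4, 1.4, 1.2, 1.2, 1.2)
    heat_capacities: tuple[float, ...] = (2.0e6, 2.0e6, 1.8e6, 1.8e6, 1.8e6)
    T_deep: float = 285.15

    def __post_init__(self):
        n = len(self.thicknesses)
        if n < 2:
            raise ValueError("soil column needs at least 2 layers")
        if (len(self.conductivities) != n or len(self.heat_capacities) != n):
            raise ValueError("per-layer property lengths disagree")
        if (min(self.thicknesses) <= 0 or min(self.conductivities) <= 0
                or min(self.heat_capacities) <= 0):
            raise ValueError("soil properties must be positive")

    @property
    def n_layers(self) -> int:
        return len(self.thicknesses)

    def steady_flux(self, T_top: float) -> float:
        """Series-resistance steady conduction flux top->deep (W m-2)."""
        R = sum(d / k for d, k in zip(self.thicknesses, self.conductivities))
        return (T_top - self.T_deep) / R


def soil_conduction_step(column: SoilColumn, T_layers: np.ndarray,
                         T_floor: float) -> tuple[np.ndarray, float]:
    """Finite-volume conduction through the column.

    Returns (dT/dt per layer, flux floor->soil in W m-2).  Node j sits at
    the centre of layer j; the top boundary is the floor surface
    temperature, the bottom a fixed deep temperature.
    """
    d = np.asarray(column.thicknesses)
    k = np.asarray(column.conductivities)
    C = np.asarray(column.heat_capacities) * d      # J m-2 K-1 per layer
    n = column.n_layers
    # interface resistances
    R = np.empty(n + 1)
    R[0] = 0.5 * d[0] / k[0]
    for j in range(1, n):
        R[j] = 0.5 * d[j - 1] / k[j - 1] + 0.5 * d[j] / k[j]
    R[n] = 0.5 * d[n - 1] / k[n - 1]
    T_ext = np.concatenate([[T_floor], T_layers, [column.T_deep]])
    q = (T_ext[:-1] - T_ext[1:]) / R                 # positive downward
    dTdt = (q[:-1] - q[1:]) / C
    return dTdt, float(q[0])


# ---------------------------------------------------------------------------
# Heating pipes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipeNetwork:
    """Lumped-capacity heating pipe loop network."""
    name: str
    area: float              # total exchange surface, m2
    diameter: float          # m
    heat_capacity: float     # J K-1 (steel + water content)
    emissivity: float = 0.88

    def __post_init__(self):
        if min(self.area, self.diameter, self.heat_capacity) <= 0:
            raise ValueError("pipe network properties must be positive")


def pipe_node_derivative(pipe: PipeNetwork, T_pipe: float, Q_injected: float,
                         Q_conv_out: float, Q_rad_out: float) -> float:
    """dT/dt of a lumped pipe node: injection minus convective and
    radiative emission over the thermal capacity."""
    if Q_injected < 0:
        raise ValueError("injected heat must be >= 0")
    return (Q_injected - Q_conv_out - Q_rad_out) / pipe.heat_capacity
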