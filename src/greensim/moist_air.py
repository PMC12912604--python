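"""Isochoric moist-air zones with explicit internal-energy and species-mass states.

Each greenhouse air zone (MainAir, TopAir) is a perfectly stirred,
constant-volume tank holding dry air, water vapour and CO2.  The energy
balance is written on the internal energy U (J) so that pressure-driven
mass exchange through the envelope closes the species balances exactly;
the usual isobaric ``rho*V*cp*dT/dt`` shortcut is not used.

State variables: U, M_dair, M_w, M_co2.  Everything else (T, p, RH,
density, specific enthalpy) is derived through the ideal-gas mixture
relations with constant per-species specific heats (see ``constants``).
CO2 is carried as a mass state for balance accounting but its partial
pressure is neglected in the total pressure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .constants import (
    CP_CO2,
    CP_DRY_AIR,
    CP_WATER_VAPOR,
    EPS_W,
    LATENT_HEAT_VAPORIZATION,
    R_CO2,
    R_DRY_AIR,
    R_WATER,
    T_REF_K,
)

__all__ = [
    "MoistAirState",
    "saturation_pressure",
    "state_from_TRH",
    "zone_derivatives",
    "humidity_ratio_from_pw",
    "absolute_humidity",
]


def saturation_pressure(T: float) -> float:
    """Saturation vapour pressure over liquid water, Pa.

    Magnus form (Alduchov & Eskridge coefficients), valid 173-373 K.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 173.0) or np.any(T >= 373.0):
        raise ValueError(f"temperature {T} K outside Magnus validity range (173, 373) K")
    t = T - T_REF_K
    out = 610.94 * np.exp(17.625 * t / (t + 243.04))
    return float(out) if out.ndim == 0 else out


def humidity_ratio_from_pw(p_w: float, p: float) -> float:
    """Humidity ratio x_w (kg_w per kg dry air) from vapour pressure."""
    if p_w >= p:
        raise ValueError(f"vapour pressure {p_w} Pa >= total pressure {p} Pa")
    return EPS_W * p_w / (p - p_w)


@dataclass
class MoistAirState:
    """An isochoric moist-air volume.

    The four extensive quantities (U, M_dair, M_w, M_co2) are the ODE
    states; temperature is recovered in closed form because U is affine
    in T for the constant-cp caloric model.
    """

    V: float                     # m3, constant
    U: float                     # J
    M_dair: float                # kg
    M_w: float                   # kg
    M_co2: float = 0.0           # kg
    name: str = field(default="zone", compare=False)

    # ---- derived properties -------------------------------------------------
    @property
    def T(self) -> float:
        """Temperature (K), from U = H - pV with H affine in T."""
        a = self.M_dair * CP_DRY_AIR + self.M_w * CP_WATER_VAPOR + self.M_co2 * CP_CO2
        c = self.M_dair * R_DRY_AIR + self.M_w * R_WATER
        # U = a*(T - Tref) + M_w*L0 - c*T
        return (self.U - self.M_w * LATENT_HEAT_VAPORIZATION + a * T_REF_K) / (a - c)

    @property
    def p_dair(self) -> float:
        return self.M_dair * R_DRY_AIR * self.T / self.V

    @property
    def p_w(self) -> float:
        return self.M_w * R_WATER * self.T / self.V

    @property
    def p_co2(self) -> float:
        return self.M_co2 * R_CO2 * self.T / self.V

    @property
    def p(self) -> float:
        """Total pressure (Pa), Dalton over dry air + vapour (CO2 neglected)."""
        return self.p_dair + self.p_w

    @property
    def x_w(self) -> float:
        return self.M_w / self.M_dair

    @property
    def RH(self) -> float:
        return self.p_w / saturation_pressure(self.T)

    @property
    def co2_ppm(self) -> float:
        return 1e6 * self.p_co2 / self.p

    @property
    def rho(self) -> float:
        """Moist air density including CO2 mass, kg m-3."""
        return (self.M_dair + self.M_w + self.M_co2) / self.V

    @property
    def h(self) -> float:
        """Moist-air specific enthalpy per kg dry air, J kg_dair-1."""
        t = self.T - T_REF_K
        return (CP_DRY_AIR * t
                + self.x_w * (LATENT_HEAT_VAPORIZATION + CP_WATER_VAPOR * t)
                + (self.M_co2 / self.M_dair) * CP_CO2 * t)

    @property
    def H(self) -> float:
        """Enthalpy H = U + p*V (J)."""
        return self.U + self.p * self.V

    # ---- constructors -------------------------------------------------------
    def masses(self) -> np.ndarray:
        return np.array([self.M_dair, self.M_w, self.M_co2])

    def copy_with(self, U=None, M_dair=None, M_w=None, M_co2=None) -> "MoistAirState":
        return MoistAirState(
            V=self.V,
            U=self.U if U is None else U,
            M_dair=self.M_dair if M_dair is None else M_dair,
            M_w=self.M_w if M_w is None else M_w,
            M_co2=self.M_co2 if M_co2 is None else M_co2,
            name=self.name,
        )


def _energy_from_T(T: float, M_dair: float, M_w: float, M_co2: float) -> float:
    """Internal energy (J) consistent with MoistAirState.T."""
    t = T - T_REF_K
    a = M_dair * CP_DRY_AIR + M_w * CP_WATER_VAPOR + M_co2 * CP_CO2
    c = M_dair * R_DRY_AIR + M_w * R_WATER
    return a * t + M_w * LATENT_HEAT_VAPORIZATION - c * T


def state_from_TRH(T: float, RH: float, p: float, V: float,
                   C_co2_ppm: float = 400.0, name: str = "zone") -> MoistAirState:
    """Build a zone state from temperature (K), relative humidity (0-1),
    total pressure (Pa), volume (m3) and CO2 volumetric concentration (ppm)."""
    if not 0.0 <= RH <= 1.0:
        raise ValueError(f"RH={RH} outside [0, 1]")
    p_w = RH * saturation_pressure(T)
    if p_w >= p:
        raise ValueError("vapour pressure exceeds total pressure")
    p_da = p - p_w
    M_dair = p_da * V / (R_DRY_AIR * T)
    M_w = p_w * V / (R_WATER * T)
    p_c = C_co2_ppm * 1e-6 * p
    M_co2 = p_c * V / (R_CO2 * T)
    U = _energy_from_T(T, M_dair, M_w, M_co2)
    return MoistAirState(V=V, U=U, M_dair=M_dair, M_w=M_w, M_co2=M_co2, name=name)


def species_enthalpy_flux(mdot_dair: float, mdot_w: float, mdot_co2: float,
                          T_carrier: float) -> float:
    """Enthalpy flux (W) carried by a species mass-flow triplet at T_carrier (K)."""
    t = T_carrier - T_REF_K
    return (mdot_dair * CP_DRY_AIR * t
            + mdot_w * (LATENT_HEAT_VAPORIZATION + CP_WATER_VAPOR * t)
            + mdot_co2 * CP_CO2 * t)


def zone_derivatives(state: MoistAirState,
                     heat_flows: Iterable[float] = (),
                     mass_flows: Sequence[tuple] = ()) -> tuple[float, np.ndarray]:
    """Time derivatives (dU/dt, dM_i/dt) of a zone.

    ``heat_flows``: sensible/latent heat flows in W, signed toward the zone.
    ``mass_flows``: tuples (mdot_dair, mdot_w, mdot_co2, T_carrier_K), each
    signed toward the zone; the enthalpy they carry (including flow work,
    i.e. the full enthalpy h) is added to dU/dt.
    """
    dU = float(sum(heat_flows))
    dM = np.zeros(3)
    for (md, mw, mc, Tc) in mass_flows:
        dM += (md, mw, mc)
        dU += species_enthalpy_flux(md, mw, mc, Tc)
    return dU, dM


def absolute_humidity(state: MoistAirState) -> float:
    """Water vapour density (kg m-3), for g m-3 humidity metrics."""
    return state.M_w / state.V
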