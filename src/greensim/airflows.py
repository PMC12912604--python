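"""Volumetric airflows (roof vents, cracks, screen gaps) and their
conversion to species-mass and sensible-heat flows between air zones.

Natural ventilation superposes a buoyancy term (density difference across
the vent, Boussinesq-free since zone densities are explicit states) and a
wind term built on empirical ventilation functions G(delta) specific to
the vent configuration; the two aggregates combine in quadrature.  Vents
commanded closed still leak through an equivalent opening height.
Envelope cracks follow the building-physics power law F = eta*|dP|^n.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .constants import (CP_CO2, CP_DRY_AIR, CP_WATER_VAPOR, GRAVITY,
                        M_CO2, M_DRY_AIR, M_WATER, R_GAS, T_REF_K)
from .moist_air import MoistAirState

__all__ = [
    "VentConfig",
    "CrackConfig",
    "ScreenGapConfig",
    "VENTILATION_FUNCTIONS",
    "buoyancy_vent_flow",
    "ventilation_function",
    "wind_vent_flow",
    "total_vent_flow",
    "vent_leak_equivalent_angle",
    "vent_leak_flow",
    "crack_flow",
    "screen_gap_flow",
    "volumetric_to_species_flows",
    "species_to_sensible_heat",
    "wind_at_roof_height",
]


# ---------------------------------------------------------------------------
# Configurations
# ---------------------------------------------------------------------------

def _gl_de_zwart(delta: float) -> float:
    return 2.46e-2 * (1.0 - math.exp(-delta / 14.5))


def _gw_de_zwart(delta: float) -> float:
    return -1.89e-5 * delta ** 2 + 2.23e-3 * delta


# registry of published ventilation-function sets, keyed by source name
VENTILATION_FUNCTIONS: dict[str, dict[str, object]] = {
    "dezwart_venlo_alternating": {"leeward": _gl_de_zwart, "windward": _gw_de_zwart},
}


@dataclass(frozen=True)
class VentConfig:
    """Roof-vent geometry and aggregation.

    ``N_L``/``N_W``: leeward/windward openings per m2 of greenhouse floor;
    ``h_vent_leak``: equivalent residual opening height (mm) of a closed
    vent; ``function_set``: registry key of the ventilation functions.
    """
    L_O: float = 1.5          # vent length, m
    H_O: float = 0.8          # vent height, m
    C_f: float = 0.6          # discharge coefficient
    N_L: float = 0.0208       # openings per m2 floor
    N_W: float = 0.0208
    psi_r: float = 22.0       # roof slope, deg
    h_vent_leak: float = 6.0  # mm
    function_set: str = "dezwart_venlo_alternating"
    superposition: str = "quadrature"   # or "sum"

    def __post_init__(self):
        if min(self.L_O, self.H_O, self.C_f) <= 0 or min(self.N_L, self.N_W) < 0:
            raise ValueError("vent dimensions/coefficients must be positive")
        if self.h_vent_leak < 0:
            raise ValueError("h_vent_leak must be >= 0")
        if self.function_set not in VENTILATION_FUNCTIONS:
            raise ValueError(f"unknown ventilation function set {self.function_set!r}")
        if self.superposition not in ("quadrature", "sum"):
            raise ValueError("superposition must be 'quadrature' or 'sum'")


@dataclass(frozen=True)
class CrackConfig:
    """Power-law crack: F = sign(dP) * eta * |dP|^n."""
    eta: float                 # m3 s-1 Pa^-n
    n: float = 0.65
    connects: tuple[str, str] = ("zone", "outdoor")

    def __post_init__(self):
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if not 0.5 <= self.n <= 1.0:
            raise ValueError("flow exponent n must lie in [0.5, 1]")


@dataclass(frozen=True)
class ScreenGapConfig:
    """Airflow across the horizontal two-screen system.

    ``g_thermal``/``g_shading``: fabric permeances (m3 s-1 m-2 Pa-1);
    ``free_coeff``: free-opening exchange coefficient (m3 s-1 m-2 Pa-1/2)
    for undeployed states; ``g_edge``: always-present edge-leak permeance.
    """
    g_thermal: float = 1.0e-3
    g_shading: float = 2.0e-3
    free_coeff: float = 0.05
    g_edge: float = 2.0e-4
    area: float = 1037.0       # m2 of screen plane

    def __post_init__(self):
        if min(self.g_thermal, self.g_shading, self.free_coeff, self.g_edge) < 0:
            raise ValueError("screen-gap conductances must be >= 0")


# ---------------------------------------------------------------------------
# Roof vents
# ---------------------------------------------------------------------------

def _opening_term(delta_deg: float, cfg: VentConfig) -> float:
    """H_O * (sin psi - sin(psi - delta)), the vertical opening extent (m)."""
    psi = math.radians(cfg.psi_r)
    d = math.radians(delta_deg)
    return cfg.H_O * (math.sin(psi) - math.sin(psi - d))


def buoyancy_vent_flow(delta_deg: float, cfg: VentConfig,
                       rho_top: float, rho_out: float) -> float:
    """Buoyancy-driven volumetric flow through one vent (m3 s-1)."""
    if delta_deg < 0 or delta_deg > 44.0:
        warnings.warn(f"vent angle {delta_deg} deg outside [0, 44]; clamped")
        delta_deg = min(max(delta_deg, 0.0), 44.0)
    if delta_deg == 0.0:
        return 0.0
    rho_ref = 0.5 * (rho_top + rho_out)
    drho = abs(rho_top - rho_out)
    if drho == 0.0:
        return 0.0
    opening = max(_opening_term(delta_deg, cfg), 0.0)
    return (cfg.C_f * cfg.L_O * opening ** 1.5 / 3.0
            * math.sqrt(GRAVITY * drho / rho_ref))


def ventilation_function(delta_deg: float, side: str,
                         function_set: str = "dezwart_venlo_alternating") -> float:
    """Dimensionless wind-driven ventilation function G(delta)."""
    funcs = VENTILATION_FUNCTIONS.get(function_set)
    if funcs is None:
        raise ValueError(f"unknown ventilation function set {function_set!r}")
    if side not in funcs:
        raise ValueError(f"unknown vent side {side!r}")
    return funcs[side](delta_deg)   # type: ignore[operator]


def wind_vent_flow(delta_deg: float, cfg: VentConfig, U_wind_r: float,
                   side: str) -> float:
    """Wind-driven volumetric flow through one vent (m3 s-1), linear in wind."""
    if U_wind_r < 0:
        raise ValueError("wind speed must be >= 0")
    G = ventilation_function(delta_deg, side, cfg.function_set)
    return cfg.L_O * cfg.H_O * G * U_wind_r


def total_vent_flow(delta_L: float, delta_W: float, cfg: VentConfig,
                    rho_top: float, rho_out: float, U_wind_r: float) -> float:
    """Total roof-vent airflow per m2 of floor (m3 s-1 m-2): quadrature
    superposition of the buoyancy and wind aggregates over the leeward and
    windward vent populations."""
    B = (cfg.N_L * buoyancy_vent_flow(delta_L, cfg, rho_top, rho_out)
         + cfg.N_W * buoyancy_vent_flow(delta_W, cfg, rho_top, rho_out))
    W = (cfg.N_L * wind_vent_flow(delta_L, cfg, U_wind_r, "leeward")
         + cfg.N_W * wind_vent_flow(delta_W, cfg, U_wind_r, "windward"))
    if cfg.superposition == "quadrature":
        return math.hypot(B, W)
    return B + W


def vent_leak_equivalent_angle(cfg: VentConfig) -> float:
    """Opening angle (deg) whose vertical opening extent equals the
    residual leak height of a nominally closed vent."""
    h = cfg.h_vent_leak * 1e-3
    if h <= 0.0:
        return 0.0
    if _opening_term(44.0, cfg) < h:
        return 44.0
    return brentq(lambda d: _opening_term(d, cfg) - h, 0.0, 44.0, xtol=1e-9)


def vent_leak_flow(cfg: VentConfig, rho_top: float, rho_out: float,
                   U_wind_r: float) -> float:
    """Airflow per m2 floor through vents commanded closed (m3 s-1 m-2)."""
    d_eq = vent_leak_equivalent_angle(cfg)
    if d_eq == 0.0:
        return 0.0
    return total_vent_flow(d_eq, d_eq, cfg, rho_top, rho_out, U_wind_r)


# ---------------------------------------------------------------------------
# Cracks and screen gaps
# ---------------------------------------------------------------------------

def crack_flow(dP: float, cfg: CrackConfig, smooth_pa: float = 0.0) -> float:
    """Power-law crack flow (m3 s-1), odd in the pressure difference.

    ``smooth_pa`` > 0 regularises the non-Lipschitz corner at dP = 0
    (F = eta * dP * (dP^2 + eps^2)^((n-1)/2)), leaving the law unchanged
    for |dP| >> eps; stiff integrators need the smooth variant.
    """
    if dP == 0.0:
        return 0.0
    if smooth_pa > 0.0:
        return cfg.eta * dP * (dP * dP + smooth_pa * smooth_pa) ** ((cfg.n - 1) / 2)
    return math.copysign(cfg.eta * abs(dP) ** cfg.n, dP)


def screen_gap_flow(u_thermal: float, u_shading: float, dP: float,
                    cfg: ScreenGapConfig, smooth_pa: float = 0.0) -> float:
    """Airflow across the horizontal screen system (m3 s-1, signed with dP).

    The two continuously managed screens define four deployment states;
    the flow is the superposition of the per-state flows weighted by the
    state probabilities (1-u1)(1-u2), u1(1-u2), (1-u1)u2, u1u2.  In the
    both-deployed state the fabric permeances combine in series; free
    states follow a square-root free-opening law; an edge leak is always
    present.
    """
    for u in (u_thermal, u_shading):
        if not 0.0 <= u <= 1.0:
            raise ValueError("screen deployment outside [0, 1]")
    sgn = math.copysign(1.0, dP) if dP else 0.0
    adp = abs(dP)
    if smooth_pa > 0.0:
        f_free = cfg.free_coeff * adp / (adp * adp + smooth_pa * smooth_pa) ** 0.25
    else:
        f_free = cfg.free_coeff * math.sqrt(adp)
    f_th = cfg.g_thermal * adp
    f_sh = cfg.g_shading * adp
    if cfg.g_thermal + cfg.g_shading > 0:
        g_ser = (cfg.g_thermal * cfg.g_shading
                 / (cfg.g_thermal + cfg.g_shading))
    else:
        g_ser = 0.0
    f_both = g_ser * adp
    w00 = (1 - u_thermal) * (1 - u_shading)
    w10 = u_thermal * (1 - u_shading)
    w01 = (1 - u_thermal) * u_shading
    w11 = u_thermal * u_shading
    per_area = (w00 * f_free + w10 * f_th + w01 * f_sh + w11 * f_both
                + cfg.g_edge * adp)
    return sgn * per_area * cfg.area


# ---------------------------------------------------------------------------
# Conversion to species and heat flows
# ---------------------------------------------------------------------------

_MOLAR = np.array([M_DRY_AIR, M_WATER, M_CO2])
_CP = np.array([CP_DRY_AIR, CP_WATER_VAPOR, CP_CO2])


def _gross_species_rate(F: float, state: MoistAirState) -> np.ndarray:
    """Species mass flow (kg s-1) carried by a volumetric flow F out of a
    zone: F * (M_i/R) * p_i / T."""
    p_i = np.array([state.p_dair, state.p_w, state.p_co2])
    return F * _MOLAR / R_GAS * p_i / state.T


def volumetric_to_species_flows(F: float, state1: MoistAirState,
                                state2: MoistAirState, mode: str = "bilateral"
                                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert a volumetric airflow into species mass flows.

    Returns (net_1to2, gross_leaving_1, gross_leaving_2), each a
    (dry air, vapour, CO2) array in kg s-1.  ``bilateral`` (vents,
    screens): both zones exchange the full volume flow (F >= 0).
    ``unilateral`` (cracks): the flow direction follows the total-pressure
    ordering; F is signed (positive means the pressure gradient pushes
    from zone 1 to zone 2).
    """
    if mode == "bilateral":
        if F < 0:
            raise ValueError("bilateral flow must be >= 0")
        g1 = _gross_species_rate(F, state1)
        g2 = _gross_species_rate(F, state2)
    elif mode == "unilateral":
        k1 = 1.0 if state1.p > state2.p else 0.0
        g1 = _gross_species_rate(abs(F), state1) * k1
        g2 = _gross_species_rate(abs(F), state2) * (1.0 - k1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return g1 - g2, g1, g2


def species_to_sensible_heat(gross1: np.ndarray, gross2: np.ndarray,
                             T1_C: float, T2_C: float) -> float:
    """Net sensible heat (W) from zone 1 to zone 2 carried by the gross
    species flows, per-species cp with temperatures in Celsius."""
    return float(np.sum(gross1 * _CP * T1_C) - np.sum(gross2 * _CP * T2_C))


def wind_at_roof_height(U_8m: float, roof_height: float,
                        roughness: float = 0.03) -> float:
    """Log-profile conversion of the 8 m mast wind to roof height."""
    if U_8m < 0:
        raise ValueError("wind speed must be >= 0")
    if roof_height <= roughness:
        return 0.0
    return U_8m * math.log(roof_height / roughness) / math.log(8.0 / roughness)
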