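"""Short-wave distribution across the indoor horizontal layer stack.

Once solar irradiance has entered through the roof (and south wall) it is
shared between the roof underside, the shading screen, the thermal
screen, the canopy and the floor.  Each layer is an abstract two-face
optical element (independent down/up transmittance and reflectance); two
layers combine through the infinite inter-reflection geometric series,
and a whole stack is resolved exactly with a backward effective-
reflectance sweep followed by a forward flux sweep.  Everything is done
per waveband (PAR and NIR carry separate layer properties).

Screens deployed over a fraction ``u`` of the span are areal mixtures:
``u`` of screen fabric and ``1-u`` of free opening.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .roof_optics import GlazingOptics, glass_direct_coefficients
from .weather import SunPosition

__all__ = [
    "LayerOpticalProps",
    "CanopyOptics",
    "WallConfig",
    "canopy_layer_transmittance",
    "canopy_layer_props",
    "screen_effective_layer",
    "combine_two_layers",
    "stack_absorption",
    "glass_hemispherical_coefficients",
    "south_wall_gain",
]


@dataclass(frozen=True)
class LayerOpticalProps:
    """Two-face optical layer: ``*_down`` applies to downward-travelling
    flux hitting the top face, ``*_up`` to upward flux hitting the bottom."""
    tau_down: float
    tau_up: float
    rho_down: float
    rho_up: float
    name: str = "layer"

    def __post_init__(self):
        for t, r, face in ((self.tau_down, self.rho_down, "down"),
                           (self.tau_up, self.rho_up, "up")):
            if t < -1e-12 or r < -1e-12 or t + r > 1.0 + 1e-9:
                raise ValueError(f"layer {self.name}: tau+rho > 1 on face {face}")

    @property
    def abs_down(self) -> float:
        return 1.0 - self.tau_down - self.rho_down

    @property
    def abs_up(self) -> float:
        return 1.0 - self.tau_up - self.rho_up

    @classmethod
    def symmetric(cls, tau: float, rho: float, name: str = "layer"):
        return cls(tau, tau, rho, rho, name=name)


IDENTITY_LAYER = LayerOpticalProps(1.0, 1.0, 0.0, 0.0, name="identity")


@dataclass(frozen=True)
class CanopyOptics:
    """Canopy extinction per band with the cultivated-area ratio r_cul:
    the canopy covers only the cropped share of the floor, the alleyway
    share (1 - r_cul) passes light unattenuated."""
    K_PAR: float = 0.7
    K_NIR: float = 0.27
    LAI: float = 0.0
    r_cul: float = 0.91
    rho_leaf_PAR: float = 0.07
    rho_leaf_NIR: float = 0.35

    def __post_init__(self):
        if self.K_PAR <= 0 or self.K_NIR <= 0:
            raise ValueError("extinction coefficients must be > 0")
        if self.LAI < 0:
            raise ValueError("LAI must be >= 0")
        if not 0 < self.r_cul <= 1:
            raise ValueError("r_cul must lie in (0, 1]")


def canopy_layer_transmittance(c: CanopyOptics, band: str = "PAR") -> float:
    """Beer-Lambert canopy transmittance diluted by the alleyway share:
    ``r_cul * exp(-K * LAI) + (1 - r_cul)``."""
    K = c.K_PAR if band == "PAR" else c.K_NIR
    return c.r_cul * math.exp(-K * c.LAI) + (1.0 - c.r_cul)


def canopy_layer_props(c: CanopyOptics, band: str = "PAR") -> LayerOpticalProps:
    """Two-face canopy layer for the stack: symmetric faces, reflectance
    from the leaf albedo weighted by the intercepted fraction."""
    tau = canopy_layer_transmittance(c, band)
    rho_leaf = c.rho_leaf_PAR if band == "PAR" else c.rho_leaf_NIR
    K = c.K_PAR if band == "PAR" else c.K_NIR
    rho = c.r_cul * rho_leaf * (1.0 - math.exp(-K * c.LAI))
    return LayerOpticalProps.symmetric(tau, rho, name=f"canopy_{band}")


def screen_effective_layer(screen: LayerOpticalProps, u: float) -> LayerOpticalProps:
    """Areal mixture of deployed screen fabric (share u) and free opening."""
    if not 0.0 <= u <= 1.0:
        raise ValueError("deployment fraction outside [0, 1]")
    return LayerOpticalProps(
        tau_down=u * screen.tau_down + (1 - u),
        tau_up=u * screen.tau_up + (1 - u),
        rho_down=u * screen.rho_down,
        rho_up=u * screen.rho_up,
        name=f"{screen.name}@u={u:.2f}",
    )


def combine_two_layers(upper: LayerOpticalProps, lower: LayerOpticalProps
                       ) -> tuple[LayerOpticalProps, tuple[float, float]]:
    """Combine two stacked layers through the infinite inter-reflection
    series.  Returns the combined layer and the per-layer absorbed
    fractions (upper, lower) for a unit downward-incident flux.
    """
    denom = 1.0 - upper.rho_up * lower.rho_down
    if denom <= 1e-12:
        raise ValueError("singular stack: inter-face reflectances multiply to >= 1")
    S = upper.tau_down / denom             # net downward flux onto lower top
    tau_down = lower.tau_down * S
    rho_down = upper.rho_down + upper.tau_up * lower.rho_down * S
    S_up = lower.tau_up / denom            # net upward flux onto upper bottom
    tau_up = upper.tau_up * S_up
    rho_up = lower.rho_up + lower.tau_down * upper.rho_up * S_up
    combined = LayerOpticalProps(tau_down, tau_up, rho_down, rho_up,
                                 name=f"({upper.name}+{lower.name})")
    abs_upper = upper.abs_down + upper.abs_up * lower.rho_down * S
    abs_lower = lower.abs_down * S
    return combined, (abs_upper, abs_lower)


def stack_absorption(stack: list[LayerOpticalProps], I_in: float
                     ) -> dict[str, float]:
    """Resolve a top-to-bottom layer stack for a downward-incident flux
    ``I_in`` (W m-2 or W).  Returns per-layer absorbed fluxes keyed by
    layer name, plus ``reflected_out`` (back to the sky) and
    ``transmitted_below`` (below the last layer).

    Exact solution: backward sweep of effective substack reflectances,
    forward sweep of gap fluxes; conservation holds to machine precision.
    """
    n = len(stack)
    # R_eff[j]: reflectance (for downward flux) of layers j..n-1
    R_eff = np.zeros(n + 1)
    for j in range(n - 1, -1, -1):
        lay = stack[j]
        denom = 1.0 - lay.rho_up * R_eff[j + 1]
        if denom <= 1e-12:
            raise ValueError(f"singular stack at layer {lay.name}")
        R_eff[j] = lay.rho_down + lay.tau_down * lay.tau_up * R_eff[j + 1] / denom
    D = np.zeros(n + 1)   # downward flux in gap above layer j
    D[0] = I_in
    out: dict[str, float] = {}
    for j in range(n):
        lay = stack[j]
        denom = 1.0 - lay.rho_up * R_eff[j + 1]
        D[j + 1] = lay.tau_down * D[j] / denom
        U_below = R_eff[j + 1] * D[j + 1]
        out[lay.name] = lay.abs_down * D[j] + lay.abs_up * U_below
    out["reflected_out"] = R_eff[0] * I_in
    out["transmitted_below"] = D[n]
    return out


# ---------------------------------------------------------------------------
# South wall
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WallConfig:
    """Glazed wall treated as a large vertical window."""
    area: float = 168.0               # m2 (exposed glazed area)
    azimuth: float = 151.0            # deg from North of the outward normal
    frame_dirt_coeff: float = 0.9
    ground_albedo: float = 0.2
    glazing: GlazingOptics = GlazingOptics()
    curtain: LayerOpticalProps = LayerOpticalProps.symmetric(0.6, 0.3, "curtain")


_HEMI_CACHE: dict = {}


def glass_hemispherical_coefficients(optics: GlazingOptics) -> tuple[float, float]:
    """Hemispherical (diffuse) transmittance and reflectance of a pane:
    cosine-weighted average of the direct coefficients over the hemisphere."""
    key = optics.key()
    if key not in _HEMI_CACHE:
        thetas = np.linspace(0.0, math.pi / 2 - 1e-6, 200)
        taus, rhos = np.array([glass_direct_coefficients(t, optics)
                               for t in thetas]).T
        w = 2.0 * np.sin(thetas) * np.cos(thetas)
        _HEMI_CACHE[key] = (float(np.trapezoid(taus * w, thetas)),
                            float(np.trapezoid(rhos * w, thetas)))
    return _HEMI_CACHE[key]


def south_wall_gain(sun: SunPosition | None, wall: WallConfig,
                    I_dir: float, I_dif: float, I_glob: float,
                    u_curtain: float = 0.0) -> tuple[float, float, float]:
    """Solar gain through a glazed wall: (transmitted W, absorbed-in-glass W,
    absorbed-in-curtain W).

    Direct part: Fresnel at the wall incidence angle times the frame/dirt
    coefficient; diffuse part: isotropic half-sky plus a fixed ground
    albedo reflection, at hemispherical transmittance.  The curtain (areal
    deployment ``u_curtain``) is combined with the glass through the
    layer-stack algebra.  The transmitted flux joins the roof flux at the
    top of the indoor multilayer stack.
    """
    tau_hemi, rho_hemi = glass_hemispherical_coefficients(wall.glazing)
    c = wall.frame_dirt_coeff
    curtain_eff = screen_effective_layer(wall.curtain, u_curtain)

    def through(irr: float, tau_g: float, rho_g: float):
        glass_layer = LayerOpticalProps(tau_g * c, tau_g * c,
                                        rho_g, rho_g, name="wall_glass")
        combined, (a_glass, a_curt) = combine_two_layers(glass_layer, curtain_eff)
        return irr * combined.tau_down, irr * a_glass, irr * a_curt

    # diffuse: isotropic sky half-hemisphere + ground-reflected
    irr_dif = I_dif / 2.0 + wall.ground_albedo * I_glob / 2.0
    trans, a_g, a_c = through(irr_dif, tau_hemi, rho_hemi)

    if sun is not None and sun.above_horizon and I_dir > 0.0:
        cos_zen = math.cos(sun.zenith)
        cos_inc = math.sin(sun.zenith) * math.cos(sun.azimuth
                                                  - math.radians(wall.azimuth))
        if cos_inc > 0.0 and cos_zen > 1e-3:
            dni = I_dir / cos_zen
            tau_d, rho_d = glass_direct_coefficients(math.acos(min(1.0, cos_inc)),
                                                     wall.glazing)
            t2, g2, c2 = through(dni * cos_inc, tau_d, rho_d)
            trans, a_g, a_c = trans + t2, a_g + g2, a_c + c2

    A = wall.area
    return trans * A, a_g * A, a_c * A
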