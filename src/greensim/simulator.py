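"""Two-zone greenhouse assembly: ODE system, integration, metrics, balances.

The compartment is modelled as two perfectly stirred isochoric moist-air
zones (MainAir below the horizontal screens, TopAir above) coupled to a
network of surface temperature nodes (floor, canopy, two screens, roof,
south glass + curtain, corridor walls, three heating-pipe networks,
growing gutters), a 1-D soil column, per-surface condensate stores and
the crop pools.  Actuators (vent angles, screen positions, injected pipe
heat, measured CO2 concentration, corridor temperatures) are forcing
inputs, not controlled.

Integration is operator-split on the 5-min forcing cadence: short-wave
distribution, view factors and crop photosynthesis are frozen per step
(they vary on the weather time scale), the stiff thermal/mass ODE is
advanced within the step by a variable-step solver, and the crop pools
and discrete pruning events are applied at step boundaries.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import airflows as af
from . import crop as crop_mod
from .config import GreenhouseConfig, study_case_config
from .constants import (CP_CO2, CP_WATER_VAPOR, LATENT_HEAT_VAPORIZATION,
                        M_CO2, PAR_FRACTION, R_CO2, SIGMA_SB, T_REF_K)
from .indoor_optics import (LayerOpticalProps, CanopyOptics, canopy_layer_props,
                            screen_effective_layer, south_wall_gain,
                            stack_absorption, glass_hemispherical_coefficients)
from .moist_air import (MoistAirState, saturation_pressure, state_from_TRH,
                        species_enthalpy_flux)
from .radiation import (Scene, SurfaceNode, ViewFactorSet,
                        net_radiative_exchange, screen_medium_transmissivity,
                        sky_and_boundary_exchange, viewfactor_pipeline)
from .roof_optics import (RadianceModel, SkyDiscretization,
                          glass_direct_coefficients, roof_diffuse_transmittance,
                          roof_direct_transmittance)
from .surfaces import (CondensateStore, convective_coefficient,
                       lewis_mass_flux, soil_conduction_step)
from .weather import SunPosition, sky_temperature, solar_position_series

__all__ = [
    "GreenhouseModel",
    "SimulationResult",
    "build_system",
    "integrate",
    "synthesize_forcing",
    "weekly_pruning_table",
    "rmse", "rrmse", "mae", "evaluate", "daily_rmse",
    "water_balance", "co2_balance", "run_variant",
    "VARIANTS",
]

P_ATM = 101325.0

SURFACE_NAMES = ["floor", "canopy", "screen_thermal", "screen_shading",
                 "roof", "south_glass", "south_curtain", "north_wall",
                 "east_wall", "pipe_rail", "pipe_forcas", "pipe_pe", "gutters"]
CONDENSING = ["roof", "screen_thermal", "screen_shading", "south_glass",
              "south_curtain", "north_wall", "east_wall"]
LEDGER_NAMES = ["vent_vapor_out", "crack_vapor_out", "co2_vent_out",
                "co2_crack_out", "co2_injected", "co2_assimilated",
                "transpired", "heat_injected"]


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

def _variant_reference(cfg: GreenhouseConfig) -> GreenhouseConfig:
    return cfg


def _variant_c1(cfg: GreenhouseConfig) -> GreenhouseConfig:
    """South gable boundary ignored."""
    return dataclasses.replace(cfg, include_south_wall=False)


def _variant_c2(cfg: GreenhouseConfig) -> GreenhouseConfig:
    """Quasi-infinite greenhouse: no walls, no alleyways, constant cover
    transmittance (direct and diffuse undistinguished)."""
    return dataclasses.replace(
        cfg, include_south_wall=False, include_corridor_walls=False,
        r_cul=1.0, cultivated_area=cfg.floor_area,
        constant_cover_transmittance=0.78)


VARIANTS = {"reference": _variant_reference, "C1": _variant_c1, "C2": _variant_c2}


# ---------------------------------------------------------------------------
# View-factor scene for the compartment
# ---------------------------------------------------------------------------

_VF_CACHE: dict = {}


def _greenhouse_scene(cfg: GreenhouseConfig, crop_h: float, crop_w: float) -> Scene:
    """Reduced parametric radiation scene (screen plane excluded: screens
    act as media / dedicated nodes at run time; mixing ducts and the west
    wall are attributed to MainAir and carry no node)."""
    L, W, Hs = cfg.length, cfg.width, cfg.screen_height
    sc = Scene()

    def rect(x0, y0, x1, y1, z):
        return np.array([[x0, y0, z], [x1, y0, z], [x1, y1, z], [x0, y1, z]])

    def vert_x(y, x0, x1, z0, z1):
        # wall in a plane of constant y
        return np.array([[x0, y, z0], [x1, y, z0], [x1, y, z1], [x0, y, z1]])

    def vert_y(x, y0, y1, z0, z1):
        # wall in a plane of constant x (gable ends)
        return np.array([[x, y0, z0], [x, y1, z0], [x, y1, z1], [x, y0, z1]])

    sc.add("floor", rect(0, 0, L, W, 0.0))
    # canopy: slab of height crop_h and width crop_w*W centred in the house
    cw = max(min(crop_w, 0.95), 0.02) * W
    y0, y1 = (W - cw) / 2, (W + cw) / 2
    h = max(crop_h, 0.05)
    top = rect(1.0, y0, L - 1.0, y1, h)
    side1 = vert_x(y0, 1.0, L - 1.0, 0.4, h)
    side2 = vert_x(y1, 1.0, L - 1.0, 0.4, h)
    sc.add("canopy", np.stack([top, side1, side2]), occludes=True)
    sc.add("roof", rect(0, 0, L, W, Hs))   # roof plane seen from below
    sc.add("south_wall", vert_y(0.0, 0, W, 0, Hs))   # gable at x = 0
    sc.add("north_wall", vert_y(L, 0, W, 0, Hs))     # gable at x = L
    sc.add("east_wall", vert_x(0.0, 0, L, 0, Hs))
    # pipe networks and gutters as equivalent horizontal slabs
    def slab(name, area, z):
        wid = min(area / (L - 2.0), W - 2.0)
        yy0, yy1 = (W - wid) / 2, (W + wid) / 2
        sc.add(name, rect(1.0, yy0, L - 1.0, yy1, z))
    slab("pipe_rail", cfg.pipe_rail.area, 0.15)
    slab("pipe_forcas", cfg.pipe_forcas.area, 1.6)
    slab("pipe_pe", cfg.pipe_pe.area, 2.2)
    slab("gutters", cfg.gutters_area, 1.1)
    return sc


def _viewfactors(cfg: GreenhouseConfig) -> ViewFactorSet:
    key = (cfg.roof.key(), cfg.length, cfg.width, cfg.screen_height,
           cfg.vf_cell_size, cfg.pipe_rail.area, cfg.gutters_area)
    if key not in _VF_CACHE:
        _VF_CACHE[key] = viewfactor_pipeline(
            lambda h, w: _greenhouse_scene(cfg, h, w),
            crop_heights=(0.5, 2.0, 3.5), crop_widths=(0.3, 0.7),
            cell_size=cfg.vf_cell_size)
    return _VF_CACHE[key]


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class GreenhouseModel:
    cfg: GreenhouseConfig
    variant: str = "reference"
    vf: ViewFactorSet | None = None
    crop_state: crop_mod.CropState = field(default_factory=crop_mod.CropState)

    # ---- state vector layout ------------------------------------------------
    @property
    def n_states(self) -> int:
        return 8 + len(SURFACE_NAMES) + self.cfg.soil.n_layers \
            + len(CONDENSING) + len(LEDGER_NAMES)

    def index(self):
        i = {}
        i["main"] = slice(0, 4)
        i["top"] = slice(4, 8)
        base = 8
        for k, n in enumerate(SURFACE_NAMES):
            i[f"T_{n}"] = base + k
        base += len(SURFACE_NAMES)
        i["soil"] = slice(base, base + self.cfg.soil.n_layers)
        base += self.cfg.soil.n_layers
        for k, n in enumerate(CONDENSING):
            i[f"cond_{n}"] = base + k
        base += len(CONDENSING)
        for k, n in enumerate(LEDGER_NAMES):
            i[f"led_{n}"] = base + k
        return i

    # ---- areas / capacities -------------------------------------------------
    def surface_area(self, name: str) -> float:
        c = self.cfg
        return {
            "floor": c.floor_area,
            "canopy": c.cultivated_area,
            "screen_thermal": c.floor_area,
            "screen_shading": c.floor_area,
            "roof": c.roof_surface_area,
            "south_glass": c.south_wall.area if c.include_south_wall else 1.0,
            "south_curtain": c.south_wall.area if c.include_south_wall else 1.0,
            "north_wall": c.north_wall_area if c.include_corridor_walls else 1.0,
            "east_wall": c.east_wall_area if c.include_corridor_walls else 1.0,
            "pipe_rail": c.pipe_rail.area,
            "pipe_forcas": c.pipe_forcas.area,
            "pipe_pe": c.pipe_pe.area,
            "gutters": c.gutters_area,
        }[name]

    def heat_capacity(self, name: str, u_th: float, u_sh: float,
                      lai: float) -> float:
        c = self.cfg
        glass_cap = c.glazing.thickness * c.glass_density * c.glass_cp
        screen_cap = lambda sp, u: (max(u, 0.1) * c.floor_area
                                    * sp.area_density * sp.cp)
        return {
            "floor": 0.10 * 2000.0 * 880.0 * c.floor_area,
            "canopy": c.canopy_heat_capacity_per_lai * max(lai, 0.2)
                      * c.cultivated_area,
            "screen_thermal": screen_cap(c.thermal_screen, u_th),
            "screen_shading": screen_cap(c.shading_screen, u_sh),
            "roof": glass_cap * c.roof_surface_area,
            "south_glass": glass_cap * self.surface_area("south_glass"),
            "south_curtain": screen_cap(c.thermal_screen, 1.0)
                             * self.surface_area("south_curtain") / c.floor_area,
            "north_wall": 12600.0 * self.surface_area("north_wall"),
            "east_wall": 12600.0 * self.surface_area("east_wall"),
            "pipe_rail": c.pipe_rail.heat_capacity,
            "pipe_forcas": c.pipe_forcas.heat_capacity,
            "pipe_pe": c.pipe_pe.heat_capacity,
            "gutters": c.gutters_heat_capacity,
        }[name]

    def emissivity(self, name: str) -> float:
        c = self.cfg
        return {
            "floor": c.floor_emissivity, "canopy": c.canopy_emissivity,
            "screen_thermal": c.thermal_screen.emissivity,
            "screen_shading": c.shading_screen.emissivity,
            "roof": c.roof_emissivity, "south_glass": c.roof_emissivity,
            "south_curtain": c.thermal_screen.emissivity,
            "north_wall": c.wall_emissivity, "east_wall": c.wall_emissivity,
            "pipe_rail": c.pipe_rail.emissivity,
            "pipe_forcas": c.pipe_forcas.emissivity,
            "pipe_pe": c.pipe_pe.emissivity,
            "gutters": c.gutters_emissivity,
        }[name]

    # ---- initial state ------------------------------------------------------
    def initial_state(self, T_out_C: float, RH: float = 0.75,
                      co2_ppm: float = 430.0,
                      offsets: tuple[float, float, float] = (4.0, 3.0, 3.0)
                      ) -> np.ndarray:
        """State vector at first-measured-value conditions; ``offsets`` are
        the (MainAir, TopAir, surfaces) initial temperature offsets above
        outdoor (zeros give a uniform isothermal start for sealed tests)."""
        cfg = self.cfg
        T0 = T_out_C + T_REF_K
        o_main, o_top, o_surf = offsets
        y = np.zeros(self.n_states)
        ix = self.index()
        main = state_from_TRH(T0 + o_main, RH, P_ATM, cfg.main_air_volume,
                              co2_ppm)
        top = state_from_TRH(T0 + o_top, RH, P_ATM, cfg.top_air_volume,
                             co2_ppm)
        y[ix["main"]] = [main.U, main.M_dair, main.M_w, main.M_co2]
        y[ix["top"]] = [top.U, top.M_dair, top.M_w, top.M_co2]
        for n in SURFACE_NAMES:
            y[ix[f"T_{n}"]] = T0 + o_surf
        y[ix["soil"]] = np.linspace(T0 + o_surf, cfg.soil.T_deep,
                                    cfg.soil.n_layers)
        return y

    def zones(self, y: np.ndarray) -> tuple[MoistAirState, MoistAirState]:
        ix = self.index()
        m = y[ix["main"]]
        t = y[ix["top"]]
        main = MoistAirState(self.cfg.main_air_volume, m[0], m[1], m[2], m[3],
                             name="main")
        top = MoistAirState(self.cfg.top_air_volume, t[0], t[1], t[2], t[3],
                            name="top")
        return main, top


def build_system(cfg: GreenhouseConfig | None = None,
                 variant: str = "reference",
                 crop_state: crop_mod.CropState | None = None) -> GreenhouseModel:
    """Assemble the integrable model for a configuration and variant."""
    cfg = cfg or study_case_config()
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; options: {list(VARIANTS)}")
    cfg = VARIANTS[variant](cfg)
    model = GreenhouseModel(cfg=cfg, variant=variant)
    if crop_state is not None:
        model.crop_state = crop_state
    model.vf = _viewfactors(cfg)
    return model


# ---------------------------------------------------------------------------
# Per-step context: solar distribution, crop rates, boundary values
# ---------------------------------------------------------------------------

@dataclass
class StepContext:
    sun: SunPosition
    T_out: float            # K
    rho_out: float
    out_state: MoistAirState
    T_sky: float
    wind_roof: float
    forcing: dict
    sw_absorbed: dict       # W per node
    par_canopy: float       # W m-2 cultivated absorbed PAR
    assim_rate: float       # kg CO2 s-1 (whole house)
    co2_target_ppm: float
    ff: np.ndarray          # view-factor matrix over vf.names
    lai: float


def _solar_distribution(model: GreenhouseModel, sun: SunPosition, I_dir: float,
                        I_dif: float, I_glob: float, Ce: float,
                        u_th: float, u_sh: float, u_curt: float,
                        lai: float) -> tuple[dict, float]:
    cfg = model.cfg
    absorbed = {n: 0.0 for n in SURFACE_NAMES}
    if I_glob <= 0.5:
        return absorbed, 0.0
    if cfg.constant_cover_transmittance is not None:
        tau = cfg.constant_cover_transmittance
        enter = tau * I_glob * cfg.floor_area
        roof_abs = 0.0
        south_trans = south_abs_g = south_abs_c = 0.0
    else:
        tau_dir = roof_direct_transmittance(sun, cfg.roof, cfg.glazing,
                                            n_rays=48) if I_dir > 0 else 0.0
        model_sky = RadianceModel("all_sky", clear_sky_index=round(1.0 - Ce, 1),
                                  sun=SunPosition(sun.azimuth,
                                                  min(sun.zenith, math.pi / 2 - 1e-3)))
        tau_dif = roof_diffuse_transmittance(cfg.roof, cfg.glazing, model_sky,
                                             SkyDiscretization(10.0, 10.0),
                                             n_rays=24)
        enter = (tau_dir * I_dir + tau_dif * I_dif) * cfg.floor_area
        # glass absorption estimate (direct at incidence + hemispheric diffuse)
        if sun.above_horizon and I_dir > 0:
            th = min(sun.zenith, math.pi / 2 - 1e-3)
            t_d, r_d = glass_direct_coefficients(th, cfg.glazing)
            a_dir = max(1.0 - t_d - r_d, 0.0)
        else:
            a_dir = 0.0
        t_h, r_h = glass_hemispherical_coefficients(cfg.glazing)
        a_dif = max(1.0 - t_h - r_h, 0.0)
        roof_abs = (a_dir * I_dir + a_dif * I_dif) * cfg.floor_area
        south_trans = south_abs_g = south_abs_c = 0.0
        if cfg.include_south_wall:
            south_trans, south_abs_g, south_abs_c = south_wall_gain(
                sun, cfg.south_wall, I_dir, I_dif, I_glob, u_curt)
    absorbed["roof"] += roof_abs
    absorbed["south_glass"] += south_abs_g
    absorbed["south_curtain"] += south_abs_c
    total_in = enter + south_trans

    par_canopy = 0.0
    for band, frac in (("PAR", PAR_FRACTION), ("NIR", 1.0 - PAR_FRACTION)):
        stack = [
            screen_effective_layer(cfg.shading_screen.sw_layer(), u_sh),
            screen_effective_layer(cfg.thermal_screen.sw_layer(), u_th),
            canopy_layer_props(CanopyOptics(LAI=lai, r_cul=cfg.r_cul), band),
            LayerOpticalProps(0.0, 0.0,
                              1.0 - (cfg.floor_absorptance_PAR if band == "PAR"
                                     else cfg.floor_absorptance_NIR),
                              0.0, name="floor"),
        ]
        res = stack_absorption(stack, total_in * frac)
        absorbed["screen_shading"] += res[stack[0].name]
        absorbed["screen_thermal"] += res[stack[1].name]
        absorbed["canopy"] += res[stack[2].name]
        absorbed["floor"] += res["floor"]
        if band == "PAR":
            par_canopy = res[stack[2].name] / max(cfg.cultivated_area, 1.0)
    return absorbed, par_canopy


def make_step_context(model: GreenhouseModel, wrow: pd.Series,
                      frow: pd.Series, sun: SunPosition,
                      T_can: float) -> StepContext:
    cfg = model.cfg
    T_out = wrow.T_air_out + T_REF_K
    out_state = state_from_TRH(T_out, min(wrow.RH_air_out, 1.0), P_ATM, 1.0,
                               420.0, name="out")
    T_sky = sky_temperature(T_out + 5.0, wrow.I_lw_sky_pyr)
    wind_roof = af.wind_at_roof_height(wrow.U_wind_8m, cfg.ridge_height,
                                       cfg.wind_roughness)
    lai = model.crop_state.lai(cfg.crop)
    sw, par = _solar_distribution(model, sun, wrow.I_dir, wrow.I_dif,
                                  wrow.I_glob, wrow.Ce, frow.u_thermal,
                                  frow.u_shading, frow.u_curtain, lai)
    assim = crop_mod.photosynthesis_rate(
        cfg.crop, par, frow.C_co2_ppm, T_can - T_REF_K,
        model.crop_state.buffer) / crop_mod.MOLAR_MASS_RATIO_CH2O_CO2 \
        * cfg.cultivated_area
    crop_h = min(max(model.crop_state.l_crop, 0.5), 3.5)
    crop_w = min(0.2 + 0.12 * lai, 0.7)
    ff = model.vf.matrix(crop_h, crop_w)
    return StepContext(sun=sun, T_out=T_out, rho_out=out_state.rho,
                       out_state=out_state, T_sky=T_sky, wind_roof=wind_roof,
                       forcing=dict(frow), sw_absorbed=sw, par_canopy=par,
                       assim_rate=assim, co2_target_ppm=frow.C_co2_ppm,
                       ff=ff, lai=lai)


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------

def _rhs(t: float, y: np.ndarray, model: GreenhouseModel,
         ctx: StepContext) -> np.ndarray:
    cfg = model.cfg
    ix = model.index()
    dy = np.zeros_like(y)
    main, top = model.zones(y)
    f = ctx.forcing
    u_th, u_sh, u_curt = f["u_thermal"], f["u_shading"], f["u_curtain"]
    lai = ctx.lai
    T = {n: y[ix[f"T_{n}"]] for n in SURFACE_NAMES}
    t_main = main.T - T_REF_K
    t_top = top.T - T_REF_K

    Q_surf = {n: ctx.sw_absorbed.get(n, 0.0) for n in SURFACE_NAMES}
    Q_main = 0.0
    Q_top = 0.0
    dM_main = np.zeros(3)
    dM_top = np.zeros(3)

    # ---- convection surface <-> zone ---------------------------------------
    def conv(name, corr, zone_T, L=1.0, wind=0.0, area=None):
        A = area if area is not None else model.surface_area(name)
        dTs = T[name] - zone_T
        h = convective_coefficient(corr, dTs, L, wind)
        return h * A * dTs, h

    q, h_floor = conv("floor", "horizontal_up", main.T)
    Q_surf["floor"] -= q
    Q_main += q

    # canopy sensible (two-sided leaf exchange)
    q_can = crop_mod.leaf_air_exchange(cfg.crop, model.crop_state,
                                       T["canopy"], main) * cfg.cultivated_area
    Q_surf["canopy"] -= q_can
    Q_main += q_can

    # screens exchange with both zones over deployed area
    for scr, u in (("screen_thermal", u_th), ("screen_shading", u_sh)):
        A = u * cfg.floor_area + 1.0
        q_lo, h_lo = conv(scr, "horizontal_down", main.T, area=A)
        q_hi, _ = conv(scr, "horizontal_up", top.T, area=A)
        Q_surf[scr] -= q_lo + q_hi
        Q_main += q_lo
        Q_top += q_hi

    # roof: underside to TopAir, exterior to outdoor air
    q, h_roof_in = conv("roof", "horizontal_down", top.T)
    Q_surf["roof"] -= q
    Q_top += q
    q_ext, _ = conv("roof", "roof_exterior", ctx.T_out, wind=ctx.wind_roof)
    Q_surf["roof"] -= q_ext

    # south wall: glass <-> curtain cavity (deployed part), glass <-> MainAir
    if cfg.include_south_wall:
        A_s = model.surface_area("south_glass")
        q_gc, _ = conv("south_glass", "cavity", T["south_curtain"],
                       area=u_curt * A_s + 1e-6)
        Q_surf["south_glass"] -= q_gc
        Q_surf["south_curtain"] += q_gc
        q_gm, h_sg = conv("south_glass", "vertical_still", main.T,
                          L=cfg.screen_height, area=(1 - u_curt) * A_s + 1e-6)
        Q_surf["south_glass"] -= q_gm
        Q_main += q_gm
        q_cm, h_sc = conv("south_curtain", "vertical_still", main.T,
                          L=cfg.screen_height, area=u_curt * A_s + 1e-6)
        Q_surf["south_curtain"] -= q_cm
        Q_main += q_cm
        q_ext, _ = conv("south_glass", "wall_exterior_tarp", ctx.T_out,
                        wind=ctx.wind_roof)
        Q_surf["south_glass"] -= q_ext
        # exterior long-wave, vertical surface
        node = SurfaceNode("south_glass", A_s, model.emissivity("south_glass"))
        Q_surf["south_glass"] -= sky_and_boundary_exchange(
            node, T["south_glass"], ctx.T_sky, ctx.T_out, tilt_deg=90.0)
    else:
        h_sg = h_sc = 3.0

    # corridor walls
    if cfg.include_corridor_walls:
        for wall, T_cor_key in (("north_wall", "T_air_Ncor"),
                                ("east_wall", "T_air_Ecor")):
            T_cor = f[T_cor_key] + T_REF_K
            q_in, h_w = conv(wall, "vertical_still", main.T, L=cfg.screen_height)
            Q_surf[wall] -= q_in
            Q_main += q_in
            A_w = model.surface_area(wall)
            dTs = T[wall] - T_cor
            h_c = convective_coefficient("vertical_still", dTs, cfg.screen_height)
            Q_surf[wall] -= h_c * A_w * dTs
            # black-body boundary at the corridor/outdoor average
            T_bb = 0.5 * (T_cor + ctx.T_out)
            eps = model.emissivity(wall)
            Q_surf[wall] -= eps * A_w * SIGMA_SB * (T[wall] ** 4 - T_bb ** 4)
    else:
        h_w = 3.0

    # pipes: convection + injection
    for pname, pcfg, Q_in in (("pipe_rail", cfg.pipe_rail, f["Q_rail"]),
                              ("pipe_forcas", cfg.pipe_forcas, f["Q_forcas"]),
                              ("pipe_pe", cfg.pipe_pe, f["Q_pe"])):
        q, _ = conv(pname, "pipe", main.T, L=pcfg.diameter)
        Q_surf[pname] -= q
        Q_surf[pname] += Q_in
        Q_main += q

    q, h_gut = conv("gutters", "horizontal_up", main.T)
    Q_surf["gutters"] -= q
    Q_main += q

    # ---- roof exterior long-wave (sky/ground split by tilt) ----------------
    roof_node = SurfaceNode("roof", model.surface_area("roof"),
                            model.emissivity("roof"))
    Q_surf["roof"] -= sky_and_boundary_exchange(
        roof_node, T["roof"], ctx.T_sky, ctx.T_out, tilt_deg=cfg.roof.roof_slope)

    # ---- indoor long-wave network ------------------------------------------
    vf_names = model.vf.names
    tau_screens = (screen_medium_transmissivity(u_th, cfg.thermal_screen.tau_lw)
                   * screen_medium_transmissivity(u_sh, cfg.shading_screen.tau_lw))
    node_for = {"south_wall": "south_glass"}
    active = {n for n in vf_names
              if (cfg.include_south_wall or n != "south_wall")
              and (cfg.include_corridor_walls or n not in ("north_wall",
                                                           "east_wall"))}
    for i, a in enumerate(vf_names):
        if a not in active:
            continue
        for j, b in enumerate(vf_names):
            if j <= i or b not in active:
                continue
            FF12, FF21 = ctx.ff[i, j], ctx.ff[j, i]
            if FF12 <= 1e-5 and FF21 <= 1e-5:
                continue
            na, nb = node_for.get(a, a), node_for.get(b, b)
            media = (tau_screens,) if "roof" in (a, b) else ()
            n1 = SurfaceNode(na, model.vf.areas[a], model.emissivity(na))
            n2 = SurfaceNode(nb, model.vf.areas[b], model.emissivity(nb))
            qr = net_radiative_exchange(n1, n2, FF12, FF21, T[na], T[nb], media)
            Q_surf[na] -= qr
            Q_surf[nb] += qr
    # screens as radiating planes: intercept the upward passage toward the roof
    i_roof = vf_names.index("roof")
    for scr, u, med in (("screen_thermal", u_th, (1.0,)),
                        ("screen_shading", u_sh,
                         (screen_medium_transmissivity(u_th,
                                                       cfg.thermal_screen.tau_lw),))):
        if u <= 1e-3:
            continue
        eps_s = u * model.emissivity(scr)
        s_node = SurfaceNode(scr, cfg.floor_area, eps_s)
        # screen <-> below nodes (mirror the roof's view of the hall)
        for j, b in enumerate(vf_names):
            if b == "roof" or b not in active:
                continue
            nb = node_for.get(b, b)
            FF12, FF21 = ctx.ff[i_roof, j], ctx.ff[j, i_roof]
            if FF12 <= 1e-5:
                continue
            n2 = SurfaceNode(nb, model.vf.areas[b], model.emissivity(nb))
            qr = net_radiative_exchange(s_node, n2, FF12, FF21, T[scr], T[nb], med)
            Q_surf[scr] -= qr
            Q_surf[nb] += qr
        # screen <-> roof
        roof_n = SurfaceNode("roof", model.vf.areas["roof"],
                             model.emissivity("roof"))
        med_up = () if scr == "screen_shading" else \
            (screen_medium_transmissivity(u_sh, cfg.shading_screen.tau_lw),)
        qr = net_radiative_exchange(s_node, roof_n, 0.95, 0.95 * cfg.floor_area
                                    / model.vf.areas["roof"],
                                    T[scr], T["roof"], med_up)
        Q_surf[scr] -= qr
        Q_surf["roof"] += qr

    # ---- soil ---------------------------------------------------------------
    dT_soil, q_floor_soil = soil_conduction_step(cfg.soil, y[ix["soil"]],
                                                 T["floor"])
    dy[ix["soil"]] = dT_soil
    Q_surf["floor"] -= q_floor_soil * cfg.floor_area

    # ---- transpiration ------------------------------------------------------
    E = crop_mod.canopy_transpiration(cfg.crop, model.crop_state, main,
                                      T["canopy"], ctx.sw_absorbed["canopy"]
                                      / max(cfg.cultivated_area, 1.0),
                                      ctx.co2_target_ppm) * cfg.cultivated_area
    h_vap_can = LATENT_HEAT_VAPORIZATION + CP_WATER_VAPOR * (T["canopy"] - T_REF_K)
    Q_surf["canopy"] -= E * h_vap_can
    dM_main[1] += E
    Q_main += E * h_vap_can
    dy[ix["led_transpired"]] = E

    # ---- condensation / evaporation ----------------------------------------
    h_conv_for = {"roof": h_roof_in, "screen_thermal": 2.0, "screen_shading": 2.0,
                  "south_glass": h_sg, "south_curtain": h_sc,
                  "north_wall": h_w, "east_wall": h_w}
    zone_of = {"roof": "top"}
    for sname in CONDENSING:
        if sname.startswith("screen"):
            u = u_th if sname == "screen_thermal" else u_sh
            A = u * cfg.floor_area
            if A <= 1.0:
                continue
        elif sname in ("south_glass", "south_curtain") and not cfg.include_south_wall:
            continue
        elif sname in ("north_wall", "east_wall") and not cfg.include_corridor_walls:
            continue
        else:
            A = model.surface_area(sname)
        zone = top if zone_of.get(sname) == "top" else main
        st = CondensateStore(sname, mass=max(y[ix[f"cond_{sname}"]], 0.0))
        m_cond = lewis_mass_flux(T[sname], zone, h_conv_for[sname], A, st)
        if m_cond == 0.0:
            continue
        t_carrier = (zone.T if m_cond > 0 else T[sname]) - T_REF_K
        h_vap = LATENT_HEAT_VAPORIZATION + CP_WATER_VAPOR * t_carrier
        Q_surf[sname] += m_cond * h_vap
        if zone is top:
            dM_top[1] -= m_cond
            Q_top -= m_cond * h_vap
        else:
            dM_main[1] -= m_cond
            Q_main -= m_cond * h_vap
        dy[ix[f"cond_{sname}"]] = m_cond

    # ---- airflows -----------------------------------------------------------
    mass_flows_main = []
    mass_flows_top = []

    # vents TopAir <-> outdoor
    dL, dW = f["delta_L"], f["delta_W"]
    if dL > 1e-3 or dW > 1e-3:
        F_vent = af.total_vent_flow(dL, dW, cfg.vents, top.rho, ctx.rho_out,
                                    ctx.wind_roof) * cfg.floor_area
    else:
        F_vent = af.vent_leak_flow(cfg.vents, top.rho, ctx.rho_out,
                                   ctx.wind_roof) * cfg.floor_area
    net, g1, g2 = af.volumetric_to_species_flows(F_vent, top, ctx.out_state,
                                                 "bilateral")
    mass_flows_top.append((g2[0], g2[1], g2[2], ctx.T_out))
    mass_flows_top.append((-g1[0], -g1[1], -g1[2], top.T))
    dy[ix["led_vent_vapor_out"]] = net[1]
    dy[ix["led_co2_vent_out"]] = net[2]

    # screen-gap MainAir <-> TopAir (bilateral exchange)
    F_gap = abs(af.screen_gap_flow(u_th, u_sh, main.p - top.p, cfg.screen_gap,
                                   smooth_pa=0.1))
    net, g1, g2 = af.volumetric_to_species_flows(F_gap, main, top, "bilateral")
    mass_flows_main.append((g2[0], g2[1], g2[2], top.T))
    mass_flows_main.append((-g1[0], -g1[1], -g1[2], main.T))
    mass_flows_top.append((g1[0], g1[1], g1[2], main.T))
    mass_flows_top.append((-g2[0], -g2[1], -g2[2], top.T))

    # cracks: TopAir <-> outdoor, MainAir <-> corridors (unilateral)
    def crack(zone, other_state, cfg_crack, is_main, led=None):
        Fc = af.crack_flow(zone.p - other_state.p, cfg_crack, smooth_pa=0.1)
        if Fc == 0.0:
            return
        net, g1, g2 = af.volumetric_to_species_flows(Fc, zone, other_state,
                                                     "unilateral")
        flows = mass_flows_main if is_main else mass_flows_top
        flows.append((g2[0], g2[1], g2[2], other_state.T))
        flows.append((-g1[0], -g1[1], -g1[2], zone.T))
        if led is not None:
            dy[ix[f"led_{led[0]}"]] += net[1]
            dy[ix[f"led_{led[1]}"]] += net[2]

    crack(top, ctx.out_state, cfg.crack_top_out, is_main=False,
          led=("crack_vapor_out", "co2_crack_out"))
    for ckey, tkey in (("crack_main_ncor", "T_air_Ncor"),
                       ("crack_main_ecor", "T_air_Ecor")):
        T_cor = f[tkey] + T_REF_K
        rh_cor = min(main.RH, 1.0) if cfg.corridor_rh_mode == "main_air" else 0.7
        cor = state_from_TRH(T_cor, max(rh_cor, 0.0), P_ATM, 1.0, 420.0)
        crack(main, cor, getattr(cfg, ckey), is_main=True,
              led=("crack_vapor_out", "co2_crack_out"))

    # ---- CO2 management -----------------------------------------------------
    M_target = (ctx.co2_target_ppm * 1e-6 * main.p * cfg.main_air_volume
                / (R_CO2 * main.T))
    inj = (M_target - main.M_co2) / 300.0
    dM_main[2] += inj
    Q_main += inj * CP_CO2 * t_main
    dy[ix["led_co2_injected"]] = inj
    dM_main[2] -= ctx.assim_rate
    Q_main -= ctx.assim_rate * CP_CO2 * t_main
    dy[ix["led_co2_assimilated"]] = ctx.assim_rate

    # ---- zone energy balances ----------------------------------------------
    for (md, mw, mc, Tc) in mass_flows_main:
        Q_main += species_enthalpy_flux(md, mw, mc, Tc)
        dM_main += (md, mw, mc)
    for (md, mw, mc, Tc) in mass_flows_top:
        Q_top += species_enthalpy_flux(md, mw, mc, Tc)
        dM_top += (md, mw, mc)

    dy[0] = Q_main
    dy[1:4] = dM_main
    dy[4] = Q_top
    dy[5:8] = dM_top

    # ---- surface temperature derivatives ------------------------------------
    for n in SURFACE_NAMES:
        C = model.heat_capacity(n, u_th, u_sh, lai)
        dy[ix[f"T_{n}"]] = Q_surf[n] / C

    dy[ix["led_heat_injected"]] = f["Q_rail"] + f["Q_forcas"] + f["Q_pe"]
    return dy


# ---------------------------------------------------------------------------
# Forcing synthesis and pruning schedule
# ---------------------------------------------------------------------------

def synthesize_forcing(weather: pd.DataFrame, seed: int = 0,
                       heat_setpoint: float = 17.0,
                       vent_threshold: float = 16.0) -> pd.DataFrame:
    """Rule-of-thumb actuator schedules for synthetic runs: vents open with
    warm/ sunny conditions, thermal screen deployed on cold nights, pipe
    heat proportional to the heating deficit, day/night CO2 setpoints and
    mild corridors."""
    rng = np.random.default_rng(seed)
    T = weather["T_air_out"].to_numpy()
    I = weather["I_glob"].to_numpy()
    day = I > 20.0
    dL = np.clip((T - vent_threshold) * 8.0 + np.where(day, 6.0, 0.0), 0, 44)
    dW = np.clip(dL - 15.0, 0.0, 44.0)
    u_th = np.where(~day & (T < 12.0), 1.0, 0.0)
    u_sh = np.where(day & (I > 600.0), 1.0, 0.0)
    u_cu = u_th.copy()
    deficit = np.clip(heat_setpoint - T, 0.0, None)
    Q_rail = np.clip(deficit * 7.0, 0, 90) * 1037.0
    Q_forcas = 0.35 * Q_rail
    Q_pe = np.where(deficit > 0, 5.0 * 1037.0, 0.0)
    co2 = np.where(day, 750.0, 430.0)
    T_cor = np.clip(T + 5.0, 14.0, 24.0)
    df = pd.DataFrame({
        "delta_L": dL, "delta_W": dW,
        "u_thermal": u_th, "u_shading": u_sh, "u_curtain": u_cu,
        "Q_rail": Q_rail, "Q_forcas": Q_forcas, "Q_pe": Q_pe,
        "C_co2_ppm": co2, "T_air_Ncor": T_cor, "T_air_Ecor": T_cor,
    }, index=weather.index)
    return df


def weekly_pruning_table(start, n_weeks: int, target_lai: float = 4.5
                         ) -> pd.DataFrame:
    """Weekly pruning schedule at a fixed target LAI."""
    idx = pd.date_range(start=start, periods=n_weeks, freq="7D", tz="UTC")
    return pd.DataFrame({"timestamp": idx, "target_LAI": target_lai})


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    series: pd.DataFrame
    ledger: dict
    crop_final: crop_mod.CropState
    variant: str
    config: GreenhouseConfig


def integrate(model: GreenhouseModel, weather: pd.DataFrame,
              forcing: pd.DataFrame, pruning: pd.DataFrame | None = None,
              solver: str = "BDF",
              y0: np.ndarray | None = None) -> SimulationResult:
    """Advance the assembled system across the weather/forcing series
    (5-min cadence), returning 5-min-sampled outputs and closed ledgers."""
    cfg = model.cfg
    if not weather.index.equals(forcing.index):
        raise ValueError("weather and forcing series are misaligned")
    idx = weather.index
    az, zen = solar_position_series(idx, cfg.latitude, cfg.longitude)
    if y0 is not None:
        y = np.array(y0, dtype=float)
    else:
        y = model.initial_state(weather["T_air_out"].iloc[0],
                                min(weather["RH_air_out"].iloc[0], 0.95),
                                forcing["C_co2_ppm"].iloc[0])
    ix = model.index()
    # per-state absolute tolerances: energies are O(1e8) J, masses O(1e3) kg,
    # temperatures O(1e2) K; ledger integrals only need coarse accuracy
    atol = np.full(model.n_states, 1e-6)
    for z in ("main", "top"):
        atol[ix[z]] = [10.0, 1e-4, 1e-6, 1e-8]
    for n in SURFACE_NAMES:
        atol[ix[f"T_{n}"]] = 1e-4
    atol[ix["soil"]] = 1e-4
    for n in CONDENSING:
        atol[ix[f"cond_{n}"]] = 1e-4
    for n in LEDGER_NAMES:
        atol[ix[f"led_{n}"]] = 1e-2
    prune_times = []
    if pruning is not None:
        prune_times = list(pd.to_datetime(pruning["timestamp"]))
    m0, t0 = model.zones(y)
    M_w_init = m0.M_w + t0.M_w
    M_co2_init = m0.M_co2 + t0.M_co2
    records = []
    dt = 300.0
    for k, ts in enumerate(idx):
        sun = SunPosition(float(az[k]), float(zen[k]))
        ctx = make_step_context(model, weather.iloc[k], forcing.iloc[k], sun,
                                y[ix["T_canopy"]])
        sol = solve_ivp(_rhs, (0.0, dt), y, args=(model, ctx), method=solver,
                        rtol=cfg.rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"solver failure at {ts}: {sol.message}\n"
                               f"state: {y}")
        y = sol.y[:, -1]
        y[ix["cond_roof"]:ix["cond_roof"] + len(CONDENSING)] = np.maximum(
            y[ix["cond_roof"]:ix["cond_roof"] + len(CONDENSING)], 0.0)

        # crop update at step boundary
        model.crop_state = crop_mod.grow_step(
            model.crop_state, cfg.crop, ctx.par_canopy,
            y[ix["T_canopy"]], ctx.co2_target_ppm, dt)
        model.crop_state.cum_transpiration = y[ix["led_transpired"]] \
            / max(cfg.cultivated_area, 1.0)
        while prune_times and ts >= prune_times[0]:
            target = float(pruning.loc[pd.to_datetime(pruning["timestamp"])
                                       == prune_times[0], "target_LAI"].iloc[0])
            model.crop_state, _ = crop_mod.apply_pruning(
                model.crop_state, crop_mod.PruningEvent(prune_times[0], target),
                cfg.crop)
            prune_times.pop(0)

        main, top = model.zones(y)
        rec = {
            "T_main": main.T - T_REF_K, "RH_main": main.RH,
            "T_top": top.T - T_REF_K, "RH_top": top.RH,
            "p_main": main.p, "p_top": top.p,
            "co2_main": main.co2_ppm,
            "x_w_main": main.x_w,
            "abs_hum_main": main.M_w / main.V,
            "T_canopy": y[ix["T_canopy"]] - T_REF_K,
            "T_roof": y[ix["T_roof"]] - T_REF_K,
            "T_floor": y[ix["T_floor"]] - T_REF_K,
            "LAI": model.crop_state.lai(cfg.crop),
            "harvest_dm": model.crop_state.cum_harvest_dm,
            "harvest_fresh": crop_mod.dm_to_fresh(
                model.crop_state.cum_harvest_dm, cfg.crop.dm_content_fruit),
            "harvest_count": model.crop_state.cum_harvest_count,
            "par_canopy": ctx.par_canopy,
        }
        for n in LEDGER_NAMES:
            rec[f"led_{n}"] = y[ix[f"led_{n}"]]
        for n in CONDENSING:
            rec[f"cond_{n}"] = y[ix[f"cond_{n}"]]
        records.append(rec)
    series = pd.DataFrame(records, index=idx)
    main, top = model.zones(y)
    ledger = {f"led_{n}": float(y[ix[f"led_{n}"]]) for n in LEDGER_NAMES}
    ledger.update({f"cond_{n}": float(y[ix[f"cond_{n}"]]) for n in CONDENSING})
    ledger["M_w_main_final"] = main.M_w
    ledger["M_w_top_final"] = top.M_w
    ledger["M_w_initial"] = M_w_init
    ledger["M_co2_initial"] = M_co2_init
    ledger["M_co2_final"] = main.M_co2 + top.M_co2
    return SimulationResult(series=series, ledger=ledger,
                            crop_final=model.crop_state,
                            variant=model.variant, config=cfg)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def rmse(sim: np.ndarray, obs: np.ndarray) -> float:
    sim, obs = np.asarray(sim, float), np.asarray(obs, float)
    return float(np.sqrt(np.mean((sim - obs) ** 2)))


def rrmse(sim: np.ndarray, obs: np.ndarray) -> float:
    """RMSE relative to the observation mean, percent."""
    return rmse(sim, obs) / float(np.mean(obs)) * 100.0


def mae(sim: np.ndarray, obs: np.ndarray) -> float:
    return float(np.mean(np.abs(np.asarray(sim) - np.asarray(obs))))


def daily_rmse(sim: pd.Series, obs: pd.Series) -> pd.Series:
    """Midnight-to-midnight daily RMSE series."""
    err2 = (sim - obs) ** 2
    return np.sqrt(err2.groupby(err2.index.floor("D")).mean())


def evaluate(sim: pd.DataFrame, obs: pd.DataFrame, variables: list[str],
             windows: dict[str, int] | None = None) -> pd.DataFrame:
    """Cumulative RMSE/RRMSE/MAE per variable at requested horizons
    (window name -> number of leading records)."""
    if not sim.index.equals(obs.index):
        raise ValueError("sim/obs series misaligned")
    windows = windows or {"all": len(sim)}
    rows = []
    for var in variables:
        for wname, n in windows.items():
            s, o = sim[var].iloc[:n], obs[var].iloc[:n]
            rows.append({"variable": var, "window": wname,
                         "RMSE": rmse(s, o), "RRMSE": rrmse(s, o),
                         "MAE": mae(s, o)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mass balances
# ---------------------------------------------------------------------------

def water_balance(result: SimulationResult) -> dict:
    """Partition cumulative transpiration into condensed / vented / leaked /
    retained-in-air shares (fractions of transpired water sum to ~1 up to
    the air storage term, which is reported explicitly)."""
    led = result.ledger
    transpired = led["led_transpired"]
    condensed = sum(led[f"cond_{n}"] for n in CONDENSING)
    vented = led["led_vent_vapor_out"]
    leaked = led["led_crack_vapor_out"]
    air_storage = (led["M_w_main_final"] + led["M_w_top_final"]
                   - led["M_w_initial"])
    out = {
        "transpired_kg": transpired,
        "condensed_kg": condensed,
        "vented_kg": vented,
        "leaked_kg": leaked,
        "air_storage_kg": air_storage,
        "closure_residual_kg": transpired - condensed - vented - leaked
                               - air_storage,
    }
    if transpired > 0:
        out["frac_condensed"] = condensed / transpired
        out["frac_vented"] = vented / transpired
        out["frac_leaked"] = leaked / transpired
        out["frac_air_storage"] = air_storage / transpired
    # crop-stored water bounds from the dry-matter contents
    crop = result.crop_final
    veg_dm = crop.leaf_dm + crop.stem_dm
    cfgc = result.config.crop
    area = result.config.cultivated_area
    out["crop_water_lo_kg"] = (veg_dm * (1 / cfgc.dm_content_veg_hi - 1)
                               + crop.total_fruit_dm
                               * (1 / cfgc.dm_content_fruit - 1)) * area
    out["crop_water_hi_kg"] = (veg_dm * (1 / cfgc.dm_content_veg_lo - 1)
                               + crop.total_fruit_dm
                               * (1 / cfgc.dm_content_fruit - 1)) * area
    return out


def co2_balance(result: SimulationResult, concentration_offset_ppm: float = 0.0
                ) -> dict:
    """CO2 ledger: implied injection vs assimilation + venting + leakage.
    ``concentration_offset_ppm`` supports the sensitivity experiment of a
    systematic sensor error (it rescales the implied injection by the
    offset-induced change in the vented/leaked concentration share)."""
    led = result.ledger
    out = {
        "injected_kg": led["led_co2_injected"],
        "assimilated_kg": led["led_co2_assimilated"],
        "vented_kg": led["led_co2_vent_out"],
        "leaked_kg": led["led_co2_crack_out"],
    }
    out["storage_change_kg"] = led["M_co2_final"] - led["M_co2_initial"]
    out["closure_residual_kg"] = (out["injected_kg"] - out["assimilated_kg"]
                                  - out["vented_kg"] - out["leaked_kg"]
                                  - out["storage_change_kg"])
    if concentration_offset_ppm:
        mean_ppm = float(result.series["co2_main"].mean())
        scale = (mean_ppm + concentration_offset_ppm) / mean_ppm
        out["injected_kg_offset"] = (out["assimilated_kg"]
                                     + (out["vented_kg"] + out["leaked_kg"])
                                     * scale + 0.0)
    return out


def run_variant(name: str, cfg: GreenhouseConfig, weather: pd.DataFrame,
                forcing: pd.DataFrame, pruning: pd.DataFrame | None = None,
                observations: pd.DataFrame | None = None) -> dict:
    """Run a variant and the reference on identical inputs and report the
    difference trajectories (temperature/RH RMSE vs the observation series
    — the reference output doubles as observation when none is given —
    plus yield, fruit-count and LAI differences)."""
    if name not in VARIANTS:
        raise ValueError(f"unknown variant {name!r}")
    ref = integrate(build_system(cfg, "reference"), weather, forcing, pruning)
    var = integrate(build_system(cfg, name), weather, forcing, pruning)
    obs = observations if observations is not None else ref.series
    diff = {
        "dRMSE_T": rmse(var.series["T_main"], obs["T_main"])
                   - rmse(ref.series["T_main"], obs["T_main"]),
        "dRMSE_RH": rmse(var.series["RH_main"], obs["RH_main"])
                    - rmse(ref.series["RH_main"], obs["RH_main"]),
        "d_yield": var.series["harvest_fresh"].iloc[-1]
                   - ref.series["harvest_fresh"].iloc[-1],
        "d_fruits": var.series["harvest_count"].iloc[-1]
                    - ref.series["harvest_count"].iloc[-1],
        "d_LAI": var.series["LAI"].iloc[-1] - ref.series["LAI"].iloc[-1],
    }
    return {"reference": ref, "variant": var, "difference": diff}
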