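"""Tomato crop: big-leaf transpiration, CO2/heat exchange, and a reduced
carbohydrate-buffer growth model with discrete pruning and harvest.

Transpiration is a Stanghellini-type big-leaf latent flux: vapour moves
from the saturated leaf interior to the zone air across an aerodynamic
(boundary-layer) and a stomatal resistance, the latter responding to
absorbed short-wave radiation, canopy temperature, CO2 and vapour
pressure deficit.

Growth follows the Vanthoor carbohydrate-buffer structure in reduced
form: canopy gross photosynthesis (PAR-, CO2- and temperature-dependent,
buffer-inhibited) fills a common assimilate buffer, which drains into
leaf, stem and fruit dry-matter pools; fruits mature through a chain of
development boxes into harvested dry matter and fruit count; every pool
pays temperature-dependent maintenance respiration.  Pruning is a
discrete event: leaf dry matter is cut back so the LAI lands exactly on
the event's target, and the removed biomass is reported as an output
flow.  Harvested dry matter converts to fresh weight through a constant
dry-matter content (5.4% for the fruits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import CP_DRY_AIR, LATENT_HEAT_VAPORIZATION
from .moist_air import MoistAirState, saturation_pressure

__all__ = [
    "CropParams",
    "CropState",
    "PruningEvent",
    "canopy_transpiration",
    "stomatal_resistance",
    "photosynthesis_rate",
    "grow_step",
    "apply_pruning",
    "leaf_air_exchange",
    "dm_to_fresh",
]

PSYCHROMETRIC_GAMMA = 65.8          # Pa K-1
MOLAR_MASS_RATIO_CH2O_CO2 = 30.0 / 44.0


@dataclass(frozen=True)
class CropParams:
    """Tunable crop parameters (per m2 of cultivated area unless noted)."""
    # canopy / optics
    SLA: float = 0.025              # specific leaf area, m2 g-1 DM
    # transpiration
    r_boundary: float = 275.0       # aerodynamic resistance, s m-1
    r_stomatal_min: float = 82.0    # minimum stomatal resistance, s m-1
    # photosynthesis
    lue: float = 7.0e-9             # light-use efficiency, kg CO2 J-1 absorbed PAR
    p_max_ref: float = 1.8e-6       # max gross assimilation, kg CO2 m-2 s-1
    co2_half: float = 300.0         # ppm, CO2 half-saturation
    T_photo_opt: float = 24.0       # degC
    T_photo_width: float = 13.0     # degC
    buffer_max: float = 0.025       # kg CH2O m-2, photosynthesis stops when full
    # partitioning (generative phase fractions; vegetative phase shifts
    # the fruit share onto leaf + stem)
    frac_fruit: float = 0.55
    frac_leaf: float = 0.28
    frac_stem: float = 0.17
    growth_rate_coeff: float = 2.0e-5   # s-1 at 20 degC, buffer outflow
                                        # (buffer turnover ~14 h, matching the
                                        # daily assimilation magnitude)
    growth_Q10: float = 1.6
    # maintenance respiration at 25 degC, s-1 of pool DM
    resp_leaf: float = 3.47e-7
    resp_stem: float = 1.47e-7
    resp_fruit: float = 1.16e-7
    resp_Q10: float = 2.0
    # fruit development
    n_dev_boxes: int = 5
    fruit_dev_rate_20: float = 1.0 / (55.0 * 86400.0)  # s-1 full-chain at 20 degC
    fruit_dev_Q10: float = 1.6
    fruit_dm_each: float = 5.4e-3   # kg DM per fruit at harvest
    # conversion
    dm_content_fruit: float = 0.054
    dm_content_veg_lo: float = 0.075
    dm_content_veg_hi: float = 0.136
    # generative switch: temperature sum after planting, degC day
    gen_temp_sum: float = 250.0


@dataclass
class CropState:
    """Crop pools (kg DM m-2 of cultivated area) and cumulative ledgers."""
    leaf_dm: float = 0.012
    stem_dm: float = 0.006
    buffer: float = 0.001
    fruit_dm: np.ndarray = field(default_factory=lambda: np.zeros(5))
    fruit_count: np.ndarray = field(default_factory=lambda: np.zeros(5))
    temp_sum: float = 0.0            # degC day since planting
    topped: bool = False
    l_crop: float = 1.0              # crop length input, m
    # cumulative ledgers
    cum_harvest_dm: float = 0.0
    cum_harvest_count: float = 0.0
    cum_pruned_dm: float = 0.0
    cum_transpiration: float = 0.0   # kg m-2
    cum_photo: float = 0.0           # kg CH2O m-2 into the buffer
    cum_resp: float = 0.0

    def lai(self, params: CropParams) -> float:
        """LAI = SLA * leaf DM (SLA in m2 g-1, DM in kg m-2)."""
        return params.SLA * self.leaf_dm * 1000.0

    @property
    def total_fruit_dm(self) -> float:
        return float(self.fruit_dm.sum())


@dataclass(frozen=True)
class PruningEvent:
    timestamp: object
    target_LAI: float

    def __post_init__(self):
        if self.target_LAI <= 0:
            raise ValueError("pruning target LAI must be > 0")


# ---------------------------------------------------------------------------
# Transpiration and leaf-air exchange
# ---------------------------------------------------------------------------

def stomatal_resistance(params: CropParams, R_abs: float, lai: float,
                        T_can_C: float, co2_ppm: float, vpd_pa: float) -> float:
    """Stomatal resistance (s m-1): minimum value scaled by radiation,
    temperature, CO2 and vapour-deficit response factors."""
    lai = max(lai, 1e-6)
    I_leaf = R_abs / (2.0 * lai)
    f_I = (I_leaf + 4.3) / (I_leaf + 0.54)
    f_T = 1.0 + 2.3e-2 * (T_can_C - 24.5) ** 2
    f_co2 = min(1.5, 1.0 + 6.1e-7 * (co2_ppm - 200.0) ** 2)
    f_vpd = min(3.8, 1.0 + 4.3 * (vpd_pa / 1000.0) ** 2)
    return params.r_stomatal_min * f_I * min(f_T, 5.0) * f_co2 * f_vpd


def canopy_transpiration(params: CropParams, state: CropState,
                         air: MoistAirState, T_can: float,
                         R_abs: float, co2_ppm: float) -> float:
    """Canopy latent mass flux (kg s-1 m-2 cultivated), big-leaf form:
    ``2*LAI * rho*cp/(DH*gamma*(r_b+r_s)) * (p_sat(T_can) - p_w_air)``."""
    lai = state.lai(params)
    if lai <= 0.0:
        return 0.0
    p_can = saturation_pressure(T_can)
    vpd = max(p_can - air.p_w, 0.0)
    r_s = stomatal_resistance(params, R_abs, lai, T_can - 273.15,
                              co2_ppm, vpd)
    vec = (2.0 * lai * air.rho * CP_DRY_AIR
           / (LATENT_HEAT_VAPORIZATION * PSYCHROMETRIC_GAMMA
              * (params.r_boundary + r_s)))
    return vec * vpd


def leaf_air_exchange(params: CropParams, state: CropState, T_can: float,
                      air: MoistAirState) -> float:
    """Sensible heat flux canopy -> air (W m-2 cultivated): two-sided
    leaf exchange across the boundary-layer resistance."""
    lai = state.lai(params)
    rho_cp = air.rho * CP_DRY_AIR
    return 2.0 * lai * rho_cp / params.r_boundary * (T_can - air.T)


# ---------------------------------------------------------------------------
# Growth
# ---------------------------------------------------------------------------

def photosynthesis_rate(params: CropParams, PAR_abs: float, co2_ppm: float,
                        T_can_C: float, buffer: float) -> float:
    """Gross canopy photosynthesis (kg CH2O m-2 s-1): light-saturating
    response scaled by CO2 and temperature, inhibited when the assimilate
    buffer is full."""
    if PAR_abs <= 0.0 or buffer >= params.buffer_max:
        return 0.0
    f_co2 = co2_ppm / (co2_ppm + params.co2_half)
    f_T = math.exp(-((T_can_C - params.T_photo_opt) / params.T_photo_width) ** 2)
    p_max = params.p_max_ref * f_co2 * f_T
    if p_max <= 0.0:
        return 0.0
    p_co2 = p_max * (1.0 - math.exp(-params.lue * PAR_abs / p_max))
    return p_co2 * MOLAR_MASS_RATIO_CH2O_CO2


def _q10(rate_ref: float, q10: float, T_C: float, T_ref: float = 20.0) -> float:
    return rate_ref * q10 ** ((T_C - T_ref) / 10.0)


def grow_step(state: CropState, params: CropParams, PAR_abs: float,
              T_can: float, co2_ppm: float, dt: float) -> CropState:
    """Advance the crop pools by ``dt`` seconds under constant conditions.

    Explicit bookkeeping keeps the carbon ledger closed: buffer inflow
    equals pool growth + respiration + harvest over any interval.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    T_C = T_can - 273.15
    s = state
    photo = photosynthesis_rate(params, PAR_abs, co2_ppm, T_C, s.buffer)

    # maintenance respiration (paid by the pools)
    rl = _q10(params.resp_leaf, params.resp_Q10, T_C, 25.0) * s.leaf_dm
    rs = _q10(params.resp_stem, params.resp_Q10, T_C, 25.0) * s.stem_dm
    rf = _q10(params.resp_fruit, params.resp_Q10, T_C, 25.0) * s.total_fruit_dm

    # buffer outflow to growth
    g = _q10(params.growth_rate_coeff, params.growth_Q10, T_C) * s.buffer
    generative = s.temp_sum >= params.gen_temp_sum
    f_fruit = params.frac_fruit if generative else 0.0
    f_leaf, f_stem = params.frac_leaf, params.frac_stem
    if s.topped:
        f_fruit, f_leaf, f_stem = f_fruit + f_leaf + f_stem, 0.0, 0.0
    else:
        veg_scale = (1.0 - f_fruit) / (f_leaf + f_stem)
        f_leaf, f_stem = f_leaf * veg_scale, f_stem * veg_scale

    # fruit development chain
    n = params.n_dev_boxes
    dev = _q10(params.fruit_dev_rate_20, params.fruit_dev_Q10, T_C) * n
    fruit_dm = s.fruit_dm.copy()
    fruit_cnt = s.fruit_count.copy()
    transfer_dm = dev * fruit_dm * dt
    transfer_cnt = dev * fruit_cnt * dt
    fruit_dm -= transfer_dm
    fruit_cnt -= transfer_cnt
    fruit_dm[1:] += transfer_dm[:-1]
    fruit_cnt[1:] += transfer_cnt[:-1]
    harvest_dm = transfer_dm[-1]
    harvest_cnt = transfer_cnt[-1]

    alloc_fruit = g * f_fruit * dt
    # maintenance respiration drains the boxes proportionally to content
    if s.total_fruit_dm > 0:
        fruit_dm -= rf * dt * s.fruit_dm / s.total_fruit_dm
    fruit_dm[0] += alloc_fruit
    fruit_dm = np.maximum(fruit_dm, 0.0)
    fruit_cnt[0] += alloc_fruit / params.fruit_dm_each

    new_leaf = max(s.leaf_dm + (g * f_leaf - rl) * dt, 0.0)
    new_stem = max(s.stem_dm + (g * f_stem - rs) * dt, 0.0)
    new_buffer = max(s.buffer + (photo - g) * dt, 0.0)

    return replace(
        s,
        leaf_dm=new_leaf,
        stem_dm=new_stem,
        buffer=new_buffer,
        fruit_dm=fruit_dm,
        fruit_count=np.maximum(fruit_cnt, 0.0),
        temp_sum=s.temp_sum + max(T_C, 0.0) * dt / 86400.0,
        cum_harvest_dm=s.cum_harvest_dm + harvest_dm,
        cum_harvest_count=s.cum_harvest_count + harvest_cnt,
        cum_photo=s.cum_photo + photo * dt,
        cum_resp=s.cum_resp + (rl + rs + rf) * dt,
    )


def apply_pruning(state: CropState, event: PruningEvent,
                  params: CropParams) -> tuple[CropState, float]:
    """Discrete pruning: set the LAI to the event target by removing leaf
    dry matter.  A target above the current LAI is a no-op with a warning
    semantics (the caller may log it); returns (new state, removed DM)."""
    current = state.lai(params)
    if event.target_LAI >= current:
        return state, 0.0
    d_lai = current - event.target_LAI
    removed = d_lai / (params.SLA * 1000.0)
    new = replace(state,
                  leaf_dm=state.leaf_dm - removed,
                  cum_pruned_dm=state.cum_pruned_dm + removed)
    return new, removed


def dm_to_fresh(dm_kg: float, dm_content: float = 0.054) -> float:
    """Convert harvested dry matter to fresh weight (kg)."""
    if not 0.0 < dm_content < 1.0:
        raise ValueError("dry-matter content must lie in (0, 1)")
    return dm_kg / dm_content
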