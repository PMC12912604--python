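"""Greenhouse configuration: geometry, materials, equipment, crop, site.

The default instance describes the study-case compartment: a 1037 m2
six-span Venlo glasshouse (spans 4 m, roof slope 22 deg, ridge axis
-29 deg from North), 944 m2 cultivated (r_cul = 0.91), corridors on the
north and east sides, a thermally neutral twin compartment to the west,
and only the south gable exposed outdoors.  All values are plain physical
properties; nothing is calibrated.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import yaml

from .airflows import CrackConfig, ScreenGapConfig, VentConfig
from .crop import CropParams
from .indoor_optics import LayerOpticalProps, WallConfig
from .roof_optics import GlazingOptics, RoofGeometry
from .surfaces import PipeNetwork, SoilColumn

__all__ = ["GreenhouseConfig", "load_config", "save_config", "study_case_config"]


@dataclass
class ScreenProps:
    """One horizontal screen: per-band short-wave props + long-wave."""
    name: str
    tau_sw: float
    rho_sw: float
    tau_lw: float
    emissivity: float
    area_density: float = 0.1      # kg m-2, for the thermal node capacity
    cp: float = 1500.0             # J kg-1 K-1

    def sw_layer(self) -> LayerOpticalProps:
        return LayerOpticalProps.symmetric(self.tau_sw, self.rho_sw, self.name)


@dataclass
class GreenhouseConfig:
    # --- geometry ---
    floor_area: float = 1037.0          # m2
    cultivated_area: float = 944.0      # m2
    r_cul: float = 0.91
    length: float = 43.2                # m, along the ridge axis
    width: float = 24.0                 # m
    screen_height: float = 6.0          # m, horizontal screen plane
    gutter_height: float = 6.97         # m
    ridge_height: float = 7.78          # m
    roof: RoofGeometry = field(default_factory=RoofGeometry)
    glazing: GlazingOptics = field(default_factory=GlazingOptics)
    latitude: float = 47.29
    longitude: float = -1.46

    # --- cover behaviour switches (model variants) ---
    constant_cover_transmittance: float | None = None   # e.g. 0.78 for C.2
    include_south_wall: bool = True
    include_corridor_walls: bool = True

    # --- south wall ---
    south_wall: WallConfig = field(default_factory=lambda: WallConfig(
        area=170.0, azimuth=151.0, frame_dirt_coeff=0.9, ground_albedo=0.2))

    # --- screens ---
    thermal_screen: ScreenProps = field(default_factory=lambda: ScreenProps(
        "thermal_screen", tau_sw=0.55, rho_sw=0.35, tau_lw=0.25, emissivity=0.60))
    shading_screen: ScreenProps = field(default_factory=lambda: ScreenProps(
        "shading_screen", tau_sw=0.60, rho_sw=0.33, tau_lw=0.55, emissivity=0.40))

    # --- airflows ---
    vents: VentConfig = field(default_factory=VentConfig)
    crack_top_out: CrackConfig = field(default_factory=lambda: CrackConfig(
        eta=0.12, n=0.65, connects=("top_air", "outdoor")))
    crack_main_ncor: CrackConfig = field(default_factory=lambda: CrackConfig(
        eta=0.06, n=0.65, connects=("main_air", "north_corridor")))
    crack_main_ecor: CrackConfig = field(default_factory=lambda: CrackConfig(
        eta=0.06, n=0.65, connects=("main_air", "east_corridor")))
    screen_gap: ScreenGapConfig = field(default_factory=ScreenGapConfig)
    wind_roughness: float = 0.03

    # --- surfaces / materials ---
    floor_emissivity: float = 0.95
    floor_absorptance_PAR: float = 0.55
    floor_absorptance_NIR: float = 0.55
    roof_emissivity: float = 0.90
    wall_emissivity: float = 0.90
    glass_density: float = 2500.0
    glass_cp: float = 840.0
    soil: SoilColumn = field(default_factory=SoilColumn)

    # --- heating pipes ---
    pipe_rail: PipeNetwork = field(default_factory=lambda: PipeNetwork(
        "pipe_rail", area=220.0, diameter=0.051, heat_capacity=2.6e6))
    pipe_forcas: PipeNetwork = field(default_factory=lambda: PipeNetwork(
        "pipe_forcas", area=115.0, diameter=0.028, heat_capacity=0.9e6))
    pipe_pe: PipeNetwork = field(default_factory=lambda: PipeNetwork(
        "pipe_pe", area=60.0, diameter=0.025, heat_capacity=0.4e6))

    # --- gutters / inertia ---
    gutters_area: float = 320.0
    gutters_heat_capacity: float = 4.0e7   # J K-1 (rockwool slabs + water)
    gutters_emissivity: float = 0.9

    # --- crop ---
    crop: CropParams = field(default_factory=CropParams)
    canopy_emissivity: float = 0.95
    canopy_heat_capacity_per_lai: float = 1200.0   # J K-1 m-2 per unit LAI

    # --- numerics ---
    rtol: float = 1e-5
    vf_cell_size: float = 6.0
    forcing_smoothing_s: float = 60.0
    corridor_rh_mode: str = "main_air"   # corridor RH assumption

    def __post_init__(self):
        if abs(self.cultivated_area - self.r_cul * self.floor_area) \
                > 0.02 * self.floor_area:
            raise ValueError("cultivated area inconsistent with r_cul * floor")

    @property
    def main_air_volume(self) -> float:
        return self.floor_area * self.screen_height

    @property
    def top_air_volume(self) -> float:
        mean_roof = self.gutter_height + 0.5 * (self.ridge_height
                                                - self.gutter_height)
        return self.floor_area * (mean_roof - self.screen_height)

    @property
    def roof_surface_area(self) -> float:
        return self.floor_area / math.cos(self.roof.slope_rad)

    @property
    def north_wall_area(self) -> float:
        return self.width * self.gutter_height * 0.95 + 30.0

    @property
    def east_wall_area(self) -> float:
        return self.length * self.gutter_height


def _to_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_dict(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_dict(x) for x in obj]
    return obj


def save_config(cfg: GreenhouseConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_dict(cfg), fh, sort_keys=False)


_NESTED = {
    "roof": RoofGeometry, "glazing": GlazingOptics, "south_wall": WallConfig,
    "thermal_screen": ScreenProps, "shading_screen": ScreenProps,
    "vents": VentConfig, "crack_top_out": CrackConfig,
    "crack_main_ncor": CrackConfig, "crack_main_ecor": CrackConfig,
    "screen_gap": ScreenGapConfig, "soil": SoilColumn,
    "pipe_rail": PipeNetwork, "pipe_forcas": PipeNetwork, "pipe_pe": PipeNetwork,
    "crop": CropParams,
}


def _build(cls, data):
    if not isinstance(data, dict):
        return data
    kwargs = {}
    hints = {f.name: f for f in dataclasses.fields(cls)}
    for k, v in data.items():
        if k not in hints:
            raise ValueError(f"unknown config key {k!r} for {cls.__name__}")
        if k in _NESTED and isinstance(v, dict):
            kwargs[k] = _build(_NESTED[k], v)
        elif k == "curtain" and isinstance(v, dict):
            kwargs[k] = LayerOpticalProps(**v)
        elif k == "glazing" and isinstance(v, dict):
            kwargs[k] = GlazingOptics(**v)
        elif isinstance(v, list) and k in ("thicknesses", "conductivities",
                                           "heat_capacities", "connects"):
            kwargs[k] = tuple(v)
        else:
            kwargs[k] = v
    return cls(**kwargs)


def load_config(path) -> GreenhouseConfig:
    """Load a greenhouse YAML configuration (schema-checked: unknown keys
    are rejected)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return _build(GreenhouseConfig, data)


def study_case_config(**overrides) -> GreenhouseConfig:
    """The experimental-compartment configuration (defaults), optionally
    overridden field-by-field."""
    cfg = GreenhouseConfig()
    if overrides:
        cfg = dataclasses.replace(cfg, **overrides)
    return cfg
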