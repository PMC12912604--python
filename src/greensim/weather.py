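"""Weather and actuator forcing: reading, validation, synthesis, sun position.

Weather series are handled as pandas DataFrames with a fixed column
vocabulary (UTC ``timestamp`` index, 5-min cadence):

======================  =======================================================
column                  meaning
======================  =======================================================
``T_air_out``           outdoor dry-bulb temperature, degC
``RH_air_out``          outdoor relative humidity, fraction 0-1
``I_glob``              global horizontal solar irradiance, W m-2
``I_dir`` / ``I_dif``   direct / diffuse horizontal components, W m-2
``I_lw_sky_pyr``        net long-wave irradiance instrument->sky, W m-2
                        (positive = net loss toward a cold sky; a config
                        switch flips the opposite sensor convention)
``U_wind_8m``           wind speed at 8 m, m s-1
``Ce``                  cloud ratio I_dif/I_glob, 0-1
======================  =======================================================

The forcing frame carries vent angles (deg), screen/curtain unfolded
fractions, injected pipe heats (W), the measured indoor CO2 concentration
(ppm) and corridor temperatures (degC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import SIGMA_SB

__all__ = [
    "SunPosition",
    "sky_temperature",
    "pyrgeometer_temperature",
    "split_global_irradiance",
    "solar_position",
    "solar_position_series",
    "SyntheticClimate",
    "synthesize_weather",
    "load_weather_csv",
    "load_forcing_csv",
    "validate_weather",
    "vertical_gradient_statistic",
    "WEATHER_COLUMNS",
    "FORCING_COLUMNS",
]

WEATHER_COLUMNS = ["T_air_out", "RH_air_out", "I_glob", "I_dir", "I_dif",
                   "I_lw_sky_pyr", "U_wind_8m", "Ce"]
FORCING_COLUMNS = ["delta_L", "delta_W", "u_thermal", "u_shading", "u_curtain",
                   "Q_rail", "Q_forcas", "Q_pe", "C_co2_ppm",
                   "T_air_Ncor", "T_air_Ecor"]

PYRGEOMETER_OFFSET_K = 5.0   # instrument body assumed 5 K above outdoor air


@dataclass(frozen=True)
class SunPosition:
    """Sun direction: azimuth from North, clockwise (rad); zenith angle (rad)."""
    azimuth: float
    zenith: float

    @property
    def above_horizon(self) -> bool:
        return self.zenith < math.pi / 2

    @property
    def elevation(self) -> float:
        return math.pi / 2 - self.zenith


# ---------------------------------------------------------------------------
# Sky temperature and irradiance splitting
# ---------------------------------------------------------------------------

def sky_temperature(T_pyr: float, I_lw_sky_pyr: float, *,
                    positive_is_loss: bool = True,
                    timestamp=None) -> float:
    """Sky black-body temperature (K) from the pyrgeometer net long-wave flux.

    ``T_sky = (T_pyr^4 - I/sigma)^(1/4)`` with I positive when the
    instrument loses heat to a colder sky.  ``positive_is_loss=False``
    flips the sensor sign convention.
    """
    I = I_lw_sky_pyr if positive_is_loss else -I_lw_sky_pyr
    radicand = T_pyr ** 4 - I / SIGMA_SB
    if radicand <= 0.0:
        when = f" at {timestamp}" if timestamp is not None else ""
        raise ValueError(
            f"non-positive radicand in sky temperature{when}: "
            f"T_pyr={T_pyr} K, I_lw={I_lw_sky_pyr} W m-2")
    return radicand ** 0.25


def pyrgeometer_temperature(T_air_out_K: float) -> float:
    """Instrument body temperature reconstructed as outdoor air + 5 K."""
    return T_air_out_K + PYRGEOMETER_OFFSET_K


def split_global_irradiance(I_glob: float, Ce: float) -> tuple[float, float]:
    """Split global horizontal irradiance into (direct, diffuse) via the
    cloud ratio Ce = I_dif/I_glob.  The sum is exact by construction."""
    I_glob = np.asarray(I_glob, dtype=float)
    Ce = np.asarray(Ce, dtype=float)
    if np.any((Ce < 0) | (Ce > 1)):
        raise ValueError("cloud ratio Ce outside [0, 1]")
    if np.any(I_glob < 0):
        raise ValueError("negative global irradiance")
    I_dif = Ce * I_glob
    I_dir = I_glob - I_dif
    if I_dir.ndim == 0:
        return float(I_dir), float(I_dif)
    return I_dir, I_dif


# ---------------------------------------------------------------------------
# Solar position (low-precision ephemeris, well under 0.5 deg error)
# ---------------------------------------------------------------------------

def _julian_day(ts: pd.Timestamp) -> float:
    ts = pd.Timestamp(ts)
    if ts.tzinfo is None:
        raise ValueError("timestamp must be timezone-aware (UTC expected)")
    ts = ts.tz_convert("UTC")
    return ts.to_julian_date()


def solar_position(timestamp, latitude: float, longitude: float) -> SunPosition:
    """Astronomical sun position for a UTC timestamp and site (deg lat/lon,
    East positive).  NOAA/Meeus low-accuracy algorithm (error < 0.02 deg in
    declination, < 0.3 deg overall including refraction neglect)."""
    az, zen = _solar_position_arrays(np.array([_julian_day(timestamp)]),
                                     latitude, longitude)
    return SunPosition(azimuth=float(az[0]), zenith=float(zen[0]))


def solar_position_series(index: pd.DatetimeIndex, latitude: float,
                          longitude: float) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised (azimuth, zenith) arrays in rad for a DatetimeIndex."""
    if index.tz is None:
        raise ValueError("index must be timezone-aware (UTC expected)")
    jd = index.tz_convert("UTC").to_julian_date().to_numpy()
    return _solar_position_arrays(jd, latitude, longitude)


def _solar_position_arrays(jd: np.ndarray, latitude: float,
                           longitude: float) -> tuple[np.ndarray, np.ndarray]:
    T = (jd - 2451545.0) / 36525.0           # Julian centuries since J2000
    L0 = np.deg2rad((280.46646 + T * (36000.76983 + 0.0003032 * T)) % 360)
    M = np.deg2rad(357.52911 + T * (35999.05029 - 0.0001537 * T))
    e = 0.016708634 - T * (0.000042037 + 0.0000001267 * T)
    C = np.deg2rad((1.914602 - T * (0.004817 + 0.000014 * T)) * np.sin(M)
                   + (0.019993 - 0.000101 * T) * np.sin(2 * M)
                   + 0.000289 * np.sin(3 * M))
    true_long = L0 + C
    omega = np.deg2rad(125.04 - 1934.136 * T)
    app_long = true_long - np.deg2rad(0.00569 + 0.00478 * np.sin(omega))
    eps0 = np.deg2rad(23.0 + (26.0 + (21.448 - T * (46.815 + T * (0.00059
                      - T * 0.001813))) / 60.0) / 60.0)
    eps = eps0 + np.deg2rad(0.00256 * np.cos(omega))
    decl = np.arcsin(np.sin(eps) * np.sin(app_long))
    # equation of time (radians of hour angle)
    y = np.tan(eps / 2.0) ** 2
    eqtime = (y * np.sin(2 * L0) - 2 * e * np.sin(M)
              + 4 * e * y * np.sin(M) * np.cos(2 * L0)
              - 0.5 * y * y * np.sin(4 * L0) - 1.25 * e * e * np.sin(2 * M))
    frac_day = (jd + 0.5) % 1.0              # UTC fraction of day
    hour_angle = 2 * np.pi * frac_day - np.pi + np.deg2rad(longitude) + eqtime
    lat = np.deg2rad(latitude)
    cos_zen = (np.sin(lat) * np.sin(decl)
               + np.cos(lat) * np.cos(decl) * np.cos(hour_angle))
    zen = np.arccos(np.clip(cos_zen, -1.0, 1.0))
    az = np.arctan2(np.sin(hour_angle),
                    np.cos(hour_angle) * np.sin(lat) - np.tan(decl) * np.cos(lat))
    az = (az + np.pi) % (2 * np.pi)          # 0 = North, clockwise
    return az, zen


# ---------------------------------------------------------------------------
# Synthetic temperate-maritime weather
# ---------------------------------------------------------------------------

@dataclass
class SyntheticClimate:
    """Parameters of the synthetic temperate-maritime (Cfb) weather generator.

    Defaults emulate the Nantes-area climate: mild winters dominated by
    overcast skies, warm summers with a larger direct-beam share.
    """
    latitude: float = 47.29
    longitude: float = -1.46
    T_mean_annual: float = 12.0      # degC
    T_seasonal_amp: float = 7.0      # degC, summer-winter half swing
    T_diurnal_amp_winter: float = 3.0
    T_diurnal_amp_summer: float = 6.0
    ce_mean_winter: float = 0.72     # cloud-ratio seasonal means
    ce_mean_summer: float = 0.35
    ce_concentration: float = 5.0    # Beta concentration of per-segment draws
    segments_per_day: int = 6        # Ce redrawn per daylight segment
    cloud_attenuation: float = 0.75  # I_glob = clear-sky * (1 - k*Ce)
    wind_mean: float = 3.5           # m s-1
    lw_clear: float = 75.0           # net LW loss under clear sky, W m-2
    lw_cloud_reduction: float = 0.85

    def __post_init__(self):
        if not (0 <= self.ce_mean_summer <= 1 and 0 <= self.ce_mean_winter <= 1):
            raise ValueError("cloud-ratio means must lie in [0, 1]")
        if self.cloud_attenuation < 0 or self.cloud_attenuation > 1:
            raise ValueError("cloud_attenuation must lie in [0, 1]")
        if self.segments_per_day < 1:
            raise ValueError("segments_per_day must be >= 1")


def _haurwitz_clear_sky(cos_zen: np.ndarray) -> np.ndarray:
    """Clear-sky global horizontal irradiance envelope (W m-2)."""
    cz = np.clip(cos_zen, 0.0, 1.0)
    out = np.zeros_like(cz)
    up = cz > 1e-3
    out[up] = 1098.0 * cz[up] * np.exp(-0.059 / cz[up])
    return out


def synthesize_weather(n_days: int, seed: int,
                       climate: SyntheticClimate | None = None,
                       start: str = "2015-01-01") -> pd.DataFrame:
    """Generate a 5-min synthetic weather series of ``n_days`` days.

    Diurnal/seasonal sinusoidal temperature, Haurwitz clear-sky irradiance
    attenuated by a per-segment cloud ratio Ce drawn from a seasonally
    shifted Beta distribution, Magnus-consistent humidity and a slowly
    varying wind.  Deterministic for a fixed seed.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    climate = climate or SyntheticClimate()
    rng = np.random.default_rng(seed)
    idx = pd.date_range(start=start, periods=n_days * 288, freq="5min", tz="UTC")
    doy = idx.dayofyear.to_numpy()
    hour = idx.hour.to_numpy() + idx.minute.to_numpy() / 60.0

    az, zen = solar_position_series(idx, climate.latitude, climate.longitude)
    cos_zen = np.cos(zen)
    I_clear = _haurwitz_clear_sky(cos_zen)

    # seasonal cloud-ratio mean: max mid-January, min mid-July
    season = np.cos(2 * np.pi * (doy - 15) / 365.25)
    ce_mean = (0.5 * (climate.ce_mean_winter + climate.ce_mean_summer)
               + 0.5 * (climate.ce_mean_winter - climate.ce_mean_summer) * season)
    # one Ce draw per day-segment
    seg = (np.arange(len(idx)) // (288 // climate.segments_per_day))
    n_seg = int(seg.max()) + 1
    seg_mean = np.zeros(n_seg)
    for s in range(n_seg):
        seg_mean[s] = ce_mean[seg == s].mean()
    k = climate.ce_concentration
    a = np.clip(seg_mean, 0.02, 0.98) * k
    b = k - a
    ce_seg = rng.beta(a, b)
    Ce = ce_seg[seg]

    I_glob = I_clear * (1.0 - climate.cloud_attenuation * Ce)
    I_glob[cos_zen <= 0] = 0.0
    I_dir, I_dif = split_global_irradiance(I_glob, Ce)

    # temperature: seasonal + diurnal (peak 15:00 local solar) + AR(1) noise
    T_season = (climate.T_mean_annual
                - climate.T_seasonal_amp * season)
    amp = (0.5 * (climate.T_diurnal_amp_winter + climate.T_diurnal_amp_summer)
           - 0.5 * (climate.T_diurnal_amp_summer - climate.T_diurnal_amp_winter)
           * season)
    solar_hour = hour + climate.longitude / 15.0
    diurnal = np.cos(2 * np.pi * (solar_hour - 15.0) / 24.0)
    noise = np.empty(len(idx))
    noise[0] = 0.0
    eps = rng.normal(0.0, 0.08, len(idx))
    for i in range(1, len(idx)):
        noise[i] = 0.995 * noise[i - 1] + eps[i]
    T_air = T_season + amp * diurnal + noise

    # humidity: high at night/overcast, drops with insolation
    RH = 0.9 - 0.25 * (I_glob / 900.0) - 0.05 * (1 - Ce) + 0.02 * rng.normal(size=len(idx))
    RH = np.clip(RH, 0.35, 0.98)

    # wind: lognormal daily level, AR within day
    day_idx = np.arange(len(idx)) // 288
    daily_wind = rng.lognormal(mean=np.log(climate.wind_mean) - 0.125, sigma=0.5,
                               size=n_days)
    wind = daily_wind[day_idx] * (1 + 0.15 * np.sin(2 * np.pi * hour / 24.0)) \
        + 0.2 * np.abs(rng.normal(size=len(idx)))

    I_lw = climate.lw_clear * (1.0 - climate.lw_cloud_reduction * Ce) \
        + 3.0 * rng.normal(size=len(idx))
    I_lw = np.clip(I_lw, 2.0, None)

    df = pd.DataFrame({
        "T_air_out": T_air,
        "RH_air_out": RH,
        "I_glob": I_glob,
        "I_dir": I_dir,
        "I_dif": I_dif,
        "I_lw_sky_pyr": I_lw,
        "U_wind_8m": wind,
        "Ce": Ce,
    }, index=idx)
    df.index.name = "timestamp"
    validate_weather(df)
    return df


# ---------------------------------------------------------------------------
# CSV loading and validation
# ---------------------------------------------------------------------------

def validate_weather(df: pd.DataFrame) -> None:
    """Check the weather-frame invariants; raise ValueError on violation."""
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing weather columns: {missing}")
    if not df.index.is_monotonic_increasing:
        raise ValueError("timestamps not monotonically increasing")
    if (df["I_glob"] < 0).any():
        raise ValueError("negative global irradiance")
    if ((df["Ce"] < 0) | (df["Ce"] > 1)).any():
        raise ValueError("cloud ratio outside [0, 1]")
    if ((df["RH_air_out"] < 0) | (df["RH_air_out"] > 1)).any():
        raise ValueError("relative humidity outside [0, 1]")
    if (df["U_wind_8m"] < 0).any():
        raise ValueError("negative wind speed")
    resid = (df["I_dir"] + df["I_dif"] - df["I_glob"]).abs()
    if (resid > 1e-6).any():
        raise ValueError("I_dir + I_dif != I_glob beyond 1e-6 W m-2")


def _load_csv(path, column_map: dict | None, required: list[str],
              max_gap_minutes: int, cadence: str) -> tuple[pd.DataFrame, list]:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    if column_map:
        df = df.rename(columns=column_map)
    if "timestamp" not in df.columns:
        raise ValueError("no 'timestamp' column after applying the column map")
    ts = pd.DatetimeIndex(df.pop("timestamp"))
    if ts.tz is None:
        ts = ts.tz_localize("UTC")
    df.index = ts
    df.index.name = "timestamp"
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory columns: {missing}")
    if not df.index.is_monotonic_increasing:
        raise ValueError("timestamps not monotonically increasing")
    full = pd.date_range(df.index[0], df.index[-1], freq=cadence, tz=df.index.tz)
    gaps = full.difference(df.index)
    df = df.reindex(full)
    limit = max(int(max_gap_minutes // 5), 1)
    df = df.ffill(limit=limit)
    flagged = [g for g in gaps if df.loc[g].isna().any()] + list(gaps)
    df.index.name = "timestamp"
    return df, sorted(set(gaps))


def load_weather_csv(path, column_map: dict | None = None,
                     max_gap_minutes: int = 30,
                     reconstruct: bool = True) -> tuple[pd.DataFrame, list]:
    """Load a 5-min weather CSV.  Returns (frame, flagged_gap_timestamps).

    Gaps up to ``max_gap_minutes`` are forward-filled; all originally
    missing rows are reported.  When ``reconstruct`` is set, absent
    ``I_dir``/``I_dif`` columns are derived from ``Ce`` and ``I_glob``.
    """
    required = ["T_air_out", "RH_air_out", "I_glob", "I_lw_sky_pyr",
                "U_wind_8m", "Ce"]
    df, gaps = _load_csv(path, column_map, required, max_gap_minutes, "5min")
    if reconstruct and ("I_dir" not in df.columns or "I_dif" not in df.columns):
        I_dir, I_dif = split_global_irradiance(df["I_glob"].to_numpy(),
                                               df["Ce"].to_numpy())
        df["I_dir"], df["I_dif"] = I_dir, I_dif
    validate_weather(df)
    return df, gaps


def load_forcing_csv(path, column_map: dict | None = None,
                     max_gap_minutes: int = 30) -> tuple[pd.DataFrame, list]:
    """Load a 5-min actuator/forcing CSV; validates actuator ranges."""
    df, gaps = _load_csv(path, column_map, FORCING_COLUMNS, max_gap_minutes, "5min")
    for c in ("delta_L", "delta_W"):
        if ((df[c] < 0) | (df[c] > 44)).any():
            raise ValueError(f"vent angle {c} outside [0, 44] deg")
    for c in ("u_thermal", "u_shading", "u_curtain"):
        if ((df[c] < 0) | (df[c] > 1)).any():
            raise ValueError(f"screen fraction {c} outside [0, 1]")
    for c in ("Q_rail", "Q_forcas", "Q_pe"):
        if (df[c] < 0).any():
            raise ValueError(f"negative injected heat in {c}")
    return df, gaps


def vertical_gradient_statistic(df: pd.DataFrame, columns: list[str],
                                threshold: float = 1.0) -> float:
    """Fraction of time the max spread across vertically stacked temperature
    sensors stays below ``threshold`` (degC)."""
    sub = df[columns]
    spread = sub.max(axis=1) - sub.min(axis=1)
    return float((spread < threshold).mean())
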