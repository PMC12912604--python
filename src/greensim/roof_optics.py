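"""Venlo roof solar transmittance: direct beam and sky-integrated diffuse.

The direct roof transmittance ``tau_r_dir = tau_g * tau_rg * tau_b``
factors into

* ``tau_g`` — glazing transmission of the saw-tooth roof, obtained by
  tracing the beam through the periodic two-slope cross-section with
  unpolarised Fresnel transmission/reflection at each pane crossing and
  Bouguer absorption in the glass; inter-span multiple reflections
  (underside reflections toward the floor, exterior reflections re-entering
  the opposite slope) are followed up to a configurable reflection order;
* ``tau_rg`` — interception by the opaque ridge + gutter strips running
  along the ridge axis, via their beam-projected shadow fraction;
* ``tau_b`` — interception by the glazing bars running down-slope,
  periodic along the ridge axis.

The diffuse transmittance ``tau_r_dif`` is the radiance-weighted average
of ``tau_r_dir`` over a discretised sky vault (default 5 deg cells) for a
selectable radiance distribution: uniform, CIE standard overcast
(Moon-Spencer), or a continuous all-sky blend driven by a clear-sky
index, with a circumsolar + horizon-gradation clear component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .weather import SunPosition

__all__ = [
    "GlazingOptics",
    "RoofGeometry",
    "RadianceModel",
    "SkyDiscretization",
    "glass_direct_transmittance",
    "glass_direct_coefficients",
    "beam_components",
    "beam_incidence_on_slopes",
    "structure_interception",
    "roof_direct_transmittance",
    "sky_radiance",
    "roof_diffuse_transmittance",
]


# ---------------------------------------------------------------------------
# Glazing: single-pane Fresnel + Bouguer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlazingOptics:
    """Single-pane glazing: refractive index, extinction (m-1), thickness (m).

    A ``tabulated`` hook (callable theta -> (tau, rho)) replaces the
    Fresnel model for exotic covers.
    """
    refractive_index: float = 1.526
    extinction_coefficient: float = 4.0
    thickness: float = 0.004
    tabulated: object = None

    def __post_init__(self):
        if self.refractive_index < 1.0:
            raise ValueError("refractive index must be >= 1")
        if self.extinction_coefficient < 0 or self.thickness < 0:
            raise ValueError("extinction and thickness must be >= 0")

    def key(self):
        return (self.refractive_index, self.extinction_coefficient,
                self.thickness, id(self.tabulated) if self.tabulated else None)


def glass_direct_coefficients(theta: float, optics: GlazingOptics
                              ) -> tuple[float, float]:
    """Unpolarised (transmittance, reflectance) of one pane at incidence
    ``theta`` (rad, 0..pi/2), including internal multiple reflections and
    Bouguer absorption along the refracted path."""
    if optics.tabulated is not None:
        return optics.tabulated(theta)
    theta = abs(theta)
    if theta >= math.pi / 2 - 1e-12:
        return 0.0, 1.0
    n = optics.refractive_index
    ci = math.cos(theta)
    st = math.sin(theta) / n
    ct = math.sqrt(max(0.0, 1.0 - st * st))
    # interface amplitude reflectances (power)
    r_s = ((ci - n * ct) / (ci + n * ct)) ** 2
    r_p = ((n * ci - ct) / (n * ci + ct)) ** 2
    a = math.exp(-optics.extinction_coefficient * optics.thickness / max(ct, 1e-9))
    tau = 0.0
    rho = 0.0
    for r in (r_s, r_p):
        denom = 1.0 - r * r * a * a
        tau += (1.0 - r) ** 2 * a / denom
        rho += r * (1.0 + (1.0 - r) ** 2 * a * a / denom)
    return tau / 2.0, rho / 2.0


def glass_direct_transmittance(theta: float, optics: GlazingOptics) -> float:
    """Unpolarised single-pane transmittance at incidence ``theta`` (rad)."""
    return glass_direct_coefficients(theta, optics)[0]


# ---------------------------------------------------------------------------
# Roof geometry and beam kinematics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RoofGeometry:
    """Venlo roof structure.

    ``greenhouse_azimuth`` is the ridge-axis azimuth (deg from North,
    positive clockwise).  Opaque elements: ridge and gutter strips
    (running along the ridge axis, one of each per span) and glazing bars
    (running down-slope, periodic along the ridge axis).  Element heights
    give the 3-D thickness used in shadow projection.
    """
    span_width: float = 4.0
    roof_slope: float = 22.0          # deg
    greenhouse_azimuth: float = -29.0  # deg from North
    n_spans: int = 6
    ridge_width: float = 0.04
    gutter_width: float = 0.12
    bar_width: float = 0.03
    bar_spacing: float = 1.0
    pane_thickness: float = 0.004
    ridge_height: float = 0.05
    gutter_height: float = 0.08
    bar_height: float = 0.02

    def __post_init__(self):
        if not 0 < self.roof_slope < 90:
            raise ValueError("roof slope must lie in (0, 90) deg")
        if self.bar_spacing <= self.bar_width:
            raise ValueError("bar spacing must exceed bar width")
        for f in ("span_width", "ridge_width", "gutter_width", "bar_width"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")

    @property
    def slope_rad(self) -> float:
        return math.radians(self.roof_slope)

    @property
    def ridge_height_above_gutter(self) -> float:
        return 0.5 * self.span_width * math.tan(self.slope_rad)

    def key(self):
        return (self.span_width, self.roof_slope, self.greenhouse_azimuth,
                self.n_spans, self.ridge_width, self.gutter_width,
                self.bar_width, self.bar_spacing, self.ridge_height,
                self.gutter_height, self.bar_height)


def beam_components(sun: SunPosition, geom: RoofGeometry
                    ) -> tuple[float, float, float]:
    """Unit vector toward the sun in the roof frame:
    x perpendicular to the ridge (horizontal), y along the ridge, z up."""
    a_rel = sun.azimuth - math.radians(geom.greenhouse_azimuth)
    sg = math.sin(sun.zenith)
    return sg * math.sin(a_rel), sg * math.cos(a_rel), math.cos(sun.zenith)


def beam_incidence_on_slopes(sun: SunPosition, geom: RoofGeometry
                             ) -> tuple[float, float]:
    """Incidence angles (rad) on the sun-facing (S1) and opposite (S2)
    roof planes.  A plane not illuminated by the beam gets pi/2."""
    if not sun.above_horizon:
        raise ValueError("sun below horizon")
    s_x, s_y, s_z = beam_components(sun, geom)
    psi = geom.slope_rad
    c1 = abs(s_x) * math.sin(psi) + s_z * math.cos(psi)
    c2 = -abs(s_x) * math.sin(psi) + s_z * math.cos(psi)
    th1 = math.acos(min(1.0, max(c1, 0.0)))
    th2 = math.acos(min(1.0, max(c2, 0.0)))
    return th1, th2


# ---------------------------------------------------------------------------
# Opaque-structure interception
# ---------------------------------------------------------------------------

def structure_interception(sun: SunPosition, geom: RoofGeometry
                           ) -> tuple[float, float]:
    """(tau_rg, tau_b): transmittances of the ridge+gutter strips and the
    glazing bars, from beam-projected shadow fractions on the periodic
    structure.  Both -> 1 as element widths -> 0."""
    s_x, s_y, s_z = beam_components(sun, geom)
    if s_z <= 1e-9:
        return 0.0, 0.0
    # ridge + gutter: horizontal shadow widths over one span period
    slant = abs(s_x) / s_z
    shadow = (geom.ridge_width + geom.ridge_height * slant
              + geom.gutter_width + geom.gutter_height * slant)
    tau_rg = max(0.0, 1.0 - min(1.0, shadow / geom.span_width))
    # bars: per-slope shadow along the ridge axis, weighted by the share of
    # beam power entering each slope (proportional to projected pane area)
    psi = geom.slope_rad
    c1 = abs(s_x) * math.sin(psi) + s_z * math.cos(psi)
    c2 = -abs(s_x) * math.sin(psi) + s_z * math.cos(psi)
    w1, w2 = max(c1, 0.0), max(c2, 0.0)
    if w1 + w2 <= 0.0:
        return tau_rg, 0.0
    f = 0.0
    for w, c in ((w1, c1), (w2, c2)):
        if w <= 0.0:
            continue
        shadow_y = geom.bar_width + geom.bar_height * abs(s_y) / max(c, 1e-9)
        f += w * min(1.0, shadow_y / geom.bar_spacing)
    tau_b = max(0.0, 1.0 - f / (w1 + w2))
    return tau_rg, tau_b


# ---------------------------------------------------------------------------
# Multi-span glazing transmission by deterministic beam tracing
# ---------------------------------------------------------------------------

_EPS = 1e-9


def _pane_hits(x, z, dx, dz, s, m, k_lo, k_hi):
    """Candidate intersections of a 2-D ray with the saw-tooth pane
    segments; yields (t, side) with side +1 for the right pane
    (normal (+sin psi, cos psi)) and -1 for the left pane."""
    h = 0.5 * s * m
    hits = []
    for k in range(k_lo, k_hi + 1):
        # left pane: z = m*(x - k*s), x in [k*s, k*s + s/2]
        den = dz - m * dx
        if abs(den) > _EPS:
            t = (m * (x - k * s) - z) / den
            if t > 1e-7:
                xi = x + t * dx
                zi = z + t * dz
                if k * s - _EPS <= xi <= k * s + 0.5 * s + _EPS and -_EPS <= zi <= h + _EPS:
                    hits.append((t, -1))
        # right pane: z = m*((k+1)*s - x), x in [k*s + s/2, (k+1)*s]
        den = dz + m * dx
        if abs(den) > _EPS:
            t = (m * ((k + 1) * s - x) - z) / den
            if t > 1e-7:
                xi = x + t * dx
                zi = z + t * dz
                if k * s + 0.5 * s - _EPS <= xi <= (k + 1) * s + _EPS and -_EPS <= zi <= h + _EPS:
                    hits.append((t, +1))
    return hits


def glazing_multispan_transmittance(sun_vec: tuple[float, float, float],
                                    geom: RoofGeometry,
                                    optics: GlazingOptics,
                                    n_rays: int = 96,
                                    max_reflection_order: int = 3,
                                    weight_cutoff: float = 1e-3) -> float:
    """Glazing transmittance tau_g of the periodic saw-tooth roof for a
    beam from direction ``sun_vec`` (unit vector toward the sun in the
    roof frame), by stratified deterministic ray tracing with Fresnel
    splitting at every pane crossing."""
    s_x, s_y, s_z = sun_vec
    if s_z <= 1e-6:
        return 0.0
    s = geom.span_width
    psi = geom.slope_rad
    m = math.tan(psi)
    h = geom.ridge_height_above_gutter
    # propagation direction (unit, downward)
    d0 = np.array([-s_x, -s_y, -s_z])
    normals = {-1: np.array([-math.sin(psi), 0.0, math.cos(psi)]),
               +1: np.array([math.sin(psi), 0.0, math.cos(psi)])}
    coeff_cache: dict = {}

    def pane_coeffs(side, d):
        key = (side, round(d[0], 9), round(d[2], 9))
        if key not in coeff_cache:
            cos_inc = abs(float(d @ normals[side]))
            theta = math.acos(min(1.0, cos_inc))
            coeff_cache[key] = glass_direct_coefficients(theta, optics)
        return coeff_cache[key]

    span_reach = geom.n_spans + 2
    transmitted = 0.0
    for i in range(n_rays):
        x0 = (i + 0.5) / n_rays * s
        # start just above ridge height; the roof is periodic in x, so the
        # stratified x0 sweep covers all entry paths
        stack = [(x0, h + 0.05, d0, 1.0, 0)]
        while stack:
            x, z, d, w, order = stack.pop()
            dx, dz = float(d[0]), float(d[2])
            k0 = math.floor(x / s)
            hits = _pane_hits(x, z, dx, dz, s, m,
                              int(k0 - span_reach), int(k0 + span_reach))
            # crossing of the gutter plane z = 0 (entry into the house)
            t_floor = math.inf
            if dz < -_EPS:
                t_floor = (0.0 - z) / dz
            t_hit = min((t for t, _ in hits), default=math.inf)
            if t_floor < t_hit:
                transmitted += w
                continue
            if not hits:
                continue   # escaped upward
            t_hit, side = min(hits, key=lambda ts: ts[0])
            xi, zi = x + t_hit * dx, z + t_hit * dz
            tau, rho = pane_coeffs(side, d)
            nvec = normals[side]
            if w * tau > weight_cutoff:
                stack.append((xi + 1e-6 * dx, zi + 1e-6 * dz, d, w * tau, order))
            if order < max_reflection_order and w * rho > weight_cutoff:
                dr = d - 2.0 * float(d @ nvec) * nvec
                stack.append((xi + 1e-6 * dr[0], zi + 1e-6 * dr[2],
                              dr, w * rho, order + 1))
    return transmitted / n_rays


def roof_direct_transmittance(sun: SunPosition, geom: RoofGeometry,
                              optics: GlazingOptics,
                              n_rays: int = 96) -> float:
    """Direct roof transmittance tau_r_dir = tau_g * tau_rg * tau_b.

    Returns 0 for a sun at or below the horizon.
    """
    if not sun.above_horizon:
        return 0.0
    vec = beam_components(sun, geom)
    tau_g = glazing_multispan_transmittance(vec, geom, optics, n_rays=n_rays)
    tau_rg, tau_b = structure_interception(sun, geom)
    return tau_g * tau_rg * tau_b


# ---------------------------------------------------------------------------
# Sky radiance distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RadianceModel:
    """Relative sky radiance L'(alpha, gamma) = L/Lz.

    kinds: ``uniform`` (L'=1), ``standard_overcast`` (Moon-Spencer
    ``(1+2 cos g)/3``), ``all_sky`` (continuous blend between the overcast
    gradation and a clear-sky gradation x circumsolar indicatrix, weighted
    by ``clear_sky_index`` in [0,1]; requires the sun position).
    """
    kind: str = "standard_overcast"
    clear_sky_index: float = 0.0
    sun: SunPosition | None = None

    def __post_init__(self):
        if self.kind not in ("uniform", "standard_overcast", "all_sky"):
            raise ValueError(f"unknown radiance model kind {self.kind!r}")
        if self.kind == "all_sky" and self.sun is None:
            raise ValueError("all_sky radiance requires the sun position")

    def key(self):
        sunkey = (round(self.sun.azimuth, 6), round(self.sun.zenith, 6)) \
            if self.sun else None
        return (self.kind, round(self.clear_sky_index, 3), sunkey)


def _clear_gradation(gamma):
    # CIE clear-sky gradation, normalised to 1 at the zenith
    cg = np.clip(np.cos(gamma), 1e-3, 1.0)
    phi = 1.0 - np.exp(-0.32 / cg)
    return phi / (1.0 - math.exp(-0.32))


def _clear_indicatrix(chi):
    # circumsolar + backscatter scattering indicatrix (CIE clear form)
    return (1.0 + 10.0 * (np.exp(-3.0 * chi) - math.exp(-3.0 * math.pi / 2))
            + 0.45 * np.cos(chi) ** 2)


def sky_radiance(alpha, gamma, model: RadianceModel):
    """Relative radiance L' of sky element(s) at azimuth ``alpha`` and
    zenith angle ``gamma`` (rad).  Vectorised over numpy inputs."""
    alpha = np.asarray(alpha, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if np.any((gamma < -1e-9) | (gamma > math.pi / 2 + 1e-9)):
        raise ValueError("sky element zenith angle outside [0, pi/2]")
    overcast = (1.0 + 2.0 * np.cos(gamma)) / 3.0
    if model.kind == "uniform":
        out = np.ones_like(gamma)
    elif model.kind == "standard_overcast":
        out = overcast
    else:
        sun = model.sun
        cos_chi = (np.cos(gamma) * math.cos(sun.zenith)
                   + np.sin(gamma) * math.sin(sun.zenith)
                   * np.cos(alpha - sun.azimuth))
        chi = np.arccos(np.clip(cos_chi, -1.0, 1.0))
        clear = (_clear_gradation(gamma) * _clear_indicatrix(chi)
                 / _clear_indicatrix(sun.zenith))
        w = min(max(model.clear_sky_index, 0.0), 1.0)
        out = (1.0 - w) * overcast + w * clear
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Diffuse transmittance by sky-vault integration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SkyDiscretization:
    """Sky vault grid: cell centres with solid-angle projection weights
    ``sin(g) cos(g) dg da`` (default 5 deg cells)."""
    d_alpha: float = 5.0
    d_gamma: float = 5.0

    def grid(self):
        da = math.radians(self.d_alpha)
        dg = math.radians(self.d_gamma)
        alphas = np.arange(da / 2, 2 * math.pi, da)
        gammas = np.arange(dg / 2, math.pi / 2, dg)
        A, G = np.meshgrid(alphas, gammas, indexing="ij")
        W = np.sin(G) * np.cos(G) * da * dg
        return A, G, W

    def key(self):
        return (self.d_alpha, self.d_gamma)


_DIFFUSE_CACHE: dict = {}


def roof_diffuse_transmittance(geom: RoofGeometry, optics: GlazingOptics,
                               model: RadianceModel | None = None,
                               disc: SkyDiscretization | None = None,
                               n_rays: int = 32) -> float:
    """Diffuse roof transmittance: radiance-weighted sky integral of the
    direct transmittance over the discretised vault.  Pure function of
    geometry/optics/radiance model, memoised."""
    model = model or RadianceModel("standard_overcast")
    disc = disc or SkyDiscretization()
    key = (geom.key(), optics.key(), model.key(), disc.key(), n_rays)
    if key in _DIFFUSE_CACHE:
        return _DIFFUSE_CACHE[key]
    A, G, W = disc.grid()
    L = sky_radiance(A, G, model)
    denom = float(np.sum(L * W))
    if denom <= 0.0:
        raise ValueError("degenerate radiance distribution (zero integral)")
    num = 0.0
    tau_cache: dict = {}
    for a, g, l, w in zip(A.ravel(), G.ravel(), L.ravel(), W.ravel()):
        if l * w == 0.0:
            continue
        sun = SunPosition(azimuth=float(a), zenith=float(g))
        vec = beam_components(sun, geom)
        # the cross-section depends on (|s_x|, |s_y|, s_z) only
        tkey = (round(abs(vec[0]), 6), round(abs(vec[1]), 6), round(vec[2], 6))
        if tkey not in tau_cache:
            tau_g = glazing_multispan_transmittance(
                (abs(vec[0]), abs(vec[1]), vec[2]), geom, optics, n_rays=n_rays)
            tau_rg, tau_b = structure_interception(sun, geom)
            tau_cache[tkey] = tau_g * tau_rg * tau_b
        num += tau_cache[tkey] * l * w
    out = num / denom
    _DIFFUSE_CACHE[key] = out
    return out
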