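import dataclasses
import math

import numpy as np
import pytest

from greensim.roof_optics import (GlazingOptics, RadianceModel, RoofGeometry,
                                  SkyDiscretization, beam_components,
                                  beam_incidence_on_slopes,
                                  glass_direct_coefficients,
                                  glass_direct_transmittance,
                                  glazing_multispan_transmittance,
                                  roof_diffuse_transmittance,
                                  roof_direct_transmittance, sky_radiance,
                                  structure_interception)
from greensim.weather import SunPosition


def sun(az_deg, zen_deg):
    return SunPosition(math.radians(az_deg), math.radians(zen_deg))


BARE = dict(ridge_width=0.0, gutter_width=0.0, bar_width=0.0,
            ridge_height=0.0, gutter_height=0.0, bar_height=0.0)


class TestGlazing:
    def test_normal_incidence_no_absorption(self):
        opt = GlazingOptics(refractive_index=1.526, extinction_coefficient=0.0)
        assert glass_direct_transmittance(0.0, opt) == pytest.approx(0.917,
                                                                     abs=1e-3)

    def test_grazing_incidence_zero(self):
        assert glass_direct_transmittance(math.pi / 2, GlazingOptics()) == 0.0

    def test_symmetry_in_incidence_sign(self):
        opt = GlazingOptics()
        for th in np.linspace(0.0, 1.5, 12):
            assert glass_direct_transmittance(th, opt) == pytest.approx(
                glass_direct_transmittance(-th, opt))

    def test_monotone_decrease_beyond_normal(self):
        opt = GlazingOptics()
        taus = [glass_direct_transmittance(t, opt)
                for t in np.linspace(0.0, math.pi / 2 - 1e-3, 60)]
        assert max(taus) == pytest.approx(taus[0], abs=1e-9)
        assert np.all(np.diff(taus[20:]) < 1e-12)

    def test_energy_budget(self):
        opt = GlazingOptics()
        for th in (0.1, 0.7, 1.2):
            tau, rho = glass_direct_coefficients(th, opt)
            assert 0.0 < tau + rho < 1.0


class TestBeamIncidence:
    def test_sun_at_zenith_gives_roof_slope(self, roof_geom):
        th1, th2 = beam_incidence_on_slopes(sun(0, 0.01), roof_geom)
        assert math.degrees(th1) == pytest.approx(22.0, abs=0.1)
        assert math.degrees(th2) == pytest.approx(22.0, abs=0.1)

    def test_ridge_aligned_sun_symmetric(self, roof_geom):
        th1, th2 = beam_incidence_on_slopes(
            sun(roof_geom.greenhouse_azimuth, 40), roof_geom)
        assert th1 == pytest.approx(th2, abs=1e-9)

    def test_matches_vector_dot_product_oracle(self, roof_geom):
        rng = np.random.default_rng(7)
        psi = roof_geom.slope_rad
        for _ in range(25):
            sp = sun(rng.uniform(0, 360), rng.uniform(1, 85))
            sx, sy, sz = beam_components(sp, roof_geom)
            n1 = np.array([math.copysign(math.sin(psi), sx), 0, math.cos(psi)])
            n2 = np.array([-n1[0], 0, math.cos(psi)])
            c1 = max(np.dot([sx, sy, sz], n1), 0.0)
            c2 = max(np.dot([sx, sy, sz], n2), 0.0)
            th1, th2 = beam_incidence_on_slopes(sp, roof_geom)
            assert math.cos(th1) == pytest.approx(c1, abs=1e-12)
            assert math.cos(th2) == pytest.approx(c2, abs=1e-12)

    def test_sun_below_horizon_rejected(self, roof_geom):
        with pytest.raises(ValueError):
            beam_incidence_on_slopes(sun(180, 95), roof_geom)


# ---------------------------------------------------------------------------
# Monte-Carlo oracles (independent of the analytic/deterministic code paths)
# ---------------------------------------------------------------------------

def _mc_ridge_gutter(sun_vec, geom, n=200_000, rng=None):
    """MC shadow test against explicit 2-D boxes at the apex and valley:
    a ground point is shadowed when its backtracked beam's x-footprint over
    the box height range overlaps the (periodic) box x-extent."""
    rng = rng or np.random.default_rng(42)
    sx, sy, sz = sun_vec
    s = geom.span_width
    h = geom.ridge_height_above_gutter
    x = rng.uniform(0.0, s, n)
    blocked = np.zeros(n, dtype=bool)
    for (cx, z0, z1, w) in ((s / 2, h, h + geom.ridge_height, geom.ridge_width),
                            (0.0, -geom.gutter_height, 0.0, geom.gutter_width)):
        if w <= 0 or z1 <= z0:
            continue
        xa = x + sx / sz * z0         # beam x at the box bottom/top heights
        xb = x + sx / sz * z1
        mid = 0.5 * (xa + xb)
        half = 0.5 * np.abs(xb - xa) + w / 2
        dist = np.abs(((mid - cx + s / 2) % s) - s / 2)
        blocked |= dist <= half
    return 1.0 - blocked.mean()


def _mc_first_pane_and_bars(sun_vec, geom, n=40_000, rng=None):
    """MC bar interception: vectorised marching finds the first pane each
    sampled ray crosses; a slab intersection test in the pane frame decides
    whether a glazing bar blocks it."""
    rng = rng or np.random.default_rng(3)
    sx, sy, sz = sun_vec
    s = geom.span_width
    psi = geom.slope_rad
    m = math.tan(psi)
    h = geom.ridge_height_above_gutter
    x = rng.uniform(0, s, n)
    y = rng.uniform(0, geom.bar_spacing, n)
    z = np.full(n, h + 0.01)
    d = -np.array([sx, sy, sz])
    # march down in z; profile(x) = m * min(x mod s, s - x mod s)
    n_steps = 400
    dzstep = (h + 0.02) / n_steps
    alive = np.ones(n, dtype=bool)
    side = np.zeros(n)           # -1 left pane, +1 right pane
    xc = np.zeros(n)
    yc = np.zeros(n)
    for _ in range(n_steps):
        t = dzstep / sz
        x = x + t * d[0]
        y = y + t * d[1]
        z = z - dzstep
        xm = np.mod(x, s)
        prof = m * np.minimum(xm, s - xm)
        crossed = alive & (z <= prof)
        side[crossed] = np.where(xm[crossed] < s / 2, -1.0, 1.0)
        xc[crossed] = x[crossed]
        yc[crossed] = y[crossed]
        alive &= ~crossed
    assert not alive.any(), "every downward ray must cross a pane"
    blocked = np.zeros(n, dtype=bool)
    P = geom.bar_spacing
    for sgn in (-1.0, 1.0):
        sel = side == sgn
        if not sel.any():
            continue
        nvec = np.array([sgn * math.sin(psi), 0.0, math.cos(psi)])
        dn = abs(float(np.dot(d, nvec)))     # into the roof plane
        # ray y-footprint while traversing the bar slab of thickness
        # bar_height along the pane normal; bars occupy [k*P, k*P + w_b]
        fl = abs(d[1]) * geom.bar_height / dn
        u = np.minimum(yc[sel], yc[sel] + np.sign(d[1]) * fl) % P
        blocked[sel] = (u < geom.bar_width) | (u + fl > P)
    return 1.0 - blocked.mean()


def _mc_glass(sun_vec, geom, optics, n=20_000, seed=5):
    """Stochastic 2-D multi-span ray tracer: explicit pane segment list,
    random Fresnel outcomes (transmit / reflect / absorb) at each crossing."""
    rng = np.random.default_rng(seed)
    sx, sy, sz = sun_vec
    s = geom.span_width
    psi = geom.slope_rad
    m = math.tan(psi)
    h = geom.ridge_height_above_gutter
    K = geom.n_spans + 3
    segs = []
    for k in range(-K, K + 1):
        segs.append(((k * s, 0.0), (k * s + s / 2, h),
                     np.array([-math.sin(psi), 0.0, math.cos(psi)])))
        segs.append(((k * s + s / 2, h), ((k + 1) * s, 0.0),
                     np.array([math.sin(psi), 0.0, math.cos(psi)])))
    transmitted = 0
    for _ in range(n):
        x = rng.uniform(0.0, s)
        z = h + 0.05
        d = np.array([-sx, -sy, -sz])
        for _bounce in range(12):
            best_t, best_n = None, None
            for (p0, p1, nv) in segs:
                ex, ez = p1[0] - p0[0], p1[1] - p0[1]
                den = d[0] * ez - d[2] * ex
                if abs(den) < 1e-14:
                    continue
                t = ((p0[0] - x) * ez - (p0[1] - z) * ex) / den
                u_den = ex if abs(ex) > abs(ez) else ez
                if t <= 1e-9:
                    continue
                xi, zi = x + t * d[0], z + t * d[2]
                u = ((xi - p0[0]) / ex) if abs(ex) > 1e-12 else ((zi - p0[1]) / ez)
                if -1e-9 <= u <= 1 + 1e-9 and (best_t is None or t < best_t):
                    best_t, best_n = t, nv
            t_floor = (0.0 - z) / d[2] if d[2] < -1e-14 else math.inf
            if best_t is None or t_floor < best_t:
                if t_floor < math.inf:
                    transmitted += 1
                break
            x, z = x + best_t * d[0], z + best_t * d[2]
            cos_inc = abs(float(d @ best_n))
            tau, rho = glass_direct_coefficients(math.acos(min(1, cos_inc)),
                                                 optics)
            r = rng.random()
            if r < tau:
                x, z = x + 1e-6 * d[0], z + 1e-6 * d[2]
                continue
            if r < tau + rho:
                d = d - 2 * float(d @ best_n) * best_n
                x, z = x + 1e-6 * d[0], z + 1e-6 * d[2]
                continue
            break   # absorbed
    return transmitted / n


class TestStructureInterception:
    def test_no_opaque_elements(self, roof_geom):
        g = dataclasses.replace(roof_geom, **BARE)
        assert structure_interception(sun(180, 40), g) == (1.0, 1.0)

    def test_fully_opaque(self, roof_geom):
        g = dataclasses.replace(
            roof_geom, ridge_width=2.0, gutter_width=2.0,
            bar_width=0.99, bar_spacing=1.0)
        tau_rg, tau_b = structure_interception(sun(151, 5), g)
        assert tau_rg == 0.0
        assert tau_b <= 0.02

    @pytest.mark.parametrize("az,zen", [(151, 20), (100, 55), (220, 70)])
    def test_matches_monte_carlo_ray_sampling(self, roof_geom, az, zen):
        sp = sun(az, zen)
        vec = beam_components(sp, roof_geom)
        tau_rg, tau_b = structure_interception(sp, roof_geom)
        assert tau_rg == pytest.approx(_mc_ridge_gutter(vec, roof_geom),
                                       abs=0.01)
        assert tau_b == pytest.approx(_mc_first_pane_and_bars(vec, roof_geom),
                                      abs=0.01)


class TestRoofDirectTransmittance:
    def test_flat_pane_limit_equals_single_glass(self, glazing):
        g = RoofGeometry(roof_slope=0.5, **BARE)
        for zen in (10, 35, 60):
            sp = sun(200, zen)
            assert roof_direct_transmittance(sp, g, glazing, n_rays=200) == \
                pytest.approx(glass_direct_transmittance(sp.zenith, glazing),
                              abs=2e-3)

    def test_below_horizon_zero(self, roof_geom, glazing):
        assert roof_direct_transmittance(sun(0, 95), roof_geom, glazing) == 0.0

    def test_in_unit_interval(self, roof_geom, glazing):
        rng = np.random.default_rng(1)
        for _ in range(10):
            tau = roof_direct_transmittance(
                sun(rng.uniform(0, 360), rng.uniform(2, 88)),
                roof_geom, glazing)
            assert 0.0 <= tau <= 1.0

    @pytest.mark.parametrize("az,zen", [(151, 30), (120, 60), (200, 75)])
    def test_glazing_matches_stochastic_ray_oracle(self, roof_geom, glazing,
                                                   az, zen):
        vec = beam_components(sun(az, zen), roof_geom)
        det = glazing_multispan_transmittance(vec, roof_geom, glazing,
                                              n_rays=200)
        mc = _mc_glass(vec, roof_geom, glazing)
        assert det == pytest.approx(mc, abs=0.01)


class TestSkyRadiance:
    def test_overcast_zenith_is_unity(self):
        assert sky_radiance(0.0, 0.0, RadianceModel("standard_overcast")) \
            == pytest.approx(1.0)

    def test_overcast_horizon_is_one_third(self):
        assert sky_radiance(1.0, math.pi / 2,
                            RadianceModel("standard_overcast")) \
            == pytest.approx(1.0 / 3.0)

    def test_uniform(self):
        assert sky_radiance(2.0, 0.7, RadianceModel("uniform")) == 1.0

    def test_all_sky_clear_peaks_near_sun(self):
        sp = sun(180, 50)
        model = RadianceModel("all_sky", clear_sky_index=1.0, sun=sp)
        A, G = np.meshgrid(np.radians(np.arange(2.5, 360, 5)),
                           np.radians(np.arange(2.5, 90, 5)), indexing="ij")
        L = sky_radiance(A, G, model)
        ia, ig = np.unravel_index(np.argmax(L), L.shape)
        chi = math.acos(math.cos(G[ia, ig]) * math.cos(sp.zenith)
                        + math.sin(G[ia, ig]) * math.sin(sp.zenith)
                        * math.cos(A[ia, ig] - sp.azimuth))
        assert math.degrees(chi) < 8.0

    def test_all_sky_overcast_limit(self):
        model = RadianceModel("all_sky", clear_sky_index=0.0, sun=sun(180, 50))
        g = np.linspace(0, math.pi / 2, 20)
        assert np.allclose(sky_radiance(0.0, g, model), (1 + 2 * np.cos(g)) / 3)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            RadianceModel("cubist")


class TestRoofDiffuseTransmittance:
    def test_constant_integrand_recovers_constant(self, roof_geom):
        # a flat single-pane roof with angle-independent tabulated optics
        g = RoofGeometry(roof_slope=0.5, **BARE)
        opt = GlazingOptics(tabulated=lambda th: (0.8, 0.0))
        tau = roof_diffuse_transmittance(g, opt, RadianceModel("uniform"),
                                         n_rays=16)
        assert tau == pytest.approx(0.8, abs=1e-6)

    def test_discretization_convergence(self, roof_geom, glazing):
        t10 = roof_diffuse_transmittance(roof_geom, glazing,
                                         RadianceModel("standard_overcast"),
                                         SkyDiscretization(10.0, 10.0))
        t5 = roof_diffuse_transmittance(roof_geom, glazing,
                                        RadianceModel("standard_overcast"),
                                        SkyDiscretization(5.0, 5.0))
        assert abs(t5 - t10) < 0.005

    def test_uniform_sky_rotation_invariance(self, roof_geom, glazing):
        rotated = dataclasses.replace(roof_geom, greenhouse_azimuth=41.0)
        t1 = roof_diffuse_transmittance(roof_geom, glazing,
                                        RadianceModel("uniform"))
        t2 = roof_diffuse_transmittance(rotated, glazing,
                                        RadianceModel("uniform"))
        assert t1 == pytest.approx(t2, abs=1e-9)

    def test_within_unit_interval_all_models(self, roof_geom, glazing):
        for model in (RadianceModel("uniform"),
                      RadianceModel("standard_overcast"),
                      RadianceModel("all_sky", clear_sky_index=0.7,
                                    sun=sun(180, 50))):
            tau = roof_diffuse_transmittance(roof_geom, glazing, model,
                                             SkyDiscretization(10, 10),
                                             n_rays=16)
            assert 0.0 < tau < 1.0
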