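import math

import numpy as np
import pytest

from greensim.constants import SIGMA_SB
from greensim.radiation import (RadLink, Scene, SurfaceNode,
                                compute_view_factor_cellpair,
                                net_radiative_exchange,
                                screen_medium_transmissivity,
                                sky_and_boundary_exchange, subdivide_quad,
                                tilt_split_factors, view_factor_between_meshes,
                                viewfactor_pipeline, quad_area)


def mc_view_factor(quad_a, quad_b, n=200_000, seed=0):
    """Monte-Carlo view factor: cosine-weighted rays from quad_a tested
    against quad_b (two-triangle intersection)."""
    rng = np.random.default_rng(seed)
    a0 = quad_a[0]
    eu = quad_a[1] - quad_a[0]
    ev = quad_a[3] - quad_a[0]
    nrm = np.cross(eu, ev)
    nrm = nrm / np.linalg.norm(nrm)
    # orient the normal toward quad_b
    if np.dot(quad_b.mean(axis=0) - quad_a.mean(axis=0), nrm) < 0:
        nrm = -nrm
    t1 = eu / np.linalg.norm(eu)
    t2 = np.cross(nrm, t1)
    pts = (a0[None, :] + rng.uniform(0, 1, (n, 1)) * eu[None, :]
           + rng.uniform(0, 1, (n, 1)) * ev[None, :])
    u1, u2 = rng.uniform(0, 1, n), rng.uniform(0, 1, n)
    ct = np.sqrt(1 - u1)
    st = np.sqrt(u1)
    phi = 2 * np.pi * u2
    dirs = (st[:, None] * np.cos(phi)[:, None] * t1[None, :]
            + st[:, None] * np.sin(phi)[:, None] * t2[None, :]
            + ct[:, None] * nrm[None, :])
    hits = np.zeros(n, dtype=bool)
    for tri in (quad_b[[0, 1, 2]], quad_b[[0, 2, 3]]):
        v0, e1, e2 = tri[0], tri[1] - tri[0], tri[2] - tri[0]
        h = np.cross(dirs, e2)
        a = h @ e1
        ok = np.abs(a) > 1e-12
        f = np.where(ok, 1.0 / np.where(ok, a, 1.0), 0.0)
        s = pts - v0
        u = f * np.einsum("md,md->m", s, h)
        q = np.cross(s, e1)
        v = f * np.einsum("md,md->m", q, dirs)
        t = f * (q @ e2)
        hits |= ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 1e-9)
    return hits.mean()


def crossed_strings(x1a, x1b, x2a, x2b, h):
    """2-D crossed-strings view factor between strip [x1a,x1b] at z=0 and
    strip [x2a,x2b] at z=h."""
    d = lambda xa, xb: math.hypot(xb - xa, h)
    crossed = d(x1a, x2b) + d(x1b, x2a)
    uncrossed = d(x1a, x2a) + d(x1b, x2b)
    return (crossed - uncrossed) / (2 * (x1b - x1a))


SQ_A = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
SQ_B = np.array([[0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], float)


class TestNetExchange:
    N1 = SurfaceNode("a", 1.0, 1.0)
    N2 = SurfaceNode("b", 1.0, 1.0)

    def test_zero_at_equal_temperature(self):
        q = net_radiative_exchange(self.N1, self.N2, 1.0, 1.0, 300.0, 300.0)
        assert q == 0.0

    def test_black_body_hand_value(self):
        q = net_radiative_exchange(self.N1, self.N2, 1.0, 1.0, 300.0, 290.0)
        assert q == pytest.approx(SIGMA_SB * (300**4 - 290**4), rel=1e-12)
        assert q == pytest.approx(58.2, abs=0.15)

    def test_opaque_medium_blocks(self):
        q = net_radiative_exchange(self.N1, self.N2, 1.0, 1.0, 300.0, 290.0,
                                   tau_media=(0.0,))
        assert q == 0.0

    def test_antisymmetric_under_swap(self):
        n1 = SurfaceNode("a", 2.0, 0.9)
        n2 = SurfaceNode("b", 4.0, 0.85)
        FF12, FF21 = 0.6, 0.3   # respects A1*FF12 = A2*FF21
        q12 = net_radiative_exchange(n1, n2, FF12, FF21, 305.0, 290.0, (0.8,))
        q21 = net_radiative_exchange(n2, n1, FF21, FF12, 290.0, 305.0, (0.8,))
        assert q12 == pytest.approx(-q21, rel=1e-12)

    def test_screen_medium_mix(self):
        assert screen_medium_transmissivity(0.0, 0.25) == 1.0
        assert screen_medium_transmissivity(1.0, 0.25) == 0.25
        assert screen_medium_transmissivity(0.5, 0.25) == pytest.approx(0.625)


class TestCellPairViewFactor:
    def test_parallel_unit_squares_catalog_value(self):
        assert compute_view_factor_cellpair(SQ_A, SQ_B) == pytest.approx(
            0.1998, abs=0.002)

    def test_perpendicular_adjacent_catalog_value(self):
        sq_c = np.array([[0, 0, 0], [1, 0, 0], [1, 0, 1], [0, 0, 1]], float)
        assert compute_view_factor_cellpair(SQ_A, sq_c) == pytest.approx(
            0.20004, abs=0.002)

    def test_full_occluder_blocks(self):
        occ = np.array([[[-1, -1, 0.5], [2, -1, 0.5], [2, 2, 0.5]],
                        [[-1, -1, 0.5], [2, 2, 0.5], [-1, 2, 0.5]]])
        assert compute_view_factor_cellpair(SQ_A, SQ_B, occ) == 0.0

    def test_reciprocity_on_random_pairs(self):
        rng = np.random.default_rng(8)
        for _ in range(6):
            qa = SQ_A * rng.uniform(0.5, 2.0)
            shift = rng.uniform(-1, 1, 3) + [0, 0, 1.5]
            qb = SQ_B * rng.uniform(0.5, 2.0) + shift
            Fab = compute_view_factor_cellpair(qa, qb)
            Fba = compute_view_factor_cellpair(qb, qa)
            assert quad_area(qa) * Fab == pytest.approx(
                quad_area(qb) * Fba, abs=1e-3)

    def test_degenerate_polygon_rejected(self):
        bad = np.zeros((4, 3))
        with pytest.raises(ValueError):
            compute_view_factor_cellpair(bad, SQ_B)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_monte_carlo_ray_sampling(self, seed):
        rng = np.random.default_rng(seed)
        qa = SQ_A * rng.uniform(0.8, 1.5)
        qb = (SQ_B + rng.uniform(-0.5, 0.5, 3)) * rng.uniform(0.8, 1.5)
        qb[:, 2] = np.abs(qb[:, 2]) + 0.8
        F = compute_view_factor_cellpair(qa, qb)
        F_mc = mc_view_factor(qa, qb)
        assert F == pytest.approx(F_mc, abs=max(0.02 * F, 0.004))


class TestCrossedStrings:
    def test_floor_to_roof_strips(self):
        """Long parallel strips approach the 2-D crossed-strings value."""
        L = 500.0
        floor = np.array([[0, 0, 0], [L, 0, 0], [L, 3, 0], [0, 3, 0]], float)
        roof = np.array([[0, 1, 4], [L, 1, 4], [L, 5, 4], [0, 5, 4]], float)
        cells_f = subdivide_quad(floor, 4.0)
        cells_r = subdivide_quad(roof, 4.0)
        F = view_factor_between_meshes(cells_f, cells_r)
        F2d = crossed_strings(0.0, 3.0, 1.0, 5.0, 4.0)
        assert F == pytest.approx(F2d, rel=0.02)


def _tiny_scene(h, w):
    sc = Scene()
    sc.add("floor", np.array([[0, 0, 0], [8, 0, 0], [8, 6, 0], [0, 6, 0]],
                             float))
    sc.add("roof", np.array([[0, 0, 4], [8, 0, 4], [8, 6, 4], [0, 6, 4]],
                            float))
    cw = max(w, 0.05) * 6.0
    y0, y1 = (6 - cw) / 2, (6 + cw) / 2
    sc.add("canopy", np.array([[1, y0, max(h, 0.05)], [7, y0, max(h, 0.05)],
                               [7, y1, max(h, 0.05)], [1, y1, max(h, 0.05)]],
                              float), occludes=True)
    return sc


@pytest.fixture(scope="module")
def vfset():
    return viewfactor_pipeline(_tiny_scene, crop_heights=(0.1, 1.0, 2.0),
                               crop_widths=(0.2, 0.8), cell_size=2.0)


class TestPipeline:

    def test_rows_normalised_to_one(self, vfset):
        for h, w in ((0.5, 0.5), (1.5, 0.3)):
            M = vfset.matrix(h, w)
            assert np.allclose(M.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_crop_minimises_canopy_factors(self, vfset):
        M_small = vfset.raw_matrix(0.1, 0.2)
        M_big = vfset.raw_matrix(2.0, 0.8)
        i_f = vfset.names.index("floor")
        i_c = vfset.names.index("canopy")
        i_r = vfset.names.index("roof")
        assert M_small[i_f, i_c] < M_big[i_f, i_c]
        assert M_small[i_f, i_r] > M_big[i_f, i_r]

    def test_reciprocity_recorded_within_tolerance(self, vfset):
        assert vfset.reciprocity_max_err < 0.02

    def test_json_round_trip(self, vfset, tmp_path):
        from greensim.radiation import ViewFactorSet
        path = tmp_path / "vf.json"
        vfset.to_json(path)
        back = ViewFactorSet.from_json(path)
        assert np.allclose(back.matrix(1.0, 0.5), vfset.matrix(1.0, 0.5))


class TestSkyBoundary:
    def test_tilt_split_limits(self):
        assert tilt_split_factors(0.0) == pytest.approx((1.0, 0.0))
        assert tilt_split_factors(90.0) == pytest.approx((0.5, 0.5))

    def test_isotropic_tilt_formula(self):
        for psi in (10.0, 22.0, 60.0):
            f_sky, f_gnd = tilt_split_factors(psi)
            assert f_sky == pytest.approx((1 + math.cos(math.radians(psi))) / 2)
            assert f_sky + f_gnd == pytest.approx(1.0)

    def test_equilibrium_no_exchange(self):
        node = SurfaceNode("roof", 100.0, 0.9)
        assert sky_and_boundary_exchange(node, 280.0, 280.0, 280.0, 22.0) == 0.0

    def test_cold_sky_drains_heat(self):
        node = SurfaceNode("roof", 100.0, 0.9)
        q = sky_and_boundary_exchange(node, 280.0, 260.0, 278.0, 22.0)
        assert q > 0.0


def test_isothermal_scene_closure():
    """Sum of all pairwise net fluxes over a closed isothermal network is
    zero to machine precision."""
    nodes = [SurfaceNode(f"s{i}", a, e) for i, (a, e) in
             enumerate([(10, 0.9), (20, 0.8), (15, 0.95)])]
    FF = np.array([[0.0, 0.6, 0.4], [0.3, 0.0, 0.7],
                   [10 * 0.4 / 15, 20 * 0.7 / 15, 0.0]])
    T = 293.15
    total = 0.0
    for i in range(3):
        for j in range(3):
            if i != j:
                total += net_radiative_exchange(nodes[i], nodes[j],
                                                FF[i, j], FF[j, i], T, T)
    assert total == 0.0
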