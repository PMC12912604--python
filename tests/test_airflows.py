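import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from greensim.airflows import (CrackConfig, ScreenGapConfig, VentConfig,
                               buoyancy_vent_flow, crack_flow, screen_gap_flow,
                               species_to_sensible_heat, total_vent_flow,
                               vent_leak_equivalent_angle, vent_leak_flow,
                               ventilation_function,
                               volumetric_to_species_flows, wind_at_roof_height,
                               wind_vent_flow)
from greensim.moist_air import state_from_TRH

CFG = VentConfig(L_O=1.5, H_O=0.8, C_f=0.6, psi_r=22.0)


class TestBuoyancyFlow:
    def test_closed_vent(self):
        assert buoyancy_vent_flow(0.0, CFG, 1.16, 1.20) == 0.0

    def test_equal_densities(self):
        assert buoyancy_vent_flow(30.0, CFG, 1.18, 1.18) == 0.0

    def test_hand_value_at_full_opening(self):
        f = buoyancy_vent_flow(44.0, CFG, 1.16, 1.20)
        assert f == pytest.approx(0.080, abs=1e-3)

    def test_clamps_beyond_range_with_warning(self):
        with pytest.warns(UserWarning):
            f = buoyancy_vent_flow(50.0, CFG, 1.16, 1.20)
        assert f == buoyancy_vent_flow(44.0, CFG, 1.16, 1.20)


class TestVentilationFunctions:
    def test_zero_at_closed(self):
        assert ventilation_function(0.0, "leeward") == 0.0
        assert ventilation_function(0.0, "windward") == 0.0

    def test_leeward_exponential_value(self):
        assert ventilation_function(14.5, "leeward") == pytest.approx(
            2.46e-2 * (1 - math.exp(-1)), abs=1e-5)

    def test_windward_quadratic_value(self):
        assert ventilation_function(44.0, "windward") == pytest.approx(
            0.0615, abs=1e-4)

    def test_windward_monotone_on_range(self):
        g = [ventilation_function(d, "windward") for d in np.linspace(0, 44, 45)]
        assert np.all(np.diff(g) > 0)

    def test_unknown_set_rejected(self):
        with pytest.raises(ValueError):
            ventilation_function(10.0, "leeward", "nonexistent")


class TestWindFlow:
    def test_no_wind_no_flow(self):
        assert wind_vent_flow(30.0, CFG, 0.0, "leeward") == 0.0

    def test_hand_value(self):
        f = wind_vent_flow(29.0, CFG, 3.0, "leeward")
        assert f == pytest.approx(0.0766, abs=5e-4)

    def test_linear_in_wind(self):
        f1 = wind_vent_flow(25.0, CFG, 2.0, "windward")
        f2 = wind_vent_flow(25.0, CFG, 4.0, "windward")
        assert f2 == pytest.approx(2 * f1)


class TestTotalVentFlow:
    def test_zero_wind_reduces_to_buoyancy(self):
        f = total_vent_flow(30.0, 30.0, CFG, 1.16, 1.20, 0.0)
        b = (CFG.N_L * buoyancy_vent_flow(30.0, CFG, 1.16, 1.20)
             + CFG.N_W * buoyancy_vent_flow(30.0, CFG, 1.16, 1.20))
        assert f == pytest.approx(b)

    def test_equal_densities_reduces_to_wind(self):
        f = total_vent_flow(30.0, 30.0, CFG, 1.18, 1.18, 3.0)
        w = (CFG.N_L * wind_vent_flow(30.0, CFG, 3.0, "leeward")
             + CFG.N_W * wind_vent_flow(30.0, CFG, 3.0, "windward"))
        assert f == pytest.approx(w)

    def test_quadrature_identity(self):
        b = total_vent_flow(30.0, 30.0, CFG, 1.16, 1.20, 0.0)
        # find the wind speed making the wind aggregate equal to b
        w_agg = (CFG.N_L * wind_vent_flow(30.0, CFG, 1.0, "leeward")
                 + CFG.N_W * wind_vent_flow(30.0, CFG, 1.0, "windward"))
        U = b / w_agg
        f = total_vent_flow(30.0, 30.0, CFG, 1.16, 1.20, U)
        assert f == pytest.approx(math.sqrt(2) * b, rel=1e-9)

    def test_continuity_near_zero_drivers(self):
        eps_vals = [1e-3, 1e-6, 1e-9]
        flows = [total_vent_flow(10.0, 5.0, CFG, 1.18 + e, 1.18, e)
                 for e in eps_vals]
        assert flows[0] > flows[1] > flows[2] >= 0.0
        assert flows[2] < 1e-4


class TestVentLeak:
    def test_zero_height_no_leak(self):
        cfg = VentConfig(h_vent_leak=0.0)
        assert vent_leak_flow(cfg, 1.16, 1.20, 3.0) == 0.0

    def test_equivalent_angle_root(self):
        cfg = VentConfig(H_O=0.8, psi_r=22.0, h_vent_leak=6.0)
        d = vent_leak_equivalent_angle(cfg)
        psi = math.radians(22.0)
        opening = 0.8 * (math.sin(psi) - math.sin(psi - math.radians(d)))
        assert opening == pytest.approx(0.006, abs=1e-9)

    def test_leak_increases_with_wind(self):
        cfg = VentConfig(h_vent_leak=6.0)
        f1 = vent_leak_flow(cfg, 1.18, 1.18, 1.0)
        f2 = vent_leak_flow(cfg, 1.18, 1.18, 4.0)
        assert f2 > f1 > 0.0


class TestCrackFlow:
    CRACK = CrackConfig(eta=0.01, n=0.65)

    def test_zero_at_no_pressure_difference(self):
        assert crack_flow(0.0, self.CRACK) == 0.0

    def test_power_law_hand_value(self):
        assert crack_flow(4.0, self.CRACK) == pytest.approx(0.0246, abs=1e-4)

    @given(dp=st.floats(0.01, 100.0))
    @settings(max_examples=40, deadline=None)
    def test_antisymmetry(self, dp):
        assert crack_flow(-dp, self.CRACK) == pytest.approx(
            -crack_flow(dp, self.CRACK))

    def test_smooth_variant_matches_away_from_zero(self):
        assert crack_flow(10.0, self.CRACK, smooth_pa=0.1) == pytest.approx(
            crack_flow(10.0, self.CRACK), rel=1e-3)


class TestScreenGapFlow:
    GAP = ScreenGapConfig(g_thermal=1e-3, g_shading=2e-3, free_coeff=0.05,
                          g_edge=2e-4, area=1000.0)

    def test_no_screens_free_opening_only(self):
        f = screen_gap_flow(0.0, 0.0, 4.0, self.GAP)
        expected = (self.GAP.free_coeff * 2.0 + self.GAP.g_edge * 4.0) * 1000.0
        assert f == pytest.approx(expected)

    def test_both_deployed_series_conductance(self):
        f = screen_gap_flow(1.0, 1.0, 5.0, self.GAP)
        g_ser = 1e-3 * 2e-3 / 3e-3
        assert f == pytest.approx((g_ser * 5.0 + 2e-4 * 5.0) * 1000.0)

    def test_partial_deployment_matches_state_enumeration(self):
        u1, u2, dp = 0.5, 0.5, 3.0
        states = {(0, 0): self.GAP.free_coeff * math.sqrt(dp),
                  (1, 0): self.GAP.g_thermal * dp,
                  (0, 1): self.GAP.g_shading * dp,
                  (1, 1): (1e-3 * 2e-3 / 3e-3) * dp}
        expected = sum(states[(a, b)]
                       * (u1 if a else 1 - u1) * (u2 if b else 1 - u2)
                       for a in (0, 1) for b in (0, 1))
        expected = (expected + self.GAP.g_edge * dp) * self.GAP.area
        assert screen_gap_flow(u1, u2, dp, self.GAP) == pytest.approx(expected)

    def test_sign_follows_pressure(self):
        assert screen_gap_flow(0.3, 0.6, -2.0, self.GAP) < 0.0


class TestSpeciesConversion:
    def test_identical_states_bilateral_zero_net(self):
        s = state_from_TRH(293.15, 0.6, 101325.0, 100.0)
        net, g1, g2 = volumetric_to_species_flows(0.5, s, s, "bilateral")
        assert np.allclose(net, 0.0)
        assert np.allclose(g1, g2)

    def test_unilateral_dry_air_hand_value(self):
        hi = state_from_TRH(293.15, 0.0, 101325.0, 100.0, C_co2_ppm=0.0)
        lo = state_from_TRH(293.15, 0.0, 101000.0, 100.0, C_co2_ppm=0.0)
        net, g1, g2 = volumetric_to_species_flows(1.0, hi, lo, "unilateral")
        assert net[0] == pytest.approx(1.204, abs=2e-3)
        assert np.allclose(g2, 0.0)

    def test_species_sum_to_moist_air_mass_flow(self):
        s = state_from_TRH(295.0, 0.7, 101325.0, 50.0, 800.0)
        _, g1, _ = volumetric_to_species_flows(0.3, s, s, "bilateral")
        assert g1.sum() == pytest.approx(0.3 * s.rho, rel=1e-3)

    def test_mass_conservation_between_zones(self):
        a = state_from_TRH(298.0, 0.5, 101325.0, 100.0)
        b = state_from_TRH(288.0, 0.8, 101300.0, 100.0)
        net, g1, g2 = volumetric_to_species_flows(0.7, a, b, "bilateral")
        assert np.allclose(net, g1 - g2)


class TestSensibleHeat:
    def test_celsius_reference_zero(self):
        g = np.array([1.0, 0.01, 0.001])
        assert species_to_sensible_heat(g, g, 0.0, 0.0) == 0.0

    def test_hand_value(self):
        g1 = np.array([1.204, 0.0, 0.0])
        q = species_to_sensible_heat(g1, np.zeros(3), 20.0, 10.0)
        assert q == pytest.approx(24200.0, abs=100.0)

    def test_antisymmetric_under_zone_swap(self):
        g1 = np.array([0.5, 0.004, 0.0003])
        g2 = np.array([0.45, 0.006, 0.0002])
        q12 = species_to_sensible_heat(g1, g2, 18.0, 24.0)
        q21 = species_to_sensible_heat(g2, g1, 24.0, 18.0)
        assert q12 == pytest.approx(-q21)


def test_wind_log_profile():
    assert wind_at_roof_height(3.0, 8.0) == pytest.approx(3.0)
    assert wind_at_roof_height(3.0, 7.78) < 3.0
    assert wind_at_roof_height(0.0, 7.78) == 0.0
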