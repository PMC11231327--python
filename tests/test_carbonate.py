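"""Seawater CO2 system solver, gas exchange and the atmospheric box."""

import numpy as np
import pytest

from sixbox.carbonate import (AtmosphereBox, atmosphere_step,
                              equilibrium_constants, gas_exchange_flux,
                              piston_velocity, schmidt_number, solve_carbonate)


def oracle_pco2(dic_umol, alk_umol, theta, salinity):
    """Independent check: fine-grid pH bisection with re-derived speciation.

    Uses the same constants but an independently coded alkalinity balance
    written in terms of the bicarbonate/carbonate fractions of DIC.
    """
    ks = equilibrium_constants(theta, salinity)
    dic, alk = dic_umol * 1e-6, alk_umol * 1e-6

    def alk_of_ph(ph):
        h = 10.0 ** -ph
        k1, k2 = float(ks["K1"]), float(ks["K2"])
        gamma = 1.0 / (1.0 + k1 / h + k1 * k2 / h ** 2)  # CO2* fraction
        co2 = dic * gamma
        hco3 = co2 * k1 / h
        co3 = hco3 * k2 / h
        borate = float(ks["BT"]) / (1.0 + h / float(ks["KB"]))
        return hco3 + 2 * co3 + borate + float(ks["KW"]) / h - h

    lo, hi = 2.0, 12.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if alk_of_ph(mid) < alk:
            lo = mid
        else:
            hi = mid
    h = 10.0 ** (-0.5 * (lo + hi))
    k1, k2 = float(ks["K1"]), float(ks["K2"])
    co2 = dic / (1.0 + k1 / h + k1 * k2 / h ** 2)
    return co2 / float(ks["K0"]) * 1e6


class TestConstants:
    def test_literature_check_values_25C_S35(self):
        ks = equilibrium_constants(25.0, 35.0)
        assert -np.log10(ks["K1"]) == pytest.approx(5.847, abs=0.002)
        assert -np.log10(ks["K2"]) == pytest.approx(8.966, abs=0.002)
        assert ks["K0"] == pytest.approx(0.0284, rel=0.002)
        assert ks["BT"] == pytest.approx(4.157e-4, rel=1e-6)


class TestSolver:
    def test_matches_independent_oracle(self):
        # surface Atlantic control-like inputs
        mine = solve_carbonate(2100.0, 2350.0, 20.0, 35.5)
        ref = oracle_pco2(2100.0, 2350.0, 20.0, 35.5)
        assert float(mine.pco2_ocean) == pytest.approx(ref, rel=0.01)

    @pytest.mark.parametrize("dic,alk,theta,sal", [
        (2100.0, 2300.0, -1.0, 34.75),
        (2400.0, 2400.0, 4.0, 35.5),
        (1900.0, 2450.0, 30.0, 36.0),
    ])
    def test_oracle_across_conditions(self, dic, alk, theta, sal):
        mine = solve_carbonate(dic, alk, theta, sal)
        assert float(mine.pco2_ocean) == pytest.approx(
            oracle_pco2(dic, alk, theta, sal), rel=0.01)

    def test_speciation_sums_to_dic(self):
        sol = solve_carbonate(2100.0, 2350.0, 20.0, 35.5)
        assert float(sol.co2_aq + sol.hco3 + sol.co3) == pytest.approx(
            2100.0, rel=1e-8)

    def test_alkalinity_closure(self):
        sol = solve_carbonate(2100.0, 2350.0, 20.0, 35.5)
        ks = equilibrium_constants(20.0, 35.5)
        h = float(sol.h_conc)
        borate = float(ks["BT"]) * float(ks["KB"]) / (float(ks["KB"]) + h)
        alk = (float(sol.hco3) + 2 * float(sol.co3)) * 1e-6 \
            + borate + float(ks["KW"]) / h - h
        assert alk == pytest.approx(2350.0e-6, rel=1e-6)

    def test_high_alkalinity_drives_pco2_to_zero(self):
        weak = solve_carbonate(2100.0, 2350.0, 20.0, 35.5)
        strong = solve_carbonate(2100.0, 3800.0, 20.0, 35.5)
        assert float(strong.pco2_ocean) < 0.05 * float(weak.pco2_ocean)

    def test_monotone_in_dic_and_alk(self, rng):
        dic = rng.uniform(1800, 2400, 1000)
        alk = rng.uniform(2250, 2500, 1000)
        base = solve_carbonate(dic, alk, 20.0, 35.0).pco2_ocean
        up_dic = solve_carbonate(dic + 10.0, alk, 20.0, 35.0).pco2_ocean
        up_alk = solve_carbonate(dic, alk + 10.0, 20.0, 35.0).pco2_ocean
        assert np.all(up_dic > base)
        assert np.all(up_alk < base)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            solve_carbonate(10.0, 2300.0, 20.0, 35.0)
        with pytest.raises(ValueError):
            solve_carbonate(2100.0, 2300.0, 90.0, 35.0)


class TestGasExchange:
    def test_zero_at_equilibrium(self):
        f = gas_exchange_flux(280.0, 280.0, 5.0, 1.0, 6.8e13, 0.337, 20.0,
                              0.03)
        assert f == 0.0

    def test_deep_boxes_exchange_nothing(self):
        f = gas_exchange_flux(400.0, 280.0, 0.0, 0.0, 6.8e13, 0.337, 4.0, 0.04)
        assert f == 0.0

    def test_wind_speed_squared(self):
        k1 = piston_velocity(5.0, 20.0, 0.337)
        k2 = piston_velocity(10.0, 20.0, 0.337)
        assert k2 == pytest.approx(4.0 * k1, rel=1e-12)

    def test_schmidt_number_reference(self):
        assert float(schmidt_number(20.0)) == pytest.approx(668.0, rel=0.01)

    def test_flux_sign_follows_gradient(self):
        into = gas_exchange_flux(260.0, 280.0, 5.0, 1.0, 1e13, 0.337, 20.0, 0.03)
        out = gas_exchange_flux(300.0, 280.0, 5.0, 1.0, 1e13, 0.337, 20.0, 0.03)
        assert into > 0 > out


class TestAtmosphere:
    def test_clamped_mode_ignores_flux(self):
        atm = AtmosphereBox(280.0, mode="clamped")
        assert atmosphere_step(atm, 1e10, 3600.0).pco2_atm == 280.0

    def test_zero_flux_leaves_pco2(self):
        atm = AtmosphereBox(280.0, mode="prognostic")
        assert atmosphere_step(atm, 0.0, 3600.0).pco2_atm == 280.0

    def test_inventory_arithmetic(self):
        """Removing 1.773e14 mol C lowers pCO2 by exactly 1 uatm."""
        atm = AtmosphereBox(280.0, mode="prognostic")
        out = atmosphere_step(atm, 1.773e20 * 1e-6, 1.0)
        assert out.pco2_atm == pytest.approx(279.0, rel=1e-12)

    def test_negative_inventory_rejected(self):
        atm = AtmosphereBox(1.0, mode="prognostic")
        with pytest.raises(ValueError):
            atmosphere_step(atm, atm.carbon_inventory * 2.0, 1.0)
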