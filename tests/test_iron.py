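"""Iron speciation, scavenging, external sources and ligand cycling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sixbox.boxes import (M_FE, RHO_SW, SECONDS_PER_DAY, SECONDS_PER_YEAR,
                          Box, default_geometry, default_params, initial_state)
from sixbox.iron import (IronSpeciation, iron_sources, ligand_tendencies,
                         scavenging_tendency, solve_speciation)

BETA = 1.0e9  # (mol m-3)-1


def bisect_free_iron(fe_total_nmol, ligand_total_nmol, beta=BETA,
                     rho=RHO_SW, tol=1e-16):
    """Independent oracle: bracketed bisection on the mass-action residual.

    At equilibrium the complex satisfies beta' * Fe' * L' = FeL with
    Fe' + FeL = FeT and L' + FeL = LT (all mol kg-1, beta' = beta * rho).
    """
    beta_kg = beta * rho
    ft = fe_total_nmol * 1e-9
    lt = ligand_total_nmol * 1e-9

    def residual(fe_free):
        fel = ft - fe_free
        return beta_kg * fe_free * (lt - fel) - fel

    lo, hi = 0.0, ft
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if residual(mid) >= 0.0:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol * max(ft, 1e-30):
            break
    return 0.5 * (lo + hi) * 1e9


class TestSpeciation:
    def test_no_ligand_all_free(self):
        spec = solve_speciation(1.3, 0.0, BETA)
        assert spec.fe_free == pytest.approx(1.3, rel=1e-12)
        assert spec.fe_ligand == pytest.approx(0.0, abs=1e-12)

    def test_no_iron_all_zero(self):
        spec = solve_speciation(0.0, 2.0, BETA)
        assert spec.fe_free == 0.0 and spec.fe_ligand == 0.0
        assert spec.ligand_free == 2.0

    def test_matches_bisection_oracle_example(self):
        spec = solve_speciation(1.0, 2.0, BETA)
        assert spec.fe_free == pytest.approx(bisect_free_iron(1.0, 2.0),
                                             rel=1e-9)

    def test_mass_balance_invariants(self, rng):
        ft = rng.uniform(0, 10, 50)
        lt = rng.uniform(0, 10, 50)
        spec = solve_speciation(ft, lt, BETA)
        np.testing.assert_allclose(spec.fe_free + spec.fe_ligand, ft, rtol=1e-10)
        np.testing.assert_allclose(spec.ligand_free + spec.fe_ligand, lt,
                                   rtol=1e-10, atol=1e-12)
        assert np.all(spec.fe_free >= 0) and np.all(spec.ligand_free >= -1e-15)

    @settings(max_examples=100, deadline=None)
    @given(ft=st.floats(1e-6, 10.0), lt=st.floats(0.0, 10.0))
    def test_equilibrium_residual(self, ft, lt):
        spec = solve_speciation(ft, lt, BETA)
        beta_kg = BETA * RHO_SW
        fel = beta_kg * (spec.fe_free * 1e-9) * (spec.ligand_free * 1e-9) * 1e9
        assert fel == pytest.approx(spec.fe_ligand, rel=1e-8, abs=1e-10)

    def test_extreme_binding_no_cancellation(self):
        # beta*|LT-FeT| >> 1: nearly all iron complexed, free iron tiny but positive
        spec = solve_speciation(1.0, 8.0, 1e12)
        assert 0.0 < spec.fe_free < 1e-6
        assert spec.fe_ligand == pytest.approx(1.0, rel=1e-6)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            solve_speciation(-1.0, 2.0, BETA)
        with pytest.raises(ValueError):
            solve_speciation(1.0, 2.0, -BETA)


class TestScavenging:
    def test_only_free_iron_lost(self):
        spec = solve_speciation(1.0, 0.0, BETA)
        assert scavenging_tendency(spec, 1e-7) == pytest.approx(-1e-7, rel=1e-12)

    def test_fully_protected_limit(self):
        spec = solve_speciation(0.5, 50.0, 1e12)
        assert abs(scavenging_tendency(spec, 1e-7)) < 1e-12

    def test_loss_strictly_decreases_with_ligand(self):
        losses = [abs(scavenging_tendency(solve_speciation(1.0, lt, BETA), 1e-7))
                  for lt in (0.0, 0.5, 1.0, 2.0, 5.0)]
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_solubility_cap_option(self):
        spec = solve_speciation(1.0, 0.0, BETA)
        assert scavenging_tendency(spec, 1e-7, fe_free_cap=2.0) == 0.0


class TestSources:
    def test_hand_unit_conversion_atlantic(self):
        params = default_params("fixed")
        geom = default_geometry()
        src = iron_sources(geom, params)
        # independent dimensional analysis: g m-2 y-1 * fraction * m2
        # / (g mol-1 * y->s * m3 * kg m-3) -> mol kg-1 s-1 -> nmol
        expect = (0.300 * 2.5e-3 * geom[Box.SA].area
                  / (M_FE * SECONDS_PER_YEAR * geom[Box.SA].volume * RHO_SW)) * 1e9
        assert src[Box.SA] == pytest.approx(expect, rel=1e-12)

    def test_zero_solubility_kills_sources(self):
        params = default_params("fixed", {"fe_solubility": 0.0})
        assert np.all(iron_sources(default_geometry(), params) == 0.0)

    def test_deep_boxes_receive_hydrothermal_iron(self):
        src = iron_sources(default_geometry(), default_params("fixed"))
        assert np.all(src > 0.0)

    def test_southern_perturbation_scales_input(self):
        base = iron_sources(default_geometry(), default_params("fixed"))
        up = iron_sources(default_geometry(),
                          default_params("fixed", {"fe_input_scale": {"SS": 20.0}}))
        assert up[Box.SS] == pytest.approx(20.0 * base[Box.SS], rel=1e-12)
        assert up[Box.SA] == pytest.approx(base[Box.SA], rel=1e-12)


class TestLigandTendencies:
    def test_fixed_mode_is_inert(self):
        params = default_params("fixed")
        state = initial_state(params)
        out = ligand_tendencies(state, np.ones(3), np.zeros(6), params)
        np.testing.assert_array_equal(out, 0.0)

    def test_fixed_mode_with_rates_rejected(self):
        params = default_params("fixed").replace(gamma_per_p=0.0053)
        with pytest.raises(ValueError):
            ligand_tendencies(initial_state(params), np.zeros(3), np.zeros(6),
                              params)

    def test_dead_ocean_zero(self):
        params = default_params("dynamic")
        state = initial_state(params)  # ligands start at zero
        out = ligand_tendencies(state, np.zeros(3), np.zeros(6), params)
        np.testing.assert_array_equal(out, 0.0)

    def test_deep_decay_hundred_times_slower(self):
        params = default_params("dynamic")
        state = initial_state(params)
        state.lig[:] = 1.0
        out = ligand_tendencies(state, np.zeros(3), np.zeros(6), params)
        assert out[Box.DA] == pytest.approx(out[Box.SA] / 100.0, rel=1e-12)

    def test_one_box_equilibrium_closed_form(self):
        """Steady ligand in an isolated surface box is gamma*J_P/lambda."""
        params = default_params("dynamic")
        j = 2.0  # umol P m-3 day-1
        j_kg = j / params.rho_sw / SECONDS_PER_DAY      # umol P kg-1 s-1
        lig_eq = params.gamma_per_p * j_kg * 1e3 / params.lambda_surf  # nmol
        state = initial_state(params)
        state.lig[Box.SA] = lig_eq
        out = ligand_tendencies(state, np.array([j, 0.0, 0.0]), np.zeros(6),
                                params)
        assert out[Box.SA] == pytest.approx(0.0, abs=1e-20)


def test_speciation_dataclass_validation():
    bad = IronSpeciation(fe_total=np.array(1.0), ligand_total=np.array(1.0),
                         fe_free=np.array(0.9), fe_ligand=np.array(0.5),
                         ligand_free=np.array(0.5))
    with pytest.raises(AssertionError):
        bad.validate()
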