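"""Air properties, boundary-layer conductance formulas and conversions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafwind.airphysics import (
    F_HEAT_WATER,
    R_GAS,
    AirProperties,
    Species,
    air_properties,
    convert_species,
    gb_combine,
    gb_forced_laminar,
    gb_free_convection,
    molar_density,
)


class TestAirProperties:
    def test_diffusivity_ordering_across_temperatures(self):
        for T in (0, 10, 25, 40, 50):
            p = air_properties(T)
            assert p.Dw > p.Dh > p.Dc > 0
            assert p.v > 0

    def test_thermal_expansion_is_ideal_gas(self):
        for T in (0, 25, 40):
            p = air_properties(T)
            assert p.at == pytest.approx(1.0 / (T + 273.15), rel=1e-12)

    def test_heat_water_factor_reproduced_from_diffusivities(self):
        p = air_properties(25.0)
        assert (p.Dw / p.Dh) ** (2.0 / 3.0) == pytest.approx(F_HEAT_WATER, rel=0.005)

    def test_power_law_temperature_scaling_is_ratio_preserving(self):
        p25, p35 = air_properties(25.0), air_properties(35.0)
        factor = (308.15 / 298.15) ** 1.75
        for attr in ("Dw", "Dh", "Dc", "v"):
            assert getattr(p35, attr) / getattr(p25, attr) == pytest.approx(factor, rel=1e-12)

    def test_pressure_scaling_inverse(self):
        assert air_properties(25, 80.0).Dw == pytest.approx(
            air_properties(25, 101.325).Dw * 101.325 / 80.0, rel=1e-12)

    @pytest.mark.parametrize("T,P", [(-20, 101.325), (70, 101.325), (25, 40), (25, 120)])
    def test_out_of_range_rejected(self, T, P):
        with pytest.raises(ValueError):
            air_properties(T, P)


class TestForcedLaminar:
    @pytest.mark.parametrize("u,expected", [(0.15, 0.196), (1.0, 0.506)])
    def test_reference_anchor_values(self, u, expected):
        # one-sided gbw for an intermediate leaf (L = 0.0825 m) at 25 degC
        g = gb_forced_laminar(u, 0.0825, air_properties(25.0), Species.WATER)
        assert g == pytest.approx(expected, rel=0.005)

    def test_zero_wind_gives_zero(self):
        assert gb_forced_laminar(0.0, 0.3) == 0.0

    def test_scaled_anchor(self):
        # sqrt(u) and 1/sqrt(L) scaling from the 0.196 anchor
        expected = 0.196 * math.sqrt(0.6 / 0.15) * math.sqrt(0.0825 / 0.3)
        g = gb_forced_laminar(0.6, 0.3, air_properties(25.0), Species.WATER)
        assert g == pytest.approx(expected, rel=0.005)

    def test_sqrt_wind_scaling_exact(self):
        g1 = gb_forced_laminar(0.4, 0.1)
        g2 = gb_forced_laminar(0.8, 0.1)
        assert g2 == pytest.approx(g1 * math.sqrt(2.0), rel=1e-12)

    def test_monotone_in_wind_and_leaf_size(self):
        u = np.linspace(0.05, 3.0, 40)
        g = gb_forced_laminar(u, 0.1)
        assert np.all(np.diff(g) > 0)
        gLs = [gb_forced_laminar(0.5, L) for L in np.linspace(0.02, 0.3, 20)]
        assert np.all(np.diff(gLs) < 0)

    def test_molar_conversion_is_ideal_gas_law(self):
        # independent recomputation of the velocity->molar conversion
        props = air_properties(30.0, 95.0)
        g_mol = gb_forced_laminar(0.5, 0.1, props, Species.WATER)
        g_vel_mm_s = 0.664 * props.Dw ** (2 / 3) * 0.5**0.5 / (0.1**0.5 * props.v ** (1 / 6))
        assert g_mol == pytest.approx(
            g_vel_mm_s * 1e-3 * props.P * 1000.0 / (R_GAS * props.T), rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            gb_forced_laminar(0.5, -0.1)
        with pytest.raises(ValueError):
            gb_forced_laminar(-0.5, 0.1)


class TestFreeConvection:
    def test_no_buoyancy_no_conductance(self):
        assert gb_free_convection(0.0, 0.1) == 0.0

    def test_quarter_power_scaling(self):
        g1 = gb_free_convection(0.5, 0.1)
        g16 = gb_free_convection(8.0, 0.1)
        assert g16 == pytest.approx(2.0 * g1, rel=1e-12)

    def test_direct_formula_evaluation(self):
        # independent hand evaluation of the printed flat-plate expression
        props = air_properties(25.0)
        D, v = props.Dh * 1e-6, props.v * 1e-6
        g_vel = 0.54 * D**0.75 * (9.81 * props.at * 5.0) ** 0.25 / (0.1**0.25 * v**0.25)
        expected = g_vel * molar_density(props)
        assert gb_free_convection(5.0, 0.1, props, Species.HEAT) == pytest.approx(
            expected, rel=1e-12)

    def test_invalid_length(self):
        with pytest.raises(ValueError):
            gb_free_convection(5.0, 0.0)


class TestCombine:
    @pytest.mark.parametrize("mode,expected", [
        ("max", 0.2),
        ("parallel_sum", 0.3),
    ])
    def test_modes(self, mode, expected):
        assert gb_combine(0.2, 0.1 if mode != "max" else 0.0, mode) == pytest.approx(
            expected if mode != "max" else 0.2)

    def test_degenerate_free_term_all_modes(self):
        for mode in ("max", "parallel_sum", "smooth"):
            assert gb_combine(0.2, 0.0, mode) == pytest.approx(0.2)

    def test_smooth_closed_form(self):
        assert gb_combine(0.2, 0.2, "smooth", k=3.5) == pytest.approx(
            0.2 * 2 ** (1 / 3.5), rel=1e-12)

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            gb_combine(0.2, 0.1, "geometric")


class TestConvertSpecies:
    @pytest.mark.parametrize("g,frm,to,regime,expected", [
        (0.5, "heat", "water", "boundary", 0.54103),
        (0.392, "water", "co2", "boundary", 0.392 / 1.37),
        (0.4, "water", "co2", "stomatal", 0.25),
    ])
    def test_reference_conversions(self, g, frm, to, regime, expected):
        assert convert_species(g, frm, to, regime) == pytest.approx(expected, rel=1e-5)

    @given(g=st.floats(0, 10, allow_nan=False), frm=st.sampled_from(list(Species)),
           to=st.sampled_from(list(Species)))
    @settings(deadline=None, max_examples=50)
    def test_round_trip_identity(self, g, frm, to):
        back = convert_species(convert_species(g, frm, to, "boundary"), to, frm, "boundary")
        assert back == pytest.approx(g, rel=1e-12, abs=1e-300)

    def test_heat_has_no_stomatal_path(self):
        with pytest.raises(ValueError):
            convert_species(0.5, "heat", "water", "stomatal")
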