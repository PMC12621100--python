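"""Coupled leaf model: FvCB targets, transport, energy balance, solvers."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

import leafwind as lw
from leafwind.airphysics import esat_kpa
from leafwind.leaf_model import (
    Forcing,
    energy_fluxes,
    fvcb_targets,
    gm_mole_fraction,
    integrate_dynamic,
    leuning_gs_target,
    relax,
    solve_steady_state,
    step_dynamic,
    transport,
)
from leafwind.params import StomatalParams, arrhenius


class TestFvcbTargets:
    def test_dark_rate_is_negative_respiration(self, tomato):
        p = tomato.photo
        for T in (15.0, 25.0, 35.0):
            fv = fvcb_targets(0.0, T, 300.0, p)
            assert fv.A_star == pytest.approx(-arrhenius(p.Rd25, p.Ea_Rd, T + 273.15),
                                              rel=1e-9)

    def test_infinite_gm_limit_is_rectangular_form(self, tomato):
        p = tomato.photo
        fv = fvcb_targets(1500.0, 25.0, 270.0, p, gm_infinite=True)
        Km = p.Kc25 * (1 + p.O / p.Ko25)
        expected_ac = p.Vcmax25 * (270 - p.GammaStar25) / (270 + Km) - p.Rd25
        assert fv.Ac == pytest.approx(expected_ac, abs=1e-6)

    def test_quadratic_root_against_bracketing_oracle(self, tomato):
        # oracle: scalar root of A = Vm (Cc - G*)/(Cc + K) - Rd with
        # Cc = Ci - A/gm, solved by brute-force bracketing
        p = tomato.photo
        for T, Ci, ppfd in [(25.0, 270.0, 1500.0), (32.0, 300.0, 800.0),
                            (20.0, 200.0, 400.0)]:
            Tk = T + 273.15
            Vm = arrhenius(p.Vcmax25, p.Ea_Vcmax, Tk)
            Rd = arrhenius(p.Rd25, p.Ea_Rd, Tk)
            Kc = arrhenius(p.Kc25, p.Ea_Kc, Tk)
            Ko = arrhenius(p.Ko25, p.Ea_Ko, Tk)
            Gs = arrhenius(p.GammaStar25, p.Ea_GammaStar, Tk)
            Km = Kc * (1 + p.O / Ko)
            gm = gm_mole_fraction(p, T)

            def f(A):
                Cc = Ci - A / gm
                return Vm * (Cc - Gs) / (Cc + Km) - Rd - A

            oracle_ac = brentq(f, -Rd - 5.0, Vm, xtol=1e-10)
            fv = fvcb_targets(ppfd, T, Ci, p)
            assert fv.Ac == pytest.approx(oracle_ac, abs=1e-6)
            assert fv.A_star == pytest.approx(min(fv.Ac, fv.Aj), rel=1e-12)

    def test_compensation_point_zeroes_net_rate(self, tomato):
        fv = fvcb_targets(1500.0, 25.0, 100.0, tomato.photo)
        at_gamma = fvcb_targets(1500.0, 25.0, fv.Gamma, tomato.photo)
        assert at_gamma.Ac == pytest.approx(0.0, abs=1e-6)

    def test_invalid_inputs(self, tomato):
        with pytest.raises(ValueError):
            fvcb_targets(-1.0, 25.0, 300.0, tomato.photo)
        with pytest.raises(ValueError):
            fvcb_targets(500.0, 25.0, -10.0, tomato.photo)


class TestConductanceSet:
    def test_conventions_and_series_conductance(self):
        from leafwind.leaf_model import conductance_set

        cs = conductance_set(0.196, 0.4, 0.32)
        assert cs.gbw_total == pytest.approx(2 * 0.196)
        assert cs.gbc == pytest.approx(cs.gbw_total / 1.37)
        assert cs.gsc == pytest.approx(0.4 / 1.6)
        assert cs.gbh_total == pytest.approx(cs.gbw_total / 1.08206)
        assert cs.gt_w == pytest.approx(1 / (1 / cs.gbw_total + 1 / 0.4))

    def test_rejects_nonpositive(self):
        from leafwind.leaf_model import conductance_set

        with pytest.raises(ValueError):
            conductance_set(0.0, 0.4, 0.32)


class TestRelax:
    def test_one_time_constant_reaches_63_percent(self):
        assert relax(0.0, 10.0, 300.0, 1.0, 300.0) == pytest.approx(
            10.0 * (1 - math.exp(-1)), rel=1e-12)
        assert relax(0.0, 10.0, 300.0, 1.0, 300.0) == pytest.approx(6.321, abs=5e-4)

    def test_at_target_stays(self):
        assert relax(5.0, 5.0, 300.0, 1.0, 60.0) == 5.0

    def test_fast_decrease_converges(self):
        assert relax(10.0, 0.0, 300.0, 1.0, 10.0) == pytest.approx(0.0, abs=1e-3)

    @given(v=st.floats(-50, 50), t=st.floats(-50, 50),
           dt=st.floats(0.1, 1e4))
    @settings(deadline=None, max_examples=60)
    def test_stays_between_value_and_target(self, v, t, dt):
        out = relax(v, t, 300.0, 450.0, dt)
        lo, hi = min(v, t), max(v, t)
        assert lo - 1e-9 <= out <= hi + 1e-9


class TestLeuning:
    SP = StomatalParams(g0=0.05, g1=11.0, D0=1.5)

    def test_no_assimilation_gives_nocturnal_conductance(self):
        assert leuning_gs_target(0.0, 350.0, 1.0, 45.0, self.SP) == pytest.approx(0.05)

    def test_direct_arithmetic(self):
        expected = 0.05 + 11 * 20 / (305 * 1.8)
        assert leuning_gs_target(20.0, 350.0, 1.2, 45.0, self.SP) == pytest.approx(
            expected, rel=1e-12)
        assert expected == pytest.approx(0.4507, abs=5e-4)

    def test_large_deficit_closes_to_g0(self):
        assert leuning_gs_target(20.0, 350.0, 1e9, 45.0, self.SP) == pytest.approx(
            0.05, abs=1e-6)

    def test_degenerate_surface_co2_pins_and_warns(self):
        with pytest.warns(UserWarning):
            out = leuning_gs_target(20.0, 40.0, 1.0, 45.0, self.SP)
        assert out == 0.05


class TestTransport:
    def test_reference_drawdowns_low_wind(self):
        Cs, Ci, Cc, E, Ds = transport(20.0, 0.4, 0.392, 0.32, 420.0, 25.0, 2.0)
        assert Cs == pytest.approx(350.0, abs=1.0)
        assert Ci == pytest.approx(270.0, abs=1.0)
        assert Cc < Ci < Cs < 420.0

    def test_reference_drawdowns_high_wind(self):
        Cs, Ci, _, _, _ = transport(20.0, 0.4, 1.012, 0.32, 420.0, 25.0, 2.0)
        assert Cs == pytest.approx(393.0, abs=1.0)
        assert Ci == pytest.approx(313.0, abs=1.0)

    def test_infinite_coupling_limit(self):
        Cs, Ci, _, E, Ds = transport(20.0, 0.4, 1e9, 0.32, 420.0, 25.0, 2.0)
        assert Cs == pytest.approx(420.0, abs=1e-5)
        assert Ds == pytest.approx(esat_kpa(25.0) - 2.0, rel=1e-6)

    def test_invalid_conductances(self):
        with pytest.raises(ValueError):
            transport(20.0, 0.0, 0.4, 0.32, 420.0, 25.0, 2.0)


class TestEnergyFluxes:
    def test_thermal_equilibrium_is_flux_free(self, tomato):
        f = Forcing(PPFD=0.0, Tair=25.0, ea=2.0, Ca=420.0)
        *_, net = energy_fluxes(25.0, f, tomato.energy, 0.4, 0.0)
        assert net == pytest.approx(0.0, abs=1e-12)

    def test_net_flux_monotone_decreasing_in_leaf_temperature(self, tomato):
        f = Forcing(PPFD=800.0, Tair=25.0, ea=2.0, Ca=420.0)
        nets = [energy_fluxes(T, f, tomato.energy, 0.4, 0.002)[-1]
                for T in np.linspace(20, 40, 21)]
        assert np.all(np.diff(nets) < 0)

    def test_warm_leaf_convects_heat_away(self, tomato):
        f = Forcing(PPFD=0.0, Tair=25.0, ea=2.0, Ca=420.0)
        Hlw, Hsw, Hconv, Hlat, _ = energy_fluxes(30.0, f, tomato.energy, 0.4, 0.0)
        assert Hconv > 0 and Hlw < 0 and Hsw == 0


class TestSteadyState:
    def test_dark_equilibrium(self, tomato):
        st_ = solve_steady_state(Forcing(PPFD=0.0, Tair=25.0, ea=esat_kpa(25.0),
                                         Ca=420.0), tomato, 1.0)
        Rd = arrhenius(tomato.photo.Rd25, tomato.photo.Ea_Rd, st_.Tleaf + 273.15)
        assert st_.A == pytest.approx(-Rd, rel=1e-3)
        assert st_.gs == pytest.approx(tomato.stomatal.g0, abs=1e-6)
        assert st_.Tleaf == pytest.approx(25.0, abs=0.05)

    def test_fick_consistency_and_energy_closure(self, tomato):
        st_ = solve_steady_state(Forcing(PPFD=1200.0, Tair=30.0, ea=2.0, Ca=420.0),
                                 tomato, 0.2)
        gm = gm_mole_fraction(tomato.photo, st_.Tleaf)
        drawdown = st_.A * (1.37 / 0.4 + 1.6 / st_.gs + 1.0 / gm)
        assert (420.0 - st_.Cc) == pytest.approx(drawdown, rel=1e-6)
        assert abs(st_.net_flux) < 0.1
        assert st_.Cc < st_.Ci < st_.Cs < 420.0

    def test_higher_gb_cools_the_leaf(self, tomato):
        f = Forcing(PPFD=1500.0, Tair=32.0, ea=2.4, Ca=425.0)
        T = [solve_steady_state(f, tomato, gb).Tleaf for gb in (0.1, 0.3, 1.0)]
        # stronger convective/evaporative coupling pulls Tleaf toward (and,
        # with strong transpiration, slightly below) air temperature
        assert T[0] > T[1] > T[2]
        assert T[0] > 32.0

    def test_infinite_gb_pins_surface_state_to_air(self, tomato):
        f = Forcing(PPFD=1000.0, Tair=28.0, ea=2.0, Ca=400.0)
        st_ = solve_steady_state(f, tomato, None)
        assert st_.Tleaf == 28.0
        assert st_.Cs == 400.0
        assert st_.Ds == pytest.approx(esat_kpa(28.0) - 2.0, rel=1e-9)

    def test_wheat_smaller_leaves_assimilate_more(self, wheat):
        # at the same wind, smaller L -> larger gbw -> slightly higher A
        from leafwind.airphysics import Species, air_properties, gb_forced_laminar
        f = Forcing(PPFD=1600.0, Tair=25.0, ea=esat_kpa(25.0) - 1.5, Ca=366.0)
        props = air_properties(25.0)
        A = [solve_steady_state(
                f, wheat, gb_forced_laminar(1.0, L, props, Species.WATER)).A
             for L in (0.015, 0.15)]
        assert A[0] > A[1]


class TestDynamic:
    def test_dark_relaxes_to_air_temperature_and_g0(self, tomato):
        f = pd.DataFrame({"time": [0, 7200], "PPFD": [0.0, 0.0],
                          "Tair": [25.0, 25.0], "ea": [esat_kpa(25.0)] * 2,
                          "Ca": [420.0] * 2})
        out = integrate_dynamic(f, tomato, 1.0, dt=2.0, record_every=7200,
                                initial=(5.0, 0.3, 30.0))
        end = out[out.time == out.time.max()].iloc[0]
        assert end.Tleaf == pytest.approx(25.0, abs=0.05)
        assert end.gs == pytest.approx(tomato.stomatal.g0, abs=1e-3)
        Rd = arrhenius(tomato.photo.Rd25, tomato.photo.Ea_Rd, 273.15 + end.Tleaf)
        assert end.A == pytest.approx(-Rd, rel=1e-2)

    def test_long_run_matches_steady_state(self, tomato):
        # the strongest internal oracle: two independent solvers agree
        f_const = Forcing(PPFD=1000.0, Tair=30.0, ea=2.1, Ca=425.0)
        st_ = solve_steady_state(f_const, tomato, 0.2)
        f = pd.DataFrame({"time": [0, 10800], "PPFD": [1000.0] * 2,
                          "Tair": [30.0] * 2, "ea": [2.1] * 2, "Ca": [425.0] * 2})
        out = integrate_dynamic(f, tomato, 0.2, dt=2.0, record_every=10800)
        end = out[out.time == out.time.max()].iloc[0]
        assert end.A == pytest.approx(st_.A, rel=0.01)
        assert end.gs == pytest.approx(st_.gs, rel=0.01)
        assert end.Tleaf == pytest.approx(st_.Tleaf, abs=0.1)

    def test_light_step_induction_time_constant(self, tomato):
        # after a PPFD step the assimilation state e-folds with tau ~ 300 s
        p = tomato.with_overrides({"stomatal": {"tauG_inc": 1e6}})
        f = pd.DataFrame({"time": [0, 3600], "PPFD": [1200.0] * 2,
                          "Tair": [25.0] * 2, "ea": [2.0] * 2, "Ca": [420.0] * 2})
        out = integrate_dynamic(f, p, 1.0, dt=1.0, record_every=60,
                                initial=(0.0, 0.3, 25.0))
        tr = out.sort_values("time")
        A300 = tr[tr.time == 300].iloc[0].A
        target = tr[tr.time == 300].iloc[0].A_star
        assert A300 / target == pytest.approx(1 - math.exp(-1), abs=0.08)

    def test_step_dynamic_scalar_wrapper(self, tomato):
        state = lw.LeafState(A=0.0, gs=0.05, Tleaf=25.0)
        f = Forcing(PPFD=800.0, Tair=25.0, ea=2.0, Ca=420.0)
        new = step_dynamic(state, f, tomato, 0.3, dt=1.0)
        assert new.A > state.A
        assert np.isfinite(new.net_flux)
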