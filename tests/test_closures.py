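"""Pointwise constitutive laws: closed-form examples and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import poromcts.closures as cl
from poromcts.parameters import CellLineParameters, InvalidParameterError

W_CRIT, W_ENV = 1e-6, 4.2e-6
CT26 = CellLineParameters(gamma_gt=3.33e-2, gamma_0nl=6.65e-4, a=890.0,
                          p1=1432.0, p_crit=5944.0)


class TestSwitchFunctions:
    @pytest.mark.parametrize("omega, expected", [
        (W_ENV, 1.0),
        (W_CRIT / 2, 0.0),
        ((W_CRIT + W_ENV) / 2, 0.5),
        (W_CRIT, 0.0),
        (1.0, 1.0),
    ])
    def test_oxygen_switch_values(self, omega, expected):
        assert cl.growth_switch_H(omega, W_CRIT, W_ENV) == pytest.approx(expected)

    def test_oxygen_switch_rejects_misordered_thresholds(self):
        with pytest.raises(InvalidParameterError):
            cl.growth_switch_H(1e-6, W_ENV, W_CRIT)

    @pytest.mark.parametrize("p, expected", [
        (1432.0, 0.0), (5944.0, 1.0), (3688.0, 0.5), (0.0, 0.0), (1e6, 1.0),
    ])
    def test_pressure_switch_values(self, p, expected):
        assert cl.pressure_switch_Hp(p, 1432.0, 5944.0) == pytest.approx(expected)

    @pytest.mark.parametrize("omega, expected", [
        (0.0, 0.0), (W_ENV, 1.0), (W_ENV / 2, 0.5), (2 * W_ENV, 1.0),
    ])
    def test_metabolism_switch_values(self, omega, expected):
        assert cl.metabolism_switch_Htilde(omega, W_ENV) == pytest.approx(expected)

    def test_metabolism_switch_rejects_negative_oxygen(self):
        with pytest.raises(ValueError):
            cl.metabolism_switch_Htilde(-1e-7, W_ENV)

    @given(st.floats(0, 1e-5))
    @settings(max_examples=200, deadline=None)
    def test_switches_bounded_and_match_piecewise_formulas(self, omega):
        """Dense sampling against direct evaluation of the cosine ramps."""
        H = cl.growth_switch_H(omega, W_CRIT, W_ENV)
        Ht = cl.metabolism_switch_Htilde(omega, W_ENV)
        assert 0.0 <= H <= 1.0 and 0.0 <= Ht <= 1.0
        if omega <= W_CRIT:
            assert H == 0.0
        elif omega >= W_ENV:
            assert H == 1.0
        else:
            x = (omega - W_CRIT) / (W_ENV - W_CRIT)
            assert H == pytest.approx(0.5 - 0.5 * np.cos(np.pi * x))
        if omega < W_ENV:
            assert Ht == pytest.approx(0.5 - 0.5 * np.cos(np.pi * omega / W_ENV))

    def test_switches_monotone_on_grid(self):
        w = np.linspace(0, 1e-5, 2001)
        for f in (lambda x: cl.growth_switch_H(x, W_CRIT, W_ENV),
                  lambda x: cl.metabolism_switch_Htilde(x, W_ENV)):
            assert np.all(np.diff(f(w)) >= -1e-15)
        p = np.linspace(-1e3, 1e4, 2001)
        assert np.all(np.diff(cl.pressure_switch_Hp(p, 1432.0, 5944.0)) >= 0)


class TestSaturation:
    @pytest.mark.parametrize("p_tl, wNt, expected", [
        (0.0, 0.0, 0.0),
        (890.0, 0.0, 0.5),       # arctan(1) at p_tl = a
        (445.0, 0.5, 0.5),       # necrotic offset halves the denominator
        (-100.0, 0.0, 0.0),      # clamped below zero
    ])
    def test_saturation_values(self, p_tl, wNt, expected):
        assert cl.cell_saturation(p_tl, wNt, 890.0) == pytest.approx(expected)

    def test_saturation_guards(self):
        with pytest.raises(ZeroDivisionError):
            cl.cell_saturation(100.0, 1.0, 890.0)
        with pytest.raises(InvalidParameterError):
            cl.cell_saturation(100.0, 0.0, -1.0)

    def test_saturation_strictly_increasing_in_p_and_necrosis(self):
        """Denser necrotic aggregates saturate at lower pressure."""
        p = np.linspace(1.0, 5000.0, 200)
        for wNt in (0.0, 0.3, 0.6, 0.9):
            s = cl.cell_saturation(p, wNt, 890.0)
            assert np.all(np.diff(s) > 0)
        wNt = np.linspace(0.0, 0.95, 100)
        for p_tl in (50.0, 500.0, 2000.0):
            s = cl.cell_saturation(p_tl, wNt, 890.0)
            assert np.all(np.diff(s) > 0)

    def test_inverse_round_trip(self):
        s = np.linspace(0.0, 0.95, 20)
        p = cl.cell_saturation_inverse(s, 0.2, 890.0)
        assert cl.cell_saturation(p, 0.2, 890.0) == pytest.approx(s.tolist())

    def test_liquid_saturation_complement(self):
        assert cl.liquid_saturation(0.0) == 1.0
        assert cl.liquid_saturation(1.0) == 0.0
        assert cl.liquid_saturation(0.6) == pytest.approx(0.4)


class TestTransportClosures:
    def test_oxygen_diffusivity(self):
        assert cl.oxygen_diffusivity(1.0, 1.0, 3.2e-9, 2.0) == pytest.approx(3.2e-9)
        assert cl.oxygen_diffusivity(0.5, 1.0, 4.0, 2.0) == pytest.approx(1.0)
        assert cl.oxygen_diffusivity(0.0, 0.5, 3.2e-9, 2.0) == 0.0
        with pytest.raises(ValueError):
            cl.oxygen_diffusivity(-0.1, 0.5, 3.2e-9, 2.0)

    def test_hydraulic_conductivity(self):
        k, mu = 1e-16, 1e-3
        assert cl.hydraulic_conductivity(k, 1.0, mu, 2.0) == pytest.approx(k / mu)
        assert cl.hydraulic_conductivity(k, 0.0, mu, 2.0) == 0.0
        assert cl.hydraulic_conductivity(k, 0.5, mu, 2.0) == pytest.approx(0.25 * k / mu)
        with pytest.raises(InvalidParameterError):
            cl.hydraulic_conductivity(k, 0.5, 0.0, 2.0)


class TestReactionTerms:
    def test_growth_rate_at_extremes(self):
        # all switches saturated: direct product gamma * eps * S_t
        v = cl.growth_mass_exchange(W_ENV, 0.0, 0.0, 0.8, 0.5, CT26)
        assert v == pytest.approx(3.33e-2 * 0.8 * 0.5)  # 1.332e-2 kg/(m^3 s)
        assert cl.growth_mass_exchange(W_CRIT / 2, 0.0, 0.0, 0.8, 0.5, CT26) == 0.0
        assert cl.growth_mass_exchange(W_ENV, 1e5, 0.0, 0.8, 0.5, CT26) == 0.0

    @given(
        omega=st.floats(0, 1e-5), p=st.floats(0, 1e4),
        wNt=st.floats(0, 0.99), eps=st.floats(0.01, 0.99),
        S_t=st.floats(0, 1),
    )
    @settings(max_examples=500, deadline=None)
    def test_growth_rate_is_product_of_factors(self, omega, p, wNt, eps, S_t):
        """Oracle: direct re-evaluation of the five-factor product."""
        expected = (
            CT26.gamma_gt
            * cl.growth_switch_H(omega, CT26.omega_crit, CT26.omega_env)
            * (1 - cl.pressure_switch_Hp(p, CT26.p1, CT26.p_crit))
            * (1 - wNt) * eps * S_t
        )
        got = cl.growth_mass_exchange(omega, p, wNt, eps, S_t, CT26)
        assert got == pytest.approx(expected, rel=1e-12, abs=1e-300)

    def test_oxygen_sink_cases(self):
        gen = CellLineParameters()  # gamma_gnl=4e-4, gamma_0nl=6e-4
        # growth fully pressure-inhibited: only metabolism consumes
        v = cl.oxygen_sink(W_ENV, 1e5, 0.0, 0.8, 0.5, gen)
        assert v == pytest.approx(gen.gamma_0nl * 0.8 * 0.5)
        assert cl.oxygen_sink(0.0, 0.0, 0.0, 0.8, 0.5, gen) == 0.0
        # both terms active at optimal oxygen and low pressure: eps*S_t=0.4
        ct = CellLineParameters(gamma_gnl=4e-4, gamma_0nl=6.65e-4)
        v = cl.oxygen_sink(W_ENV, 0.0, 0.0, 0.8, 0.5, ct)
        assert v == pytest.approx((4e-4 + 6.65e-4) * 0.4)  # 4.26e-4

    def test_necrosis_rate_cases(self):
        gNt, eps, S_t = 0.01, 0.8, 0.5
        assert cl.necrosis_rate(W_ENV, 0.0, eps, S_t, gNt, W_ENV) == 0.0
        assert cl.necrosis_rate(0.0, 0.0, eps, S_t, gNt, W_ENV) == \
            pytest.approx(gNt * eps * S_t)
        v = cl.necrosis_rate(W_ENV / 2, 0.5, eps, S_t, gNt, W_ENV)
        assert v == pytest.approx(0.25 * gNt * eps * S_t)

    def test_growing_fraction(self):
        assert cl.growing_fraction(W_CRIT, 0.6, CT26) == 0.0
        assert cl.growing_fraction(W_ENV, 0.6, CT26) == pytest.approx(0.6)
        assert cl.growing_fraction(W_ENV / 2, 0.6, CT26) == pytest.approx(0.3)


class TestMechanics:
    def test_solid_pressure_weighted_mean(self):
        assert cl.solid_pressure(1.0, 2000.0, -5.0) == pytest.approx(2000.0)
        assert cl.solid_pressure(0.0, 2000.0, -5.0) == pytest.approx(-5.0)
        assert cl.solid_pressure(0.5, 2000.0, 0.0) == pytest.approx(1000.0)

    def test_effective_stress_voigt(self):
        E, nu = 1000.0, 0.4
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        assert np.allclose(cl.effective_stress(np.zeros((3, 3)), E, nu), 0.0)
        e = 1e-3
        uni = np.diag([e, 0.0, 0.0])
        sig = cl.effective_stress(uni, E, nu)
        assert sig[0, 0] == pytest.approx((lam + 2 * mu) * e)
        assert sig[1, 1] == pytest.approx(lam * e)
        hydro = e * np.eye(3)
        sig = cl.effective_stress(hydro, E, nu)
        assert np.allclose(np.diag(sig), (3 * lam + 2 * mu) * e)
        with pytest.raises(InvalidParameterError):
            cl.effective_stress(uni, E, 0.5)

    def test_porosity_update(self):
        assert cl.update_porosity(0.8, 1.0) == pytest.approx(0.8)
        assert cl.update_porosity(0.8, 1.25) == pytest.approx(0.84)
        assert cl.update_porosity(0.8, 1e9) == pytest.approx(1.0, abs=1e-8)
        with pytest.raises(cl.PorosityCollapseError):
            cl.update_porosity(0.5, 0.4)
        with pytest.raises(ValueError):
            cl.update_porosity(0.5, -1.0)
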