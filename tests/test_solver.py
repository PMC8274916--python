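"""Solver behavior: initialization, limits with closed-form solutions,
conservation and qualitative growth dynamics."""

import numpy as np
import pytest

import poromcts as pm
from poromcts.parameters import ModelParameters, CellLineParameters
from poromcts.solver import ForwardModel, initialize_state, probe_radial


def _no_growth_params(**over):
    """Cell line with all reaction rates off (inert phases)."""
    base = dict(gamma_gt=0.0, gamma_gnl=0.0, gamma_0nl=0.0, gamma_Nt=0.0)
    base.update(over)
    return ModelParameters(cell_line=CellLineParameters(**base))


class TestInitialization:
    def test_initial_profile(self, generic, coarse_disc):
        model, state = initialize_state(
            pm.free_growth_domain(), coarse_disc, generic
        )
        r = model.S.node_coords()
        # oxygen at the boundary value everywhere, IF pressure zero
        assert np.allclose(state.w, 4.2e-6)
        assert np.allclose(state.p_l, 0.0)
        # seed core at the target saturation, exterior cell-free
        S = model.nodal_saturation(state)
        assert S[0] == pytest.approx(0.6, abs=0.01)
        assert np.all(S[r > 60e-6] == 0.0)
        assert np.all(state.u == 0.0)

    def test_seed_pressure_is_inverse_of_saturation_law(self, generic, coarse_disc):
        model, state = initialize_state(
            pm.free_growth_domain(), coarse_disc, generic, S_t0=0.6
        )
        a = generic.cell_line.a
        assert state.p_tl[0] == pytest.approx(a * np.tan(np.pi * 0.3))


class TestDegenerateLimits:
    def test_uniform_equilibrium_is_stationary(self, coarse_disc):
        """No seed, no sources: one step leaves every field unchanged."""
        model, state = initialize_state(
            pm.free_growth_domain(), coarse_disc, _no_growth_params(), S_t0=1e-12
        )
        state.p_tl[:] = 0.0
        new, diag = model.step(state, 2400.0)
        assert np.allclose(new.u, 0.0, atol=1e-12)
        assert np.allclose(new.p_l, 0.0, atol=1e-6)
        assert np.allclose(new.w, 4.2e-6)

    def test_oxygen_relaxes_to_boundary_value(self, coarse_disc):
        """Without sinks, diffusion restores the far-field oxygen level."""
        model, state = initialize_state(
            pm.free_growth_domain(), coarse_disc, _no_growth_params()
        )
        state.w *= 0.5  # disturb
        state.m_w = state.eps_s * (1 - model.storage_saturation(state)) \
            * state.w[model.S.elem_dofs]
        for _ in range(40):
            state, _ = model.step(state, 2400.0)
        assert np.allclose(state.w, 4.2e-6, rtol=1e-3)

    def test_necrosis_only_closed_form(self):
        """At zero oxygen without growth the necrotic fraction obeys
        omega_Nt = 1 - exp(-(gamma_Nt/rho_t) t)."""
        params = _no_growth_params(gamma_Nt=0.01)
        rate = 0.01 / params.phases.rho_t
        disc = pm.Discretization(dh=20e-6, dt=600.0, t_end=86400.0)
        model, state = initialize_state(pm.free_growth_domain(), disc, params)
        # anoxic bath: start at zero oxygen and hold the far-field
        # boundary value at zero (no sinks, so it stays uniform)
        state.w[:] = 0.0
        state.m_w[:] = 0.0
        model.dirichlet_vals[-1] = 0.0
        t = 0.0
        for _ in range(20):
            state, _ = model.step(state, 600.0)
            t += 600.0
        expected = 1.0 - np.exp(-rate * t)
        # implicit Euler at rate*dt = 6e-3: first-order accurate
        assert state.omega_Nt_s.max() == pytest.approx(expected, rel=5e-3)

    def test_no_growth_conserves_tumor_volume(self, coarse_disc):
        model, state = initialize_state(
            pm.free_growth_domain(), coarse_disc, _no_growth_params()
        )
        v0 = model.tumor_volume(state)
        for _ in range(10):
            state, _ = model.step(state, 2400.0)
        assert model.tumor_volume(state) == pytest.approx(v0, rel=1e-3)


class TestGrowthRuns:
    def test_free_growth_monotone_volume(self, free_run_coarse):
        v = free_run_coarse.series["V_tumor_m3"].to_numpy()
        assert free_run_coarse.status == "ok"
        assert np.all(np.diff(v) >= -1e-25)

    def test_mass_budget_per_step(self, free_run_coarse, capsule_run_coarse):
        """Conservation defect below 1e-6 of total mass at every step."""
        for res in (free_run_coarse, capsule_run_coarse):
            assert res.series["mass_budget_cell"].max() < 1e-6
            assert res.series["mass_budget_total"].max() < 1e-6

    def test_oxygen_maximum_principle(self, free_run_coarse):
        """0 <= omega <= omega_env up to solver tolerance everywhere."""
        for snap in free_run_coarse.snapshots:
            w = snap["omega_nl"]
            assert w.max() <= 4.2e-6 * (1 + 1e-6)
            assert w.min() >= -1e-9 * 4.2e-6

    def test_confluence_detected_and_capsule_dilates(self, capsule_run_coarse):
        res = capsule_run_coarse
        assert res.status == "ok"
        assert np.isfinite(res.confluence_time_s)
        s = res.series
        # before confluence the capsule is undeformed, after it dilates
        pre = s[s["time_s"] < res.confluence_time_s - 7200]
        post = s[s["time_s"] > res.confluence_time_s + 24 * 3600]
        assert abs(pre["R_in_m"].iloc[0] - res.R_in0_m) < 1e-9
        assert post["R_in_m"].iloc[-1] > res.R_in0_m + 0.5e-6

    def test_no_cell_infiltration_into_shell(self, capsule_run_coarse):
        """Cell saturation strictly inside the alginate stays < 1e-3."""
        for snap in capsule_run_coarse.snapshots:
            r, St = snap["r_m"], snap["S_t"]
            # shell interior in the current (dilated) configuration
            u_wall = np.interp(capsule_run_coarse.R_in0_m, snap["r_u_m"],
                               snap["u_m"])
            rin_now = capsule_run_coarse.R_in0_m + u_wall
            shell = (r > rin_now + 3e-6) & (r < rin_now + 30e-6)
            if shell.any():
                assert St[shell].max() < 1e-3

    def test_zero_growth_rate_keeps_volume_constant(self):
        params = _no_growth_params(gamma_0nl=6e-4, gamma_Nt=0.01)
        disc = pm.Discretization(dh=20e-6, dt=2400.0, t_end=86400.0)
        res = pm.run_simulation(pm.free_growth_domain(), disc, params)
        v = res.series["V_tumor_m3"]
        assert v.iloc[-1] == pytest.approx(v.iloc[0], rel=1e-3)


class TestProbing:
    def test_probe_initial_fields(self, free_run_coarse):
        r, w = probe_radial(free_run_coarse, 0.0, "omega_nl")
        assert np.allclose(w, 4.2e-6)
        _, u = probe_radial(free_run_coarse, 0.0, "u_s")
        assert np.allclose(u, 0.0)

    def test_probe_interpolates_on_request(self, free_run_coarse):
        radii = np.array([0.0, 33e-6, 150e-6])
        r, vals = probe_radial(free_run_coarse, 86400.0, "S_t", radii=radii)
        assert r.shape == vals.shape == (3,)

    def test_probe_unknown_field_lists_available(self, free_run_coarse):
        with pytest.raises(KeyError, match="available"):
            probe_radial(free_run_coarse, 0.0, "pressure_of_doom")

    def test_probe_time_out_of_range(self, free_run_coarse):
        with pytest.raises(ValueError, match="range"):
            probe_radial(free_run_coarse, 1e9, "S_t")
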