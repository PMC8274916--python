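"""Local Sobol machinery on analytically known cost surfaces."""

import itertools

import numpy as np
import pandas as pd
import pytest

from poromcts.parameters import ModelParameters
from poromcts.sensitivity import (
    PERTURBATION_GRID,
    SEVEN_PARAMETERS,
    CostSpec,
    first_order_design,
    fit_first_order,
    fit_interaction,
    interaction_design,
)


def make_polynomial_cost(theta: dict, theta_pairs: dict | None = None,
                         J0: float = 2.0):
    """Cost whose relative variation is exactly the given polynomial in
    the normalized perturbations alpha_i = frac_i / 10%."""
    base = ModelParameters().cell_line
    theta_pairs = theta_pairs or {}

    def cost(params: ModelParameters) -> float:
        alpha = {
            n: (getattr(params.cell_line, n) / getattr(base, n) - 1.0) / 0.10
            for n in SEVEN_PARAMETERS
        }
        var = sum(t * alpha[n] for n, t in theta.items())
        var += sum(t * alpha[n1] * alpha[n2]
                   for (n1, n2), t in theta_pairs.items())
        return J0 * (1.0 + var)

    return cost


class TestFirstOrder:
    def test_design_shape_and_var_zero_at_baseline(self):
        cost = make_polynomial_cost({"gamma_gt": 1.0})
        design = first_order_design(cost, ModelParameters())
        assert len(design) == 7 * 8  # 7 parameters x 8 grid points
        assert set(design["parameter"]) == set(SEVEN_PARAMETERS)
        assert design["Var"].abs().max() <= 1.0 + 1e-12

    def test_single_active_parameter_gets_index_one(self):
        cost = make_polynomial_cost({"gamma_gt": 0.7})
        res = fit_first_order(first_order_design(cost, ModelParameters()))
        assert res.S1["gamma_gt"] == pytest.approx(1.0)
        assert res.theta["gamma_gt"] == pytest.approx(0.7, rel=1e-12)

    def test_three_four_slope_split(self):
        cost = make_polynomial_cost({"a": 3.0, "gamma_gt": 4.0})
        res = fit_first_order(first_order_design(cost, ModelParameters()))
        assert res.S1["a"] == pytest.approx(0.36)
        assert res.S1["gamma_gt"] == pytest.approx(0.64)

    def test_slopes_recovered_to_machine_precision(self):
        theta = {n: v for n, v in zip(
            SEVEN_PARAMETERS, (0.3, -1.2, 2.5, 0.01, -0.4, 0.0, 5.0))}
        cost = make_polynomial_cost(theta)
        res = fit_first_order(first_order_design(cost, ModelParameters()))
        for n in SEVEN_PARAMETERS:
            assert res.theta[n] == pytest.approx(theta[n], abs=1e-10)

    def test_indices_sum_to_one_and_scale_invariant(self):
        theta = dict(zip(SEVEN_PARAMETERS, (1.0, 0.2, 0.5, 0.0, 0.1, 0.3, 0.7)))
        d1 = first_order_design(make_polynomial_cost(theta, J0=2.0),
                                ModelParameters())
        d2 = first_order_design(make_polynomial_cost(theta, J0=200.0),
                                ModelParameters())
        r1, r2 = fit_first_order(d1), fit_first_order(d2)
        assert sum(r1.S1.values()) == pytest.approx(1.0)
        for n in SEVEN_PARAMETERS:
            assert r1.S1[n] == pytest.approx(r2.S1[n], abs=1e-12)

    def test_all_zero_slopes_raise(self):
        cost = make_polynomial_cost({})
        with pytest.raises(ZeroDivisionError):
            fit_first_order(first_order_design(cost, ModelParameters()))

    def test_failed_runs_excluded_with_warning(self):
        calls = {"n": 0}
        base_cost = make_polynomial_cost({"gamma_gt": 1.0})

        def flaky(params):
            calls["n"] += 1
            if calls["n"] % 13 == 0:
                raise RuntimeError("synthetic failure")
            return base_cost(params)

        with pytest.warns(UserWarning, match="run failed"):
            design = first_order_design(flaky, ModelParameters())
        res = fit_first_order(design)
        assert design["cost"].isna().sum() >= 1
        assert res.S1["gamma_gt"] == pytest.approx(1.0)


class TestInteraction:
    def test_additive_cost_has_zero_pair_indices(self):
        theta = {"gamma_gt": 1.0, "a": 0.5}
        cost = make_polynomial_cost(theta)
        params = ModelParameters()
        d1 = first_order_design(cost, params)
        dp = interaction_design(cost, params, J0=d1.attrs["J0"])
        assert len(dp) == 21 * 2  # all pairs at the two extremes
        res = fit_interaction(d1, dp)
        assert max(abs(v) for v in res.theta_pairs.values()) < 1e-10
        assert all(v < 1e-12 for v in res.S_pairs.values())

    def test_pure_pair_cost_gets_index_one(self):
        cost = make_polynomial_cost({}, {("a", "gamma_gt"): 1.0})
        params = ModelParameters()
        d1 = first_order_design(cost, params)
        dp = interaction_design(cost, params, J0=d1.attrs["J0"])
        res = fit_interaction(d1, dp)
        assert res.S_pairs[("a", "gamma_gt")] == pytest.approx(1.0)

    def test_quadratic_surface_recovered_and_normalized(self):
        theta = dict(zip(SEVEN_PARAMETERS, (0.8, -0.3, 1.5, 0.0, 0.2, 0.05, -0.6)))
        theta_pairs = {("a", "gamma_gt"): 0.9, ("p1", "p_crit"): -0.25}
        cost = make_polynomial_cost(theta, theta_pairs)
        params = ModelParameters()
        d1 = first_order_design(cost, params)
        dp = interaction_design(cost, params, J0=d1.attrs["J0"])
        res = fit_interaction(d1, dp)
        for n, v in theta.items():
            assert res.theta[n] == pytest.approx(v, abs=1e-9)
        for p, v in theta_pairs.items():
            assert res.theta_pairs[p] == pytest.approx(v, abs=1e-9)
        total = sum(res.S1.values()) + sum(res.S_pairs.values())
        assert total == pytest.approx(1.0)


class TestCostSpecs:
    def test_free_spec_requires_points(self):
        with pytest.raises(ValueError):
            CostSpec(kind="free")

    def test_confined_spec_requires_both_observables(self):
        with pytest.raises(ValueError):
            CostSpec(kind="confined", u_Rin_m=1e-6)

    def test_free_cost_values(self, free_run_coarse):
        from poromcts.sensitivity import cost_free

        s = free_run_coarse.series
        t = np.array([43200.0, 86400.0, 129600.0])
        v_model = np.interp(t, s["time_s"], s["V_tumor_m3"])
        exact = CostSpec(kind="free", times_s=t, volumes_m3=v_model)
        assert cost_free(free_run_coarse, exact) == pytest.approx(0.0, abs=1e-30)
        # constant offset: n * delta^2
        delta = 1e-13
        off = CostSpec(kind="free", times_s=t, volumes_m3=v_model + delta)
        assert cost_free(free_run_coarse, off) == pytest.approx(3 * delta ** 2)

    def test_free_cost_rejects_short_simulation(self, free_run_coarse):
        from poromcts.sensitivity import cost_free

        data = CostSpec(kind="free", times_s=np.array([1e9]),
                        volumes_m3=np.array([1e-12]))
        with pytest.raises(ValueError, match="horizon"):
            cost_free(free_run_coarse, data)

    def test_confined_cost_perfect_match_is_zero(self, capsule_run_coarse):
        from poromcts.sensitivity import cost_conf

        res = capsule_run_coarse
        t_eval = res.confluence_time_s + 86400.0
        s = res.series
        u = float(np.interp(t_eval, s["time_s"], s["R_in_m"]) - res.R_in0_m)
        p = float(np.interp(t_eval, s["time_s"], s["p_s_wall_Pa"]))
        data = CostSpec(kind="confined", u_Rin_m=u, P_conf_Pa=p)
        assert cost_conf(res, data) == pytest.approx(0.0, abs=1e-12)
        # pure pressure mismatch enters squared
        data2 = CostSpec(kind="confined", u_Rin_m=u, P_conf_Pa=p + 10.0)
        assert cost_conf(res, data2) == pytest.approx(100.0)

    def test_confined_cost_requires_confluence(self, free_run_coarse):
        from poromcts.sensitivity import cost_conf

        data = CostSpec(kind="confined", u_Rin_m=1e-6, P_conf_Pa=100.0)
        with pytest.raises(ValueError):
            cost_conf(free_run_coarse, data)
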