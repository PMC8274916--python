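"""Analytic and convergence verification of the solver.

The solver kernel, restricted to a single fluid phase without growth on
a Cartesian column under a constant drained surface load, is linear
poroelastic consolidation (Terzaghi's problem) and is compared against
the classical cosine-exponential series solution.  A mesh-refinement
study on the free-growth configuration monitors the oxygen mass
fraction at the spheroid center and quantifies the solution degradation
relative to the finest mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .mesh import Discretization, free_growth_domain
from .parameters import ModelParameters, PhaseProperties, SubdomainMaterial
from .solver import ForwardModel, run_simulation

__all__ = [
    "TerzaghiConfig",
    "rmse",
    "terzaghi_analytic",
    "consolidation_coefficient",
    "run_terzaghi_verification",
    "mesh_convergence_study",
]


@dataclass(frozen=True)
class TerzaghiConfig:
    """Consolidation column: length, load and poroelastic constants."""

    L: float = 100e-6      # column length, m
    p0: float = 1000.0     # applied surface load, Pa
    E: float = 1000.0      # Young modulus, Pa
    nu: float = 0.4
    k: float = 1.0e-16     # intrinsic permeability, m^2
    mu_l: float = 1.0e-3   # fluid viscosity, Pa s
    series_terms: int = 200

    def __post_init__(self) -> None:
        if min(self.L, self.p0, self.E, self.k, self.mu_l) <= 0:
            raise ValueError("all Terzaghi constants must be > 0")
        if self.series_terms < 1:
            raise ValueError("series_terms must be >= 1")


def rmse(xi_num, xi_ex) -> float:
    """Relative root-mean-square error of a numerical vector against a
    reference: sqrt(mean(((ex - num)/ex)^2))."""
    num = np.atleast_1d(np.asarray(xi_num, dtype=float))
    ex = np.atleast_1d(np.asarray(xi_ex, dtype=float))
    if num.shape != ex.shape:
        raise ValueError(f"length mismatch: {num.shape} vs {ex.shape}")
    if np.any(ex == 0.0):
        raise ZeroDivisionError("reference vector contains zero entries")
    return float(np.sqrt(np.mean(((ex - num) / ex) ** 2)))


def consolidation_coefficient(config: TerzaghiConfig) -> float:
    """c_v = k (lambda + 2 mu) / mu_l."""
    mat = SubdomainMaterial(E=config.E, nu=config.nu, k=config.k)
    return config.k * (mat.lame_lambda + 2 * mat.lame_mu) / config.mu_l


def terzaghi_analytic(y, t_bar, config: TerzaghiConfig,
                      tol: float = 1e-12) -> np.ndarray | float:
    """Series solution of the consolidation pore pressure.

    p(y, t_bar) = p0 (4/pi) sum_k (-1)^(k-1)/(2k-1)
                  cos((2k-1) (pi/2) y/L) exp(-(2k-1)^2 (pi^2/4) t_bar)
    with t_bar = c_v t / L^2; the drained boundary is y = L.
    """
    y_arr = np.atleast_1d(np.asarray(y, dtype=float))
    if np.any((y_arr < 0) | (y_arr > config.L)):
        raise ValueError("need 0 <= y <= L")
    if t_bar <= 0:
        raise ValueError("t_bar must be > 0")
    total = np.zeros_like(y_arr)
    converged = False
    for k in range(1, config.series_terms + 1):
        m = 2 * k - 1
        term = ((-1) ** (k - 1) / m
                * np.cos(m * np.pi / 2 * y_arr / config.L)
                * np.exp(-m ** 2 * np.pi ** 2 / 4 * t_bar))
        total += term
        if np.max(np.abs(term)) < tol:
            converged = True
            break
    if not converged and np.exp(-(2 * config.series_terms + 1) ** 2
                                * np.pi ** 2 / 4 * t_bar) > tol:
        raise RuntimeError(
            f"series not converged with {config.series_terms} terms; increase series_terms"
        )
    out = config.p0 * 4.0 / np.pi * total
    return out if np.ndim(y) else float(out[0])


def run_terzaghi_verification(
    config: TerzaghiConfig | None = None,
    dh: float = 5e-6,
    dt_bar: float = 1e-4,
    t_bars: tuple[float, ...] = (0.01, 0.1, 0.5, 1.0),
) -> dict:
    """Run the solver in single-fluid consolidation mode and compare.

    ``dt_bar`` is the time step in units of the consolidation time
    L^2/c_v.  Pore-pressure profiles are compared with the analytic
    series at each requested dimensionless time (interior nodes only;
    the drained boundary value is exactly zero) and the per-time
    relative RMSE values and their sum are returned.
    """
    config = config or TerzaghiConfig()
    c_v = consolidation_coefficient(config)
    t_char = config.L ** 2 / c_v
    dt_phys = dt_bar * t_char
    disc = Discretization(dh=dh, dt=dt_phys, t_end=max(t_bars) * t_char)
    material = SubdomainMaterial(E=config.E, nu=config.nu, k=config.k)
    phases = PhaseProperties(mu_l=config.mu_l)
    model = ForwardModel.consolidation_column(
        config.L, config.p0, material, phases, disc
    )
    state = model.initial_state()

    targets = sorted(t_bars)
    per_time: dict[float, float] = {}
    profiles: list[dict] = []
    y_nodes = model.S.node_coords()
    interior = slice(0, model.n_s - 1)  # exclude the drained boundary node
    t_bar_now = 0.0
    i_target = 0
    n_steps = round(max(t_bars) / dt_bar)
    for n in range(n_steps):
        state, _ = model.step(state, dt_phys)
        t_bar_now = (n + 1) * dt_bar
        if i_target < len(targets) and t_bar_now >= targets[i_target] - dt_bar / 2:
            tb = targets[i_target]
            p_ex = terzaghi_analytic(y_nodes, tb, config)
            per_time[tb] = rmse(state.p_l[interior], p_ex[interior])
            profiles.append({
                "t_bar": tb, "y_m": y_nodes.copy(),
                "p_numeric_Pa": state.p_l.copy(), "p_analytic_Pa": p_ex,
            })
            i_target += 1
    return {
        "per_time_rmse": per_time,
        "sum_rmse": float(sum(per_time.values())),
        "profiles": profiles,
        "c_v": c_v,
        "dt_s": dt_phys,
    }


def mesh_convergence_study(
    dh_list: tuple[float, ...] = (50e-6, 20e-6, 10e-6, 5e-6, 2.5e-6),
    reference_dh: float = 2.5e-6,
    params: ModelParameters | None = None,
    disc: Discretization | None = None,
    n_samples: int = 40,
) -> dict:
    """Free-growth runs at several mesh sizes; center-oxygen RMSE.

    The oxygen mass fraction at the spheroid center is monitored over
    the run horizon and each mesh is scored by the relative RMSE of its
    center-oxygen time series against the finest-mesh reference.
    """
    if reference_dh not in dh_list:
        raise ValueError(f"reference dh {reference_dh} missing from {dh_list}")
    params = params or ModelParameters()
    disc = disc or Discretization(t_end=4 * 86400.0)
    domain = free_growth_domain()
    t_sample = np.linspace(disc.dt, disc.t_end, n_samples)

    series = {}
    for dh in dh_list:
        res = run_simulation(domain, replace(disc, dh=dh), params)
        s = res.series
        series[dh] = np.interp(t_sample, s["time_s"], s["omega_center"])
    ref = series[reference_dh]
    table = {
        dh: (0.0 if dh == reference_dh else rmse(series[dh], ref))
        for dh in dh_list
    }
    return {"rmse": table, "t_sample_s": t_sample, "center_oxygen": series}
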