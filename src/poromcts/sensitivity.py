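"""Cost functions and local response-surface Sobol sensitivity.

The sensitivity procedure is the *local* variant built on one-at-a-time
perturbations: each parameter is disturbed on a fixed percent grid, the
relative cost variation is fitted by a linear (first-order) or
quadratic (pairwise-interaction) polynomial in the normalized
perturbations, and Sobol-type indices are formed from the squared
fitted coefficients.  It quantifies the local variance share of each
parameter around a working point; it is not a global (Saltelli-style)
Sobol estimate, and the class names say so.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .capsule import CapsuleGeometry, confinement_pressure_timeseries, CapsuleTrack
from .mesh import Discretization, DomainSpec
from .parameters import ModelParameters
from .solver import SimulationResult, run_simulation

__all__ = [
    "PERTURBATION_GRID",
    "SEVEN_PARAMETERS",
    "CostSpec",
    "LocalSobolResult",
    "cost_free",
    "cost_conf",
    "make_free_cost",
    "make_confined_cost",
    "first_order_design",
    "fit_first_order",
    "interaction_design",
    "fit_interaction",
]

# one-at-a-time perturbation grid (fractions of the baseline value)
PERTURBATION_GRID = (-0.10, -0.05, -0.02, -0.01, 0.01, 0.02, 0.05, 0.10)

# the seven parameters screened for sensitivity
SEVEN_PARAMETERS = ("mu_t", "a", "gamma_gt", "gamma_gnl", "gamma_0nl", "p1", "p_crit")


@dataclass(frozen=True)
class CostSpec:
    """Experimental data entering one cost function.

    ``kind='free'``: tumor volumes (m^3) at sampling times (s).
    ``kind='confined'``: inner-wall displacement (m) and confinement
    pressure (Pa) one day after confluence.
    """

    kind: str
    times_s: np.ndarray | None = None
    volumes_m3: np.ndarray | None = None
    u_Rin_m: float | None = None
    P_conf_Pa: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "free":
            if self.times_s is None or self.volumes_m3 is None \
                    or len(np.atleast_1d(self.times_s)) < 1:
                raise ValueError("free cost needs at least one volume point")
        elif self.kind == "confined":
            if self.u_Rin_m is None or self.P_conf_Pa is None:
                raise ValueError(
                    "confined cost needs displacement and pressure at matching time"
                )
        else:
            raise ValueError("kind must be 'free' or 'confined'")


def cost_free(sim_result: SimulationResult, data: CostSpec) -> float:
    """Sum of squared tumor-volume mismatches at the data times (m^6)."""
    if data.kind != "free":
        raise ValueError("cost_free requires a free-growth CostSpec")
    s = sim_result.series
    t = np.atleast_1d(np.asarray(data.times_s, dtype=float))
    if t.max() > s["time_s"].iloc[-1] + 1e-6:
        raise ValueError(
            f"simulation horizon {s['time_s'].iloc[-1]:.0f}s shorter than "
            f"data horizon {t.max():.0f}s"
        )
    v_model = np.interp(t, s["time_s"], s["V_tumor_m3"])
    return float(np.sum((np.asarray(data.volumes_m3) - v_model) ** 2))


def cost_conf(sim_result: SimulationResult, data: CostSpec,
              geometry: CapsuleGeometry | None = None,
              displacement_term: str = "abs") -> float:
    """Confined-growth cost one day after confluence.

    Boundary-averaged displacement mismatch (absolute value by default,
    ``displacement_term='squared'`` for the squared dialect) plus the
    squared mismatch between the experimental confinement pressure and
    the model solid pressure at the inner wall.  In the 1-D spherical
    reduction boundary averages are the wall values themselves.
    """
    if data.kind != "confined":
        raise ValueError("cost_conf requires a confined CostSpec")
    if not sim_result.encapsulated:
        raise ValueError("cost_conf requires an encapsulated simulation")
    tc = sim_result.confluence_time_s
    if not np.isfinite(tc):
        raise ValueError("confluence not reached in simulation")
    t_eval = tc + 86400.0
    s = sim_result.series
    if s["time_s"].iloc[-1] + 1e-6 < t_eval:
        raise ValueError("simulation does not extend one day past confluence")
    R_in0 = sim_result.R_in0_m
    u_model = np.interp(t_eval, s["time_s"], s["R_in_m"]) - R_in0
    p_s_model = np.interp(t_eval, s["time_s"], s["p_s_wall_Pa"])
    du = data.u_Rin_m - u_model
    term_u = abs(du) if displacement_term == "abs" else du ** 2
    return float(term_u + (data.P_conf_Pa - p_s_model) ** 2)


# ---------------------------------------------------------------------------
# cost factories wrapping forward simulations


def make_free_cost(domain: DomainSpec, disc: Discretization, data: CostSpec,
                   model_kw: dict | None = None):
    """Return cost(params) running a free-growth simulation."""

    def cost(params: ModelParameters) -> float:
        res = run_simulation(domain, disc, params, model_kw=model_kw)
        if res.status != "ok":
            raise RuntimeError(f"forward run failed: {res.status}")
        return cost_free(res, data)

    return cost


def make_confined_series_cost(domain: DomainSpec, disc: Discretization,
                              dt_after_confluence_s: np.ndarray,
                              R_out_m: np.ndarray,
                              model_kw: dict | None = None):
    """Return cost(params) matching the capsule outer-radius trajectory.

    Sum of squared mismatches (in um^2) of R_out at the given times
    after confluence.  Unlike the single-time confined cost, the
    trajectory constrains the shape of the pressure-inhibition ramp and
    identifies p1 and p_crit jointly; the single-time cost leaves them
    on a near-flat valley because wall displacement and solid pressure
    are tied through the shell elasticity.
    """
    dt_after = np.asarray(dt_after_confluence_s, dtype=float)
    R_exp = np.asarray(R_out_m, dtype=float)

    def cost(params: ModelParameters) -> float:
        res = run_simulation(
            domain, disc, params,
            t_end_after_confluence=dt_after.max() + 0.1 * 86400.0,
            model_kw=model_kw,
        )
        if res.status != "ok" or not np.isfinite(res.confluence_time_s):
            raise RuntimeError(f"forward run failed: {res.status}")
        s = res.series
        R_model = np.interp(res.confluence_time_s + dt_after,
                            s["time_s"], s["R_out_m"])
        return float(np.sum(((R_exp - R_model) / 1e-6) ** 2))

    return cost


def make_confined_cost(domain: DomainSpec, disc: Discretization, data: CostSpec,
                       model_kw: dict | None = None,
                       displacement_term: str = "abs"):
    """Return cost(params) running an encapsulated simulation."""

    def cost(params: ModelParameters) -> float:
        res = run_simulation(
            domain, disc, params,
            t_end_after_confluence=1.5 * 86400.0,
            model_kw=model_kw,
        )
        if res.status != "ok":
            raise RuntimeError(f"forward run failed: {res.status}")
        return cost_conf(res, data, displacement_term=displacement_term)

    return cost


# ---------------------------------------------------------------------------
# perturbation designs


@dataclass
class LocalSobolResult:
    """Fitted local response surface and its Sobol-type indices."""

    names: tuple[str, ...]
    J0: float
    design: pd.DataFrame
    theta: dict[str, float]
    theta_pairs: dict[tuple[str, str], float] = field(default_factory=dict)
    S1: dict[str, float] = field(default_factory=dict)
    S_pairs: dict[tuple[str, str], float] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "J0": self.J0,
            "theta": self.theta,
            "theta_pairs": {f"{a}:{b}": v for (a, b), v in self.theta_pairs.items()},
            "S1": self.S1,
            "S_pairs": {f"{a}:{b}": v for (a, b), v in self.S_pairs.items()},
        }


def _perturbed(params: ModelParameters, updates: dict[str, float]) -> ModelParameters:
    base = {n: getattr(params.cell_line, n) for n in updates}
    return params.with_updates(**{
        n: base[n] * (1.0 + frac) for n, frac in updates.items()
    })


def first_order_design(cost_fn, params: ModelParameters,
                       names: tuple[str, ...] = SEVEN_PARAMETERS,
                       grid: tuple[float, ...] = PERTURBATION_GRID,
                       J0: float | None = None) -> pd.DataFrame:
    """One-at-a-time perturbed runs: |names| x |grid| cost evaluations.

    Returns a table (parameter, frac, alpha, cost, Var) with the
    relative cost variation Var = (J - J0)/J0; failed runs are recorded
    with NaN cost and excluded from fits, with a warning.
    """
    if J0 is None:
        J0 = cost_fn(params)
    if J0 <= 0:
        raise ValueError("baseline cost must be positive to form relative variations")
    alpha_scale = max(abs(g) for g in grid)
    rows = []
    for name in names:
        for frac in grid:
            try:
                J = cost_fn(_perturbed(params, {name: frac}))
            except Exception as err:  # noqa: BLE001 - design must survive run failures
                warnings.warn(f"run failed for {name} {frac:+.0%}: {err}")
                J = float("nan")
            rows.append({
                "parameter": name, "frac": frac, "alpha": frac / alpha_scale,
                "cost": J, "Var": (J - J0) / J0,
            })
    df = pd.DataFrame(rows)
    df.attrs["J0"] = J0
    return df


def fit_first_order(design: pd.DataFrame,
                    J0: float | None = None) -> LocalSobolResult:
    """Per-parameter linear fit Var = theta_i alpha_i; S_i = theta_i^2/sum."""
    J0 = J0 if J0 is not None else design.attrs.get("J0", float("nan"))
    names = tuple(dict.fromkeys(design["parameter"]))
    theta = {}
    for name in names:
        sub = design[(design["parameter"] == name) & design["cost"].notna()]
        if len(sub) < 2:
            raise ValueError(f"fewer than 2 valid grid points for {name}")
        a = sub["alpha"].to_numpy()
        v = sub["Var"].to_numpy()
        theta[name] = float(a @ v / (a @ a))
    denom = sum(t ** 2 for t in theta.values())
    if denom == 0:
        raise ZeroDivisionError(
            "all slopes vanish: first-order indices are undefined"
        )
    S1 = {n: t ** 2 / denom for n, t in theta.items()}
    return LocalSobolResult(names=names, J0=J0, design=design, theta=theta, S1=S1)


def interaction_design(cost_fn, params: ModelParameters,
                       names: tuple[str, ...] = SEVEN_PARAMETERS,
                       extremes: tuple[float, float] = (-0.10, 0.10),
                       J0: float | None = None) -> pd.DataFrame:
    """Pairwise runs at the grid extremes for all parameter tuples.

    Each of the |names| choose 2 pairs is evaluated at the two
    same-sign extreme combinations, which identifies the quadratic
    cross term on top of the first-order slopes.
    """
    if J0 is None:
        J0 = cost_fn(params)
    alpha_scale = max(abs(e) for e in extremes)
    rows = []
    for n1, n2 in itertools.combinations(names, 2):
        for frac in extremes:
            try:
                J = cost_fn(_perturbed(params, {n1: frac, n2: frac}))
            except Exception as err:  # noqa: BLE001
                warnings.warn(f"run failed for ({n1},{n2}) {frac:+.0%}: {err}")
                J = float("nan")
            rows.append({
                "parameter": f"{n1}:{n2}", "p1": n1, "p2": n2,
                "frac": frac, "alpha": frac / alpha_scale,
                "cost": J, "Var": (J - J0) / J0,
            })
    df = pd.DataFrame(rows)
    df.attrs["J0"] = J0
    return df


def fit_interaction(first_order: pd.DataFrame, pairs: pd.DataFrame,
                    J0: float | None = None) -> LocalSobolResult:
    """Joint least squares of the quadratic response surface.

    Var = sum_i theta_i alpha_i + sum_{i<j} theta_ij alpha_i alpha_j is
    fitted to the one-at-a-time and pairwise runs together; indices use
    the combined normalization S_i = theta_i^2 / (sum theta^2 + sum
    theta_pair^2), so all first-order and pair indices sum to one.
    """
    J0 = J0 if J0 is not None else first_order.attrs.get("J0", float("nan"))
    names = tuple(dict.fromkeys(first_order["parameter"]))
    pair_names = list(itertools.combinations(names, 2))
    n1, n2 = len(names), len(pair_names)
    rows_A, rows_b = [], []
    for _, r in first_order[first_order["cost"].notna()].iterrows():
        row = np.zeros(n1 + n2)
        row[names.index(r["parameter"])] = r["alpha"]
        rows_A.append(row)
        rows_b.append(r["Var"])
    for _, r in pairs[pairs["cost"].notna()].iterrows():
        row = np.zeros(n1 + n2)
        row[names.index(r["p1"])] = r["alpha"]
        row[names.index(r["p2"])] = r["alpha"]
        row[n1 + pair_names.index((r["p1"], r["p2"]))] = r["alpha"] ** 2
        rows_A.append(row)
        rows_b.append(r["Var"])
    A = np.array(rows_A)
    b = np.array(rows_b)
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    theta = {n: float(coef[i]) for i, n in enumerate(names)}
    theta_pairs = {p: float(coef[n1 + i]) for i, p in enumerate(pair_names)}
    denom = sum(t ** 2 for t in theta.values()) \
        + sum(t ** 2 for t in theta_pairs.values())
    if denom == 0:
        raise ZeroDivisionError("all coefficients vanish: indices undefined")
    return LocalSobolResult(
        names=names, J0=J0, design=pd.concat([first_order, pairs]),
        theta=theta, theta_pairs=theta_pairs,
        S1={n: t ** 2 / denom for n, t in theta.items()},
        S_pairs={p: t ** 2 / denom for p, t in theta_pairs.items()},
    )
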