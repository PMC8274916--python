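"""Bounded Nelder-Mead calibration and the two-stage identification.

Parameters are identified with the derivative-free Nelder-Mead simplex
(scipy's bounded implementation) from multiple starts spread around the
initial guess, since the simplex converges to local minima.  The
staged protocol mirrors the two experimental configurations: growth
kinetics (gamma_gt, gamma_0nl, a) are identified on free-growth volume
data first, then frozen while the pressure-inhibition thresholds
(p1, p_crit) are identified on encapsulated data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .parameters import InvalidParameterError, ModelParameters

__all__ = ["CalibrationResult", "calibrate", "staged_identification"]

STAGE1_PARAMETERS = ("gamma_gt", "gamma_0nl", "a")
STAGE2_PARAMETERS = ("p1", "p_crit")


@dataclass
class CalibrationResult:
    """Best simplex outcome over all starts."""

    parameters: dict[str, float]
    cost: float
    n_evaluations: int
    at_bounds: dict[str, bool] = field(default_factory=dict)
    start_costs: list[float] = field(default_factory=list)
    log: list[dict] = field(default_factory=list)


def calibrate(
    cost_fn,
    x0: dict[str, float],
    bounds: dict[str, tuple[float, float]],
    base_params: ModelParameters | None = None,
    start_offsets: tuple[float, ...] = (0.0, -0.2, 0.2),
    maxiter: int = 200,
    xatol: float = 1e-3,
    fatol: float = 1e-4,
    n_restarts: int = 0,
) -> CalibrationResult:
    """Minimize cost over a parameter subset with bounded Nelder-Mead.

    ``cost_fn`` maps a ModelParameters to a scalar; ``x0`` holds the
    initial values of the free cell-line parameters; ``bounds`` their
    admissible intervals.  Each entry of ``start_offsets`` launches one
    simplex from x0 scaled by (1 + offset); the best converged start
    wins.  Optimization runs on the x/x0 scale so all parameters are
    O(1); ``fatol`` is relative to the starting cost.

    ``n_restarts`` optionally relaunches the simplex from its own best
    point with a fresh (re-inflated) simplex.  Restarting helps when the
    simplex degenerates on a well-resolved valley, but on cost surfaces
    whose valley floor sits at the forward solver's noise level it makes
    the iteration wander; it is off by default.
    """
    base_params = base_params or ModelParameters()
    names = tuple(x0)
    ref = np.array([x0[n] for n in names])
    lo = np.array([bounds[n][0] for n in names]) / ref
    hi = np.array([bounds[n][1] for n in names]) / ref
    n_eval = 0
    log: list[dict] = []

    def wrapped(z: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        vals = dict(zip(names, z * ref))
        try:
            params = base_params.with_updates(**vals)
            c = cost_fn(params)
        except (InvalidParameterError, RuntimeError, ValueError) as err:
            log.append({"eval": n_eval, "params": vals, "cost": None,
                        "error": str(err)})
            return 1e30
        log.append({"eval": n_eval, "params": vals, "cost": c})
        return c

    c_start = wrapped(np.clip(np.ones(len(names)), lo, hi))
    best = None
    start_costs = []
    errors = []
    opts = {"maxiter": maxiter, "xatol": xatol,
            "fatol": fatol * max(c_start, 1e-300), "adaptive": True}
    for off in start_offsets:
        z0 = np.clip((1.0 + off) * np.ones(len(names)), lo, hi)
        try:
            res = minimize(wrapped, z0, method="Nelder-Mead",
                           bounds=list(zip(lo, hi)), options=opts)
            for _ in range(n_restarts):
                prev = res.fun
                res = minimize(wrapped, res.x, method="Nelder-Mead",
                               bounds=list(zip(lo, hi)), options=opts)
                if res.fun >= prev * (1.0 - 1e-6):
                    break
        except Exception as err:  # noqa: BLE001 - keep other starts alive
            errors.append(str(err))
            continue
        start_costs.append(float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(
            "all calibration starts failed: " + "; ".join(errors)
        )
    z = np.clip(best.x, lo, hi)
    at_bounds = {
        n: bool(np.isclose(z[i], lo[i]) or np.isclose(z[i], hi[i]))
        for i, n in enumerate(names)
    }
    if any(at_bounds.values()):
        warnings.warn(f"calibrated parameters on a bound: {at_bounds}")
    return CalibrationResult(
        parameters=dict(zip(names, z * ref)),
        cost=float(best.fun),
        n_evaluations=n_eval,
        at_bounds=at_bounds,
        start_costs=start_costs,
        log=log,
    )


def staged_identification(
    free_cost,
    confined_cost,
    start: ModelParameters | None = None,
    bounds1: dict[str, tuple[float, float]] | None = None,
    bounds2: dict[str, tuple[float, float]] | None = None,
    **calibrate_kw,
) -> tuple[ModelParameters, dict]:
    """Two-stage identification of the five governing parameters.

    Stage 1 fits (gamma_gt, gamma_0nl, a) on the free-growth cost;
    stage 2 freezes them and fits (p1, p_crit) on the confined cost.
    A stage-1 failure aborts stage 2.  Returns the identified parameter
    set and a report with both stage results.
    """
    start = start or ModelParameters()
    cl = start.cell_line
    x0_1 = {n: getattr(cl, n) for n in STAGE1_PARAMETERS}
    bounds1 = bounds1 or {n: (0.5 * v, 2.0 * v) for n, v in x0_1.items()}
    stage1 = calibrate(free_cost, x0_1, bounds1, base_params=start,
                       **calibrate_kw)
    params1 = start.with_updates(**stage1.parameters)

    x0_2 = {n: getattr(cl, n) for n in STAGE2_PARAMETERS}
    bounds2 = bounds2 or {n: (0.5 * v, 3.0 * v) for n, v in x0_2.items()}

    def conf_cost_guarded(params: ModelParameters) -> float:
        if params.cell_line.p1 >= params.cell_line.p_crit:
            raise InvalidParameterError("p1 >= p_crit candidate rejected")
        return confined_cost(params)

    stage2 = calibrate(conf_cost_guarded, x0_2, bounds2, base_params=params1,
                       **calibrate_kw)
    final = params1.with_updates(**stage2.parameters)
    return final, {"stage1": stage1, "stage2": stage2}
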