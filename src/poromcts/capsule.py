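"""Capsule "dynamometer" inverse analysis.

An elastic, incompressible alginate shell dilated by the growing
spheroid works as a pressure sensor: the thick-walled-vessel solution
converts the measured inner-wall displacement into the confinement
pressure, and shell volume conservation lets the pressure be written as
a function of the inner radius alone.  A further correction using the
ECM bulk modulus estimates the Biot solid pressure from the
confinement pressure.  These formulas are applied both to experimental
radius tracks and to the model's own inner-wall trajectory to compare
the inverse-analysis pressure with the model's phase pressures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .solver import SimulationResult

__all__ = [
    "CapsuleGeometry",
    "CapsuleTrack",
    "confinement_pressure_from_u",
    "confinement_pressure_timeseries",
    "solid_pressure_estimate",
    "compare_pressures",
    "NoCapsuleError",
]


class NoCapsuleError(ValueError):
    """Operation requires an encapsulated (confined) simulation."""


@dataclass(frozen=True)
class CapsuleGeometry:
    """Initial capsule radii and alginate stiffness (SI units)."""

    R_in0: float
    R_out0: float
    E_alg: float = 68e3

    def __post_init__(self) -> None:
        if not (self.R_out0 > self.R_in0 > 0):
            raise ValueError(
                f"need R_out0 > R_in0 > 0, got {self.R_in0}, {self.R_out0}"
            )
        if self.E_alg <= 0:
            raise ValueError("E_alg must be > 0")

    @property
    def shell_volume_const(self) -> float:
        """delta(R0^3) = R_out0^3 - R_in0^3 (incompressible shell)."""
        return self.R_out0 ** 3 - self.R_in0 ** 3


@dataclass
class CapsuleTrack:
    """Time series of the capsule inner radius (and optionally outer)."""

    time_s: np.ndarray
    R_in_m: np.ndarray
    R_out_m: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.R_in_m = np.asarray(self.R_in_m, dtype=float)
        if np.any(self.R_in_m <= 0):
            raise ValueError("radii must be positive")
        if self.R_out_m is not None:
            self.R_out_m = np.asarray(self.R_out_m, dtype=float)

    def check_volume_conservation(self, rtol: float = 1e-2) -> bool:
        """Warn if the tracked shell volume drifts (inconsistent input)."""
        if self.R_out_m is None:
            return True
        dv = self.R_out_m ** 3 - self.R_in_m ** 3
        ok = np.allclose(dv, dv[0], rtol=rtol, atol=0.0)
        if not ok:
            warnings.warn("shell volume R_out^3 - R_in^3 is not conserved in track")
        return ok


def confinement_pressure_from_u(u, geometry: CapsuleGeometry):
    """Confinement pressure from inner-wall displacement (small strain).

    P = (4/3) E u/R_in (1 - (R_in/R_out)^3): inversion of the
    thick-walled incompressible-shell displacement formula.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        warnings.warn("negative wall displacement: shell drawn inward")
    ratio = (geometry.R_in0 / geometry.R_out0) ** 3
    out = (4.0 / 3.0) * geometry.E_alg * (1.0 - ratio) * u / geometry.R_in0
    return out if out.ndim else float(out)


def confinement_pressure_timeseries(track: CapsuleTrack,
                                    geometry: CapsuleGeometry):
    """Confinement pressure from the R_in(t) track alone.

    Uses shell volume conservation to eliminate R_out(t):
    P(t) = (4/3) E [1 - 1/(1 + delta(R0^3)/R_in^3)] u(R_in)/R_in.
    """
    R_in = track.R_in_m
    if np.any(np.diff(R_in) < -1e-9 * geometry.R_in0):
        warnings.warn("shrinking capsule track: non-physical for a growing MCTS")
    track.check_volume_conservation()
    u = R_in - geometry.R_in0
    d3 = geometry.shell_volume_const
    factor = 1.0 - 1.0 / (1.0 + d3 / R_in ** 3)
    return (4.0 / 3.0) * geometry.E_alg * factor * u / R_in


def solid_pressure_estimate(P_conf, u, R_in, K_T: float):
    """Solid pressure from the confinement pressure and ECM bulk modulus:
    p_s = P_conf + 3 K_T u / R_in."""
    if K_T < 0:
        raise ValueError("K_T must be >= 0")
    out = np.asarray(P_conf, dtype=float) + 3.0 * K_T * np.asarray(u, dtype=float) \
        / np.asarray(R_in, dtype=float)
    return out if out.ndim else float(out)


def compare_pressures(sim_result: SimulationResult,
                      geometry: CapsuleGeometry | None = None,
                      K_T: float = 1666.7) -> pd.DataFrame:
    """Tabulate inverse-analysis pressures against model wall pressures.

    Applies the shell formulas to the simulation's own R_in(t) and lists
    them beside the model's inner-wall solid, cell and radial-stress
    values.  ``K_T`` defaults to the bulk modulus of a 1 kPa / nu=0.4
    ECM scaffold.
    """
    if not sim_result.encapsulated:
        raise NoCapsuleError("free-growth result has no capsule to invert")
    s = sim_result.series
    if geometry is None:
        geometry = CapsuleGeometry(sim_result.R_in0_m, sim_result.R_out0_m)
    track = CapsuleTrack(s["time_s"].to_numpy(), s["R_in_m"].to_numpy(),
                         s["R_out_m"].to_numpy())
    P_conf = confinement_pressure_timeseries(track, geometry)
    u = track.R_in_m - geometry.R_in0
    p_s_est = solid_pressure_estimate(P_conf, u, track.R_in_m, K_T)
    return pd.DataFrame({
        "time_s": s["time_s"],
        "u_Rin_m": u,
        "strain": u / geometry.R_in0,
        "P_conf_inverse_Pa": P_conf,
        "p_s_estimate_Pa": p_s_est,
        "p_s_model_Pa": s["p_s_wall_Pa"],
        "p_t_model_Pa": s["p_t_wall_Pa"],
        "sigma_rr_model_Pa": s["sigma_rr_wall_Pa"],
    })
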