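"""Experimental time series: CSV I/O and the synthetic generator.

Real capsule experiments provide two kinds of training curves: the
volume of a freely growing spheroid over days, and the radius (or
radial strain) of a deformed capsule after confluence.  This module
reads such series from CSV (units normalized to SI on read), and can
generate surrogate series with the same structure by running the
forward model at known parameters and adding multiplicative Gaussian
noise -- the basis of all parameter-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mesh import Discretization, DomainSpec, capsule_domain, free_growth_domain
from .parameters import ModelParameters
from .solver import run_simulation

__all__ = [
    "ExperimentSeries",
    "SyntheticSpec",
    "read_experiment_csv",
    "write_experiment_csv",
    "generate_synthetic_experiment",
]

KINDS = ("free-volume", "capsule-radius")

# recognized value columns and their SI conversion factors
_VALUE_COLUMNS = {
    "volume_m3": ("free-volume", 1.0),
    "volume_mm3": ("free-volume", 1e-9),
    "R_out_m": ("capsule-radius", 1.0),
    "R_out_um": ("capsule-radius", 1e-6),
    "R_in_m": ("capsule-radius", 1.0),
    "R_in_um": ("capsule-radius", 1e-6),
}
_TIME_COLUMNS = {"time_s": 1.0, "time_day": 86400.0, "time_h": 3600.0}


class ExperimentCSVError(ValueError):
    """Malformed experiment CSV."""


@dataclass
class ExperimentSeries:
    """One measured (or surrogate) time series in SI units."""

    kind: str
    time_s: np.ndarray
    values: np.ndarray  # m^3 for free-volume, m for capsule-radius
    value_column: str = "volume_m3"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.time_s) <= 0):
            raise ExperimentCSVError("times must be strictly increasing")
        if np.any(self.values <= 0):
            raise ExperimentCSVError("values must be positive")


def read_experiment_csv(path: str | Path) -> ExperimentSeries:
    """Read a declared-header CSV into an SI-normalized series.

    The header must contain one time column (time_s | time_h | time_day)
    and one value column (volume_m3 | volume_mm3 | R_in_m | R_in_um |
    R_out_m | R_out_um).  Extra columns are kept as metadata.
    """
    df = pd.read_csv(path)
    t_cols = [c for c in df.columns if c in _TIME_COLUMNS]
    v_cols = [c for c in df.columns if c in _VALUE_COLUMNS]
    if len(t_cols) != 1 or len(v_cols) != 1:
        raise ExperimentCSVError(
            f"{path}: need exactly one time column {sorted(_TIME_COLUMNS)} and "
            f"one value column {sorted(_VALUE_COLUMNS)}; got {list(df.columns)}"
        )
    t = df[t_cols[0]].to_numpy(dtype=float) * _TIME_COLUMNS[t_cols[0]]
    bad = np.flatnonzero(np.diff(t) <= 0)
    if len(bad):
        raise ExperimentCSVError(
            f"{path}: non-monotone time at data line {bad[0] + 2}"
        )
    kind, factor = _VALUE_COLUMNS[v_cols[0]]
    meta = {c: df[c].iloc[0] for c in df.columns if c not in (t_cols[0], v_cols[0])}
    return ExperimentSeries(
        kind=kind, time_s=t, values=df[v_cols[0]].to_numpy(dtype=float) * factor,
        value_column=v_cols[0], metadata=meta,
    )


def write_experiment_csv(series: ExperimentSeries, path: str | Path) -> None:
    """Write a series back to CSV in SI units (time_s + SI value column)."""
    col = {"free-volume": "volume_m3", "capsule-radius": "R_out_m"}[series.kind] \
        if series.value_column not in _VALUE_COLUMNS else series.value_column
    factor = _VALUE_COLUMNS[col][1]
    pd.DataFrame({"time_s": series.time_s, col: series.values / factor}) \
        .to_csv(path, index=False)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a surrogate experimental curve.

    The forward model is run at ``params`` on ``domain`` and the
    relevant observable sampled at ``times_s``; multiplicative Gaussian
    noise of relative standard deviation ``noise`` is added with the
    given ``seed`` (bit-for-bit reproducible).
    """

    kind: str
    params: ModelParameters
    domain: DomainSpec | None = None
    disc: Discretization | None = None
    times_s: tuple[float, ...] = tuple(float(d) * 86400 for d in range(1, 5))
    noise: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")


def generate_synthetic_experiment(spec: SyntheticSpec) -> ExperimentSeries:
    """Run the forward model and sample a noisy surrogate series."""
    if spec.kind == "free-volume":
        domain = spec.domain or free_growth_domain()
        disc = spec.disc or Discretization(t_end=max(spec.times_s))
        res = run_simulation(domain, disc, spec.params)
        col, name = "V_tumor_m3", "volume_m3"
    else:
        domain = spec.domain or capsule_domain()
        disc = spec.disc or Discretization(t_end=max(spec.times_s))
        res = run_simulation(domain, disc, spec.params)
        col, name = "R_out_m", "R_out_m"
    if res.status != "ok":
        raise RuntimeError(f"forward model failed: {res.status}")
    s = res.series
    t = np.asarray(spec.times_s, dtype=float)
    clean = np.interp(t, s["time_s"], s[col])
    rng = np.random.default_rng(spec.seed)
    noisy = clean * (1.0 + spec.noise * rng.standard_normal(len(t)))
    meta = {"noise": spec.noise, "seed": spec.seed,
            "confluence_time_s": res.confluence_time_s}
    if spec.kind == "capsule-radius":
        meta.update(R_in0_m=domain.R_in, h_m=domain.h,
                    E_alg_Pa=domain.materials["alginate"].E)
    return ExperimentSeries(kind=spec.kind, time_s=t, values=noisy,
                            value_column=name, metadata=meta)
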