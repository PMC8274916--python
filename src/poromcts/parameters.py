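"""Parameter containers for the multiphase spheroid model.

The tumor tissue is treated as a porous multiphase continuum: an
extracellular-matrix solid scaffold saturated by two immiscible fluid
phases, the tumor-cell phase (t) and the interstitial fluid (l), with
oxygen dissolved in the interstitial fluid as the single limiting
nutrient.  Three groups of constants parameterize the closure laws:

* :class:`CellLineParameters` -- growth, oxygen-consumption and necrosis
  kinetics plus the pressure-inhibition thresholds; cell-line specific.
* :class:`PhaseProperties` -- densities, viscosities and transport
  exponents shared by all subdomains.
* :class:`SubdomainMaterial` -- elasticity, intrinsic permeability and
  reference porosity of one spatial subdomain (spheroid interior,
  alginate shell, exterior medium).

Two presets are shipped: ``"generic"`` (literature initial guesses) and
``"CT26-optimized"`` (values identified for the CT26 mouse colon
carcinoma line).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "CellLineParameters",
    "PhaseProperties",
    "SubdomainMaterial",
    "PointState",
    "ModelParameters",
    "preset",
    "load_config",
    "dump_config",
    "PRESETS",
]


class InvalidParameterError(ValueError):
    """A physical parameter violates its admissible range."""


@dataclass(frozen=True)
class CellLineParameters:
    """Growth / metabolism / necrosis constants of one cell line.

    Units: all rate coefficients (including ``gamma_Nt``) in
    kg/(m^3 s), pressures in Pa, oxygen thresholds as mass fractions
    (dimensionless).  The specific necrosis rate is gamma_Nt/rho_t.
    """

    gamma_gt: float = 4.0e-2      # tumor-cell growth rate
    gamma_gnl: float = 4.0e-4     # O2 consumption tied to growth
    gamma_0nl: float = 6.0e-4     # O2 consumption of basal metabolism
    gamma_Nt: float = 0.01        # hypoxic necrosis rate coefficient, kg/(m^3 s)
    omega_crit: float = 1.0e-6    # hypoxia threshold (~20 mmHg)
    omega_env: float = 4.2e-6     # optimal oxygenation (~90 mmHg)
    p1: float = 1800.0            # growth inhibition onset pressure
    p_crit: float = 4000.0        # full growth inhibition pressure
    a: float = 800.0              # ECM-thinness / surface-tension parameter
    mu_t: float = 36.0            # tumor-cell phase dynamic viscosity, Pa s

    def __post_init__(self) -> None:
        for name in ("gamma_gt", "gamma_gnl", "gamma_0nl", "gamma_Nt"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if not (0 < self.omega_crit < self.omega_env < 1):
            raise InvalidParameterError(
                "need 0 < omega_crit < omega_env < 1, got "
                f"omega_crit={self.omega_crit}, omega_env={self.omega_env}"
            )
        if not (0 < self.p1 < self.p_crit):
            raise InvalidParameterError(
                f"need 0 < p1 < p_crit, got p1={self.p1}, p_crit={self.p_crit}"
            )
        if self.a <= 0:
            raise InvalidParameterError("a must be > 0")
        if self.mu_t <= 0:
            raise InvalidParameterError("mu_t must be > 0")


@dataclass(frozen=True)
class PhaseProperties:
    """Phase densities and transport constants (SI units)."""

    rho_s: float = 1000.0     # ECM scaffold density, kg/m^3
    rho_t: float = 1000.0     # tumor-cell phase density, kg/m^3
    rho_l: float = 1000.0     # interstitial fluid density, kg/m^3
    mu_l: float = 1.0e-3      # interstitial fluid viscosity, Pa s
    D0_nl: float = 3.2e-9     # free oxygen diffusivity in IF, m^2/s
    delta: float = 2.0        # tortuosity exponent of Fick diffusion
    A_t: float = 2.0          # cell-phase relative-permeability exponent
    A_l: float = 2.0          # IF relative-permeability exponent

    def __post_init__(self) -> None:
        if min(self.rho_s, self.rho_t, self.rho_l) <= 0:
            raise InvalidParameterError("densities must be > 0")
        if self.mu_l <= 0:
            raise InvalidParameterError("mu_l must be > 0")
        if self.D0_nl <= 0:
            raise InvalidParameterError("D0_nl must be > 0")
        if self.delta < 0 or self.A_t < 0 or self.A_l < 0:
            raise InvalidParameterError("exponents must be >= 0")


@dataclass(frozen=True)
class SubdomainMaterial:
    """Poroelastic constants of one spatial subdomain.

    ``k_cell_factor`` multiplies the intrinsic permeability seen by the
    tumor-cell phase only; it is the penalty that keeps cells out of the
    alginate shell while letting interstitial fluid and oxygen through.
    """

    E: float                    # Young modulus of the solid scaffold, Pa
    nu: float = 0.4             # Poisson ratio
    k: float = 1.0e-16          # intrinsic permeability, m^2
    eps0: float = 0.8           # reference porosity
    k_cell_factor: float = 1.0  # cell-phase permeability penalty

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise InvalidParameterError("E must be > 0")
        if not (0 <= self.nu < 0.5):
            raise InvalidParameterError("need 0 <= nu < 0.5")
        if self.k <= 0:
            raise InvalidParameterError("k must be > 0")
        if not (0 < self.eps0 < 1):
            raise InvalidParameterError("need 0 < eps0 < 1")
        if self.k_cell_factor <= 0:
            raise InvalidParameterError("k_cell_factor must be > 0")

    @property
    def lame_lambda(self) -> float:
        return self.E * self.nu / ((1 + self.nu) * (1 - 2 * self.nu))

    @property
    def lame_mu(self) -> float:
        return self.E / (2 * (1 + self.nu))

    @property
    def bulk_modulus(self) -> float:
        return self.E / (3 * (1 - 2 * self.nu))


@dataclass
class PointState:
    """Primary and internal variables at one material point."""

    p_l: float = 0.0        # interstitial fluid pressure, Pa
    p_tl: float = 0.0       # cell/IF pressure difference, Pa
    omega_nl: float = 4.2e-6  # oxygen mass fraction in IF
    eps: float = 0.8        # porosity
    omega_Nt: float = 0.0   # necrotic mass fraction of the cell phase

    def __post_init__(self) -> None:
        if not (0 < self.eps < 1):
            raise InvalidParameterError("need 0 < eps < 1")
        if not (0 <= self.omega_Nt <= 1):
            raise InvalidParameterError("need 0 <= omega_Nt <= 1")
        if self.omega_nl < 0:
            raise InvalidParameterError("omega_nl must be >= 0")


# Default subdomain materials.  The spheroid ECM stiffness is 1 kPa, the
# exterior carries a mechanically negligible fictitious scaffold of
# 0.6 kPa at very high porosity, and the alginate shell combines the
# measured 68 kPa stiffness with a strong cell-permeability penalty.
MCTS_INTERIOR = SubdomainMaterial(E=1000.0)
ALGINATE_SHELL = SubdomainMaterial(E=68e3, eps0=0.8, k_cell_factor=1e-6)
EXTERIOR_MEDIUM = SubdomainMaterial(E=600.0, eps0=0.99)


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set handed to the solver."""

    cell_line: CellLineParameters = field(default_factory=CellLineParameters)
    phases: PhaseProperties = field(default_factory=PhaseProperties)

    def with_updates(self, **updates: float) -> "ModelParameters":
        """Return a copy with named cell-line constants replaced.

        Keys are cell-line field names (``gamma_gt``, ``a`` ...); used by
        the sensitivity and calibration drivers.
        """
        return ModelParameters(
            cell_line=replace(self.cell_line, **updates), phases=self.phases
        )


def _cell_line_preset(name: str) -> CellLineParameters:
    if name == "generic":
        return CellLineParameters()
    if name in ("CT26-optimized", "ct26-optimized"):
        # Identified values; mu_t and gamma_gnl were not identifiable from
        # the data and keep their generic values.
        return CellLineParameters(
            gamma_gt=3.33e-2,
            gamma_0nl=6.65e-4,
            a=890.0,
            p1=1432.0,
            p_crit=5944.0,
        )
    raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")


PRESETS = ("generic", "CT26-optimized")


def preset(name: str = "generic") -> ModelParameters:
    """Return a named parameter preset."""
    return ModelParameters(cell_line=_cell_line_preset(name))


# ---------------------------------------------------------------------------
# Flat YAML/JSON config round-trip


def dump_config(params: ModelParameters, path: str | Path) -> None:
    """Serialize a parameter set as a sectioned YAML file."""
    doc = {"cell_line": asdict(params.cell_line), "phases": asdict(params.phases)}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_config(path: str | Path, base: ModelParameters | None = None) -> ModelParameters:
    """Load a parameter set from YAML, overlaying ``base`` (default generic).

    Unknown section or key names raise ``KeyError`` listing valid ones.
    """
    base = base or preset("generic")
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(doc, Mapping):
        raise ValueError(f"config root must be a mapping, got {type(doc).__name__}")
    valid_sections = {"cell_line", "phases", "preset"}
    unknown = set(doc) - valid_sections
    if unknown:
        raise KeyError(f"unknown config sections {sorted(unknown)}; valid: {sorted(valid_sections)}")
    if "preset" in doc:
        base = preset(doc["preset"])
    cl, ph = base.cell_line, base.phases
    if "cell_line" in doc:
        _check_keys(doc["cell_line"], asdict(cl), "cell_line")
        cl = replace(cl, **doc["cell_line"])
    if "phases" in doc:
        _check_keys(doc["phases"], asdict(ph), "phases")
        ph = replace(ph, **doc["phases"])
    return ModelParameters(cell_line=cl, phases=ph)


def _check_keys(given: Mapping, known: Mapping, section: str) -> None:
    unknown = set(given) - set(known)
    if unknown:
        raise KeyError(
            f"unknown keys {sorted(unknown)} in section {section!r}; "
            f"valid: {sorted(known)}"
        )
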