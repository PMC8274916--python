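"""Pointwise constitutive and closure laws of the multiphase model.

All functions are vectorized over numpy arrays and operate in SI units.
They encode, in order: the regularized biological switch functions
(oxygen, pressure, metabolism), the pressure-saturation closure of the
cell phase, transport closures (Fick diffusivity with tortuosity,
Darcy conductivity with relative permeability), the reactive source
terms (growth, oxygen sink, hypoxic necrosis), and the mechanical
closures (Biot solid pressure, linear-elastic effective stress,
porosity update under incompressible solid grains).
"""

from __future__ import annotations

import numpy as np

from .parameters import CellLineParameters, InvalidParameterError, PhaseProperties

__all__ = [
    "growth_switch_H",
    "pressure_switch_Hp",
    "metabolism_switch_Htilde",
    "cell_saturation",
    "cell_saturation_inverse",
    "liquid_saturation",
    "oxygen_diffusivity",
    "hydraulic_conductivity",
    "growth_mass_exchange",
    "oxygen_sink",
    "necrosis_rate",
    "growing_fraction",
    "solid_pressure",
    "effective_stress",
    "update_porosity",
    "PorosityCollapseError",
]


class PorosityCollapseError(ValueError):
    """Compression drove the porosity to zero or below."""


def growth_switch_H(omega_nl, omega_crit: float, omega_env: float):
    """Oxygen dependency of growth: 0 below the hypoxia threshold,
    cosine ramp between ``omega_crit`` and ``omega_env``, 1 above."""
    if not omega_crit < omega_env:
        raise InvalidParameterError("need omega_crit < omega_env")
    w = np.asarray(omega_nl, dtype=float)
    x = (w - omega_crit) / (omega_env - omega_crit)
    ramp = 0.5 - 0.5 * np.cos(np.pi * np.clip(x, 0.0, 1.0))
    return ramp if ramp.ndim else float(ramp)


def pressure_switch_Hp(p_t, p1: float, p_crit: float):
    """Pressure dependency of growth: linear ramp from 0 at ``p1`` to 1
    at ``p_crit``; the growth factor applied downstream is ``1 - Hp``."""
    if not p1 < p_crit:
        raise InvalidParameterError("need p1 < p_crit")
    p = np.asarray(p_t, dtype=float)
    out = np.clip((p - p1) / (p_crit - p1), 0.0, 1.0)
    return out if out.ndim else float(out)


def metabolism_switch_Htilde(omega_nl, omega_env: float):
    """Metabolic oxygen dependency: cosine ramp from 0 at anoxia to 1 at
    ``omega_env`` and above."""
    if omega_env <= 0:
        raise InvalidParameterError("need omega_env > 0")
    w = np.asarray(omega_nl, dtype=float)
    if np.any(w < 0):
        raise ValueError("omega_nl must be >= 0")
    out = np.where(w >= omega_env, 1.0, 0.5 - 0.5 * np.cos(np.pi * np.minimum(w, omega_env) / omega_env))
    return out if out.ndim else float(out)


def cell_saturation(p_tl, omega_Nt, a: float):
    """Cell-phase saturation from the cell/IF pressure difference.

    S_t = (2/pi) arctan( p_tl / ((1 - omega_Nt) a) ); the necrotic
    fraction offsets the curve so denser (necrotic) aggregates reach a
    given saturation at lower pressure difference.  Negative ``p_tl`` is
    clamped to saturation zero (no cell phase where the cell pressure
    does not exceed the IF pressure).
    """
    if a <= 0:
        raise InvalidParameterError("a must be > 0")
    wn = np.asarray(omega_Nt, dtype=float)
    if np.any(wn >= 1.0):
        raise ZeroDivisionError("omega_Nt = 1 makes the saturation argument singular")
    p = np.asarray(p_tl, dtype=float)
    out = (2.0 / np.pi) * np.arctan(np.maximum(p, 0.0) / ((1.0 - wn) * a))
    return out if out.ndim else float(out)


def cell_saturation_inverse(S_t, omega_Nt, a: float):
    """Pressure difference that yields saturation ``S_t`` (inverse closure)."""
    s = np.asarray(S_t, dtype=float)
    if np.any((s < 0) | (s >= 1)):
        raise ValueError("need 0 <= S_t < 1")
    out = (1.0 - np.asarray(omega_Nt, dtype=float)) * a * np.tan(np.pi * s / 2.0)
    return out if out.ndim else float(out)


def liquid_saturation(S_t):
    """Saturation constraint S_t + S_l = 1."""
    out = 1.0 - np.asarray(S_t, dtype=float)
    return out if out.ndim else float(out)


def oxygen_diffusivity(eps, S_l, D0_nl: float, delta: float = 2.0):
    """Effective oxygen diffusivity D0 (eps S_l)^delta (tortuosity law)."""
    e = np.asarray(eps, dtype=float)
    s = np.asarray(S_l, dtype=float)
    if D0_nl < 0 or np.any(e < 0) or np.any(s < 0):
        raise ValueError("negative input to oxygen_diffusivity")
    out = D0_nl * (e * s) ** delta
    return out if out.ndim else float(out)


def hydraulic_conductivity(k, S_f, mu_f: float, A: float = 2.0):
    """Darcy conductivity k S_f^A / mu_f of one fluid phase."""
    if mu_f <= 0:
        raise InvalidParameterError("mu_f must be > 0")
    out = np.asarray(k, dtype=float) * np.asarray(S_f, dtype=float) ** A / mu_f
    return out if out.ndim else float(out)


def growth_mass_exchange(omega_nl, p_t, omega_Nt, eps, S_t, params: CellLineParameters):
    """Mass exchanged from IF to the cell phase by growth, kg/(m^3 s).

    gamma_gt * H(omega) * (1 - Hp(p_t)) * (1 - omega_Nt) * eps * S_t,
    i.e. the growth rate scaled by the living cell volume fraction and
    throttled by hypoxia and compressive stress.
    """
    H = growth_switch_H(omega_nl, params.omega_crit, params.omega_env)
    Hp = pressure_switch_Hp(p_t, params.p1, params.p_crit)
    out = params.gamma_gt * np.asarray(H) * (1.0 - np.asarray(Hp)) * (
        1.0 - np.asarray(omega_Nt, dtype=float)
    ) * np.asarray(eps, dtype=float) * np.asarray(S_t, dtype=float)
    return out if out.ndim else float(out)


def oxygen_sink(omega_nl, p_t, omega_Nt, eps, S_t, params: CellLineParameters):
    """Oxygen consumed by the living cells, kg/(m^3 s).

    Growth-linked uptake shuts down with growth; basal metabolic uptake
    persists (scaled by the metabolic switch) even when growth is
    pressure-inhibited.
    """
    H = growth_switch_H(omega_nl, params.omega_crit, params.omega_env)
    Hp = pressure_switch_Hp(p_t, params.p1, params.p_crit)
    Ht = metabolism_switch_Htilde(omega_nl, params.omega_env)
    out = (
        params.gamma_gnl * np.asarray(H) * (1.0 - np.asarray(Hp))
        + params.gamma_0nl * np.asarray(Ht)
    ) * (1.0 - np.asarray(omega_Nt, dtype=float)) * np.asarray(eps, dtype=float) * np.asarray(S_t, dtype=float)
    return out if out.ndim else float(out)


def necrosis_rate(omega_nl, omega_Nt, eps, S_t, gamma_Nt: float, omega_env: float):
    """Hypoxic death rate of living cells (volumetric, 1/s scale source).

    gamma_Nt * (1 - Htilde) * (1 - omega_Nt) * eps * S_t: zero at full
    oxygenation, maximal at anoxia.
    """
    Ht = metabolism_switch_Htilde(omega_nl, omega_env)
    out = gamma_Nt * (1.0 - np.asarray(Ht)) * (
        1.0 - np.asarray(omega_Nt, dtype=float)
    ) * np.asarray(eps, dtype=float) * np.asarray(S_t, dtype=float)
    return out if out.ndim else float(out)


def growing_fraction(omega_nl, S_t, params: CellLineParameters):
    """Proliferating-cell proxy comparable to KI-67 staining profiles:
    S_t * omega / omega_env above the hypoxia threshold, zero below."""
    w = np.asarray(omega_nl, dtype=float)
    out = np.where(w <= params.omega_crit, 0.0, np.asarray(S_t, dtype=float) * w / params.omega_env)
    return out if out.ndim else float(out)


def solid_pressure(S_t, p_t, p_l):
    """Biot solid pressure p_s = S_t p_t + (1 - S_t) p_l."""
    s = np.asarray(S_t, dtype=float)
    out = s * np.asarray(p_t, dtype=float) + (1.0 - s) * np.asarray(p_l, dtype=float)
    return out if out.ndim else float(out)


def effective_stress(strain: np.ndarray, E: float, nu: float) -> np.ndarray:
    """Linear-elastic effective stress sigma = lambda tr(eps) I + 2 mu eps.

    ``strain`` is a symmetric small-strain tensor (..., d, d).
    """
    if nu >= 0.5:
        raise InvalidParameterError("nu = 0.5 (incompressible) not representable")
    eps = np.asarray(strain, dtype=float)
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    d = eps.shape[-1]
    tr = np.trace(eps, axis1=-2, axis2=-1)
    return lam * tr[..., None, None] * np.eye(d) + 2 * mu * eps


def update_porosity(eps0, J):
    """Porosity after a volume change J under incompressible solid grains:
    (1 - eps) J = 1 - eps0, hence eps = 1 - (1 - eps0)/J."""
    e0 = np.asarray(eps0, dtype=float)
    jac = np.asarray(J, dtype=float)
    if np.any(jac <= 0):
        raise ValueError("deformation Jacobian must be > 0")
    out = 1.0 - (1.0 - e0) / jac
    if np.any(out <= 0):
        raise PorosityCollapseError("compression exhausted the pore space (eps <= 0)")
    return out if out.ndim else float(out)
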