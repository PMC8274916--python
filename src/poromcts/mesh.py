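"""1-D radial meshes for the three-subdomain capsule geometry.

The computational domain is a radius [0, R_domain] split into up to
three concentric subdomains: the intracapsular region that can host the
tumor-cell phase, the alginate shell, and the exterior culture medium
(carrying a mechanically negligible fictitious scaffold, as required by
the poroelastic framework).  Subdomain interfaces always fall on mesh
vertices so material properties are element-wise constant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .parameters import (
    ALGINATE_SHELL,
    EXTERIOR_MEDIUM,
    MCTS_INTERIOR,
    SubdomainMaterial,
)

__all__ = [
    "DomainSpec",
    "Discretization",
    "RadialMesh",
    "build_mesh",
    "free_growth_domain",
    "capsule_domain",
]

# subdomain tags
MCTS, ALGINATE, EXTERIOR = 0, 1, 2
_TAG_NAMES = {MCTS: "mcts", ALGINATE: "alginate", EXTERIOR: "exterior"}


@dataclass(frozen=True)
class DomainSpec:
    """Concentric geometry of one simulation setup (SI units).

    ``R_in``/``h`` describe the capsule; for free growth (``encapsulated
    = False``) ``R_in`` only bounds the region carrying the tumor ECM
    material and no shell is meshed.
    """

    R_seed: float
    R_in: float
    h: float
    R_domain: float
    encapsulated: bool = True
    materials: dict[str, SubdomainMaterial] = field(
        default_factory=lambda: {
            "mcts": MCTS_INTERIOR,
            "alginate": ALGINATE_SHELL,
            "exterior": EXTERIOR_MEDIUM,
        }
    )

    def __post_init__(self) -> None:
        if min(self.R_seed, self.R_in, self.h, self.R_domain) <= 0:
            raise ValueError("all radii must be > 0")
        if not (self.R_seed <= self.R_in < self.R_out < self.R_domain):
            raise ValueError(
                "need R_seed <= R_in < R_out < R_domain, got "
                f"{self.R_seed}, {self.R_in}, {self.R_out}, {self.R_domain}"
            )

    @property
    def R_out(self) -> float:
        return self.R_in + self.h


def free_growth_domain(
    R_seed: float = 50e-6,
    R_domain: float = 300e-6,
    materials: dict[str, SubdomainMaterial] | None = None,
) -> DomainSpec:
    """Free-growth setup: spheroid seed in culture medium, no shell."""
    mats = {
        "mcts": MCTS_INTERIOR,
        "alginate": ALGINATE_SHELL,
        "exterior": EXTERIOR_MEDIUM,
    }
    if materials:
        mats.update(materials)
    # the nominal h is never meshed; keep the invariant chain valid
    return DomainSpec(
        R_seed=R_seed,
        R_in=R_seed,
        h=1e-9,
        R_domain=R_domain,
        encapsulated=False,
        materials=mats,
    )


def capsule_domain(
    R_in: float = 100e-6,
    h: float = 34e-6,
    E_alg: float = 68e3,
    R_seed: float = 50e-6,
    R_domain: float | None = None,
    materials: dict[str, SubdomainMaterial] | None = None,
) -> DomainSpec:
    """Encapsulated setup (CCT); default geometry is the CCT0 capsule."""
    from dataclasses import replace

    mats = {
        "mcts": MCTS_INTERIOR,
        "alginate": replace(ALGINATE_SHELL, E=E_alg),
        "exterior": EXTERIOR_MEDIUM,
    }
    if materials:
        mats.update(materials)
    if R_domain is None:
        R_domain = 2.0 * (R_in + h)
    return DomainSpec(
        R_seed=R_seed, R_in=R_in, h=h, R_domain=R_domain,
        encapsulated=True, materials=mats,
    )


@dataclass(frozen=True)
class Discretization:
    """Mesh size, time step and solver controls."""

    dh: float = 5e-6          # target element size, m
    dt: float = 1200.0        # base time step, s
    t_end: float = 4 * 86400.0
    order_u: int = 2          # displacement polynomial order
    order_scalar: int = 1     # scalar-field polynomial order
    newton_tol: float = 1e-8
    newton_maxit: int = 25
    max_dt_halvings: int = 6

    def __post_init__(self) -> None:
        if self.dh <= 0 or self.dt <= 0:
            raise ValueError("dh and dt must be > 0")
        if self.order_u < self.order_scalar + 1:
            raise ValueError(
                "displacement order must exceed scalar order (inf-sup): "
                f"got {self.order_u} vs {self.order_scalar}"
            )


class RadialMesh:
    """Conforming 1-D mesh with element subdomain tags.

    ``vertices`` are the current (possibly deformed) element end points;
    ``vertices0`` keeps the initial configuration.
    """

    def __init__(self, vertices: np.ndarray, tags: np.ndarray):
        self.vertices = np.asarray(vertices, dtype=float).copy()
        self.vertices0 = self.vertices.copy()
        self.tags = np.asarray(tags, dtype=int)
        if len(self.tags) != len(self.vertices) - 1:
            raise ValueError("one tag per element required")
        if np.any(np.diff(self.vertices) <= 0):
            raise ValueError("vertices must be strictly increasing")

    @property
    def n_elements(self) -> int:
        return len(self.tags)

    @property
    def lengths(self) -> np.ndarray:
        return np.diff(self.vertices)

    def tag_names(self) -> list[str]:
        return [_TAG_NAMES[t] for t in self.tags]

    def elements_with_tag(self, tag: int) -> np.ndarray:
        return np.flatnonzero(self.tags == tag)


def _segment(r0: float, r1: float, dh: float) -> np.ndarray:
    n = max(1, math.ceil((r1 - r0) / dh - 1e-9))
    return np.linspace(r0, r1, n + 1)


def build_mesh(domain: DomainSpec, disc: Discretization) -> RadialMesh:
    """Mesh the domain with elements of size <= dh and interfaces on nodes."""
    if disc.dh > domain.R_domain:
        raise ValueError(f"dh={disc.dh} exceeds the domain radius {domain.R_domain}")
    if domain.encapsulated:
        breaks = [0.0, domain.R_seed, domain.R_in, domain.R_out, domain.R_domain]
        seg_tags = [MCTS, MCTS, ALGINATE, EXTERIOR]
    else:
        breaks = [0.0, domain.R_seed, domain.R_domain]
        seg_tags = [MCTS, EXTERIOR]
    # drop zero-length segments from coincident breakpoints
    keep = [i for i in range(len(seg_tags)) if breaks[i + 1] - breaks[i] > 1e-12]
    verts = [np.array([0.0])]
    tags: list[int] = []
    for i in keep:
        seg = _segment(breaks[i], breaks[i + 1], disc.dh)
        if len(seg) - 1 == 1 and breaks[i + 1] - breaks[i] < disc.dh / 2:
            warnings.warn(
                f"subdomain segment [{breaks[i]:.3g}, {breaks[i+1]:.3g}] thinner "
                f"than dh; local refinement applied"
            )
        verts.append(seg[1:])
        tags.extend([seg_tags[i]] * (len(seg) - 1))
    return RadialMesh(np.concatenate(verts), np.array(tags))
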