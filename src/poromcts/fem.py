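"""Minimal 1-D Lagrange finite-element infrastructure.

Provides arbitrary-order Lagrange spaces on a :class:`~poromcts.mesh.
RadialMesh` with Gauss quadrature, interpolation of nodal vectors to
quadrature points, and scatter-assembly of elementwise residual
contributions.  Mixed discretizations (displacement one order above the
scalars, Taylor-Hood style) are obtained by instantiating two spaces on
the same mesh.
"""

from __future__ import annotations

import numpy as np

from .mesh import RadialMesh

__all__ = ["lagrange_basis", "gauss_rule", "FieldSpace"]


def lagrange_basis(order: int, xi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Values and derivatives of equispaced Lagrange shape functions.

    Returns arrays of shape (order+1, len(xi)) with N_i(xi) and
    dN_i/dxi on the reference element [0, 1].
    """
    xi = np.asarray(xi, dtype=float)
    nodes = np.linspace(0.0, 1.0, order + 1)
    n = order + 1
    N = np.ones((n, len(xi)))
    dN = np.zeros((n, len(xi)))
    for i in range(n):
        for j in range(n):
            if j == i:
                continue
            N[i] *= (xi - nodes[j]) / (nodes[i] - nodes[j])
        # derivative by product rule
        for j in range(n):
            if j == i:
                continue
            term = np.ones_like(xi) / (nodes[i] - nodes[j])
            for m in range(n):
                if m in (i, j):
                    continue
                term *= (xi - nodes[m]) / (nodes[i] - nodes[m])
            dN[i] += term
    return N, dN


def gauss_rule(n_points: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre points and weights mapped to [0, 1]."""
    x, w = np.polynomial.legendre.leggauss(n_points)
    return 0.5 * (x + 1.0), 0.5 * w


class FieldSpace:
    """Continuous Lagrange space of a given order on a radial mesh."""

    def __init__(self, mesh: RadialMesh, order: int, n_quad: int):
        self.mesh = mesh
        self.order = order
        ne = mesh.n_elements
        self.n_dofs = ne * order + 1
        self.elem_dofs = (
            np.arange(ne)[:, None] * order + np.arange(order + 1)[None, :]
        )
        self.xi_q, self.w_q = gauss_rule(n_quad)
        self.N, self.dN = lagrange_basis(order, self.xi_q)  # (n_loc, n_q)

    # -- geometry ----------------------------------------------------------
    def node_coords(self) -> np.ndarray:
        """Current coordinates of all dofs (equispaced within elements)."""
        v = self.mesh.vertices
        local = np.linspace(0.0, 1.0, self.order + 1)
        coords = v[:-1, None] + np.diff(v)[:, None] * local[None, :]
        out = np.empty(self.n_dofs)
        out[self.elem_dofs] = coords
        return out

    def quad_coords(self) -> np.ndarray:
        """Physical coordinates of quadrature points, shape (ne, n_q)."""
        v = self.mesh.vertices
        return v[:-1, None] + np.diff(v)[:, None] * self.xi_q[None, :]

    def jacobians(self) -> np.ndarray:
        """Element mapping Jacobians h_e, shape (ne,)."""
        return self.mesh.lengths

    # -- interpolation -----------------------------------------------------
    def values(self, dof_vec: np.ndarray) -> np.ndarray:
        """Field values at quadrature points, shape (ne, n_q)."""
        return np.einsum("el,lq->eq", dof_vec[self.elem_dofs], self.N)

    def gradients(self, dof_vec: np.ndarray) -> np.ndarray:
        """Field derivatives d/dr at quadrature points, shape (ne, n_q)."""
        return (
            np.einsum("el,lq->eq", dof_vec[self.elem_dofs], self.dN)
            / self.jacobians()[:, None]
        )

    # -- assembly ----------------------------------------------------------
    def assemble(self, integrand_val: np.ndarray | None,
                 integrand_grad: np.ndarray | None,
                 measure: np.ndarray) -> np.ndarray:
        """Assemble sum_q w_q [f N_i + g dN_i/dr] measure into dof vector.

        ``integrand_val`` (f) and ``integrand_grad`` (g) have shape
        (ne, n_q); ``measure`` is the geometric weight (ne, n_q) already
        including the metric factor (e.g. r^2) but not h_e or w_q.
        """
        h = self.jacobians()[:, None]
        contrib = 0.0
        if integrand_val is not None:
            contrib = contrib + np.einsum(
                "eq,lq,q->el", integrand_val * measure * h, self.N, self.w_q
            )
        if integrand_grad is not None:
            contrib = contrib + np.einsum(
                "eq,lq,q->el", integrand_grad * measure, self.dN, self.w_q
            )
        out = np.zeros(self.n_dofs)
        np.add.at(out, self.elem_dofs, contrib)
        return out

    def integrate(self, integrand: np.ndarray, measure: np.ndarray) -> float:
        """Integrate a quadrature-point field over the mesh."""
        h = self.jacobians()[:, None]
        return float(np.einsum("eq,q->", integrand * measure * h, self.w_q))

    def boundary_dofs(self) -> tuple[int, int]:
        """Dof indices of the first and last mesh node."""
        return 0, self.n_dofs - 1

    def interp_at(self, dof_vec: np.ndarray, r: np.ndarray) -> np.ndarray:
        """Evaluate the field at arbitrary radii (piecewise polynomial)."""
        r = np.atleast_1d(np.asarray(r, dtype=float))
        v = self.mesh.vertices
        e = np.clip(np.searchsorted(v, r, side="right") - 1, 0, self.mesh.n_elements - 1)
        xi = (r - v[e]) / self.mesh.lengths[e]
        N, _ = lagrange_basis(self.order, np.clip(xi, 0.0, 1.0))
        # N has shape (n_loc, n_pts) with per-point xi: lagrange_basis
        # broadcasts over the xi vector, so N[:, i] matches point i.
        vals = np.einsum("il,li->i", dof_vec[self.elem_dofs[e]], N)
        return vals
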