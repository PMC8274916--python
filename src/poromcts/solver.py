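"""Coupled finite-element solver for the multiphase spheroid model.

Discretizes the four-field system -- radial ECM displacement u_s,
interstitial-fluid pressure p_l, cell/IF pressure difference p_tl and
oxygen mass fraction omega_nl -- on a 1-D spherically-symmetric mesh
with mixed Lagrange elements (displacement one order above the
scalars), advanced by an incremental monolithic implicit-Euler scheme:
each step solves for the displacement increment and the end-of-step
scalars with a damped Newton iteration, then updates the geometry
(updated-Lagrangian), the porosity (incompressible solid grains) and
the necrotic fraction (pointwise implicit ODE).

Numerical design, in brief:

* Flux, momentum and stiffness terms are integrated with Gauss
  quadrature; storage and reaction terms are mass-lumped at the
  element-local nodes (row-sum lumping with the radial metric).
  Lumping keeps the Newton iteration monotone at the degenerate
  cell-phase saturation front, where a consistent mass matrix
  produces limit cycles.
* The Jacobian is assembled by finite differences on the residual
  using a graph coloring of the element connectivity, so every
  pointwise closure (switch functions, saturation law, implicit
  necrosis update) is differentiated consistently without hand-coded
  linearizations.
* The same kernel, configured in Cartesian single-fluid mode with a
  surface load, is linear poroelastic consolidation and serves as the
  Terzaghi verification benchmark.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import closures as cl
from .fem import FieldSpace, lagrange_basis
from .mesh import (
    ALGINATE,
    Discretization,
    DomainSpec,
    MCTS,
    RadialMesh,
    build_mesh,
)
from .parameters import ModelParameters, PhaseProperties, SubdomainMaterial

__all__ = [
    "SimState",
    "SimulationResult",
    "ForwardModel",
    "NewtonError",
    "initialize_state",
    "assemble_residual",
    "advance_step",
    "run_simulation",
    "probe_radial",
]


class NewtonError(RuntimeError):
    """The Newton iteration failed to converge for one time step."""


@dataclass
class SimState:
    """Discrete unknowns and internal variables at one time level.

    Internal variables are carried at two point sets: Gauss points
    (suffix ``_g``; feed fluxes and the stress update) and element-local
    nodes (suffix ``_s``; feed the lumped storage terms).
    """

    t: float
    u: np.ndarray        # total displacement, u-space nodes, m
    p_l: np.ndarray      # IF pressure, scalar nodes, Pa
    p_tl: np.ndarray     # cell/IF pressure difference, scalar nodes, Pa
    w: np.ndarray        # oxygen mass fraction, scalar nodes
    eps_g: np.ndarray    # porosity at Gauss points (ne, nq)
    eps_s: np.ndarray    # porosity at storage points (ne, k+1)
    omega_Nt_g: np.ndarray
    omega_Nt_s: np.ndarray
    e_rr: np.ndarray     # accumulated radial strain, Gauss points
    e_tt: np.ndarray     # accumulated hoop strain, Gauss points
    m_t: np.ndarray      # stored cell content eps*S_t, storage points
    m_w: np.ndarray      # stored oxygen content eps*S_l*w, storage points

    def copy(self) -> "SimState":
        return SimState(
            self.t, *(a.copy() for a in (
                self.u, self.p_l, self.p_tl, self.w,
                self.eps_g, self.eps_s, self.omega_Nt_g, self.omega_Nt_s,
                self.e_rr, self.e_tt, self.m_t, self.m_w,
            ))
        )


@dataclass
class SimulationResult:
    """Time series, snapshots and scalar summaries of one run."""

    series: pd.DataFrame
    snapshots: list[dict]
    confluence_time_s: float
    status: str = "ok"
    R_in0_m: float = float("nan")
    R_out0_m: float = float("nan")
    encapsulated: bool = False

    def to_csv(self, path) -> None:
        self.series.to_csv(path, index=False)


_SNAPSHOT_FIELDS = ("p_l", "p_tl", "omega_nl", "S_t", "omega_Nt", "omega_grow", "eps")


class ForwardModel:
    """One configured simulation setup (mesh, materials, physics mode)."""

    def __init__(
        self,
        mesh: RadialMesh,
        tag_materials: dict[int, SubdomainMaterial],
        disc: Discretization,
        params: ModelParameters,
        *,
        geometry: str = "spherical",
        single_fluid: bool = False,
        traction: float = 0.0,
        update_geometry: bool = True,
        S_t0: float = 0.6,
        seed_radius: float = 0.0,
        seed_width: float = 10e-6,
        p_l_scale: float = 10.0,
        wall_band_elements: int = 2,
        reg_eps: float = 1e-6,
    ):
        if geometry not in ("spherical", "cartesian"):
            raise ValueError("geometry must be 'spherical' or 'cartesian'")
        self.mesh = mesh
        self.disc = disc
        self.params = params
        self.geometry = geometry
        self.single_fluid = single_fluid
        self.traction = float(traction)
        self.update_geometry = update_geometry
        self.S_t0 = S_t0
        self.seed_radius = seed_radius
        self.seed_width = seed_width
        self.wall_band_elements = wall_band_elements
        self.reg_eps = reg_eps
        self.linear = single_fluid and not update_geometry

        nq = disc.order_u + 2
        self.U = FieldSpace(mesh, disc.order_u, nq)
        self.S = FieldSpace(mesh, disc.order_scalar, nq)
        self.n_u = self.U.n_dofs
        self.n_s = self.S.n_dofs
        self.n_dofs = self.n_u + 3 * self.n_s
        self.off = {
            "u": 0, "p_l": self.n_u, "p_tl": self.n_u + self.n_s,
            "w": self.n_u + 2 * self.n_s,
        }
        # storage (lumping) points = element-local scalar nodes; the
        # scalar basis is the identity there, the u basis is tabulated
        k = disc.order_scalar
        self.xi_s = np.linspace(0.0, 1.0, k + 1)
        self.Nu_s, self.dNu_s = lagrange_basis(disc.order_u, self.xi_s)
        self.n_sloc = k + 1

        # Cell-capable subdomains: the cell phase exists only where the
        # three-domain physics allows it (never inside the alginate gel,
        # whose ~20 nm pores exclude cells; the exterior hosts cells in
        # free growth, where the spheroid advances into the medium).
        self.cell_capable = (mesh.tags != ALGINATE).astype(float)[:, None]

        # per-element material arrays
        mats = [tag_materials[t] for t in mesh.tags]
        col = lambda attr: np.array([getattr(m, attr) for m in mats])[:, None]
        self.lam = col("lame_lambda")
        self.mu = col("lame_mu")
        self.k = col("k")
        self.k_cell = col("k") * col("k_cell_factor")
        self.eps0_g = np.broadcast_to(col("eps0"), (mesh.n_elements, nq)).copy()
        self.eps0_s = np.broadcast_to(col("eps0"), (mesh.n_elements, self.n_sloc)).copy()

        # unknown scaling (units of each block) for FD steps and norms
        w_env = params.cell_line.omega_env
        self.scales = np.concatenate([
            np.full(self.n_u, 1e-6),
            np.full(self.n_s, p_l_scale),
            np.full(self.n_s, params.cell_line.a),
            np.full(self.n_s, w_env),
        ])

        self._setup_dirichlet()
        self._setup_sparsity()
        self._wall_elements = self._find_wall_band()
        self._lu_cache = None

    # -- construction helpers ---------------------------------------------
    @classmethod
    def from_domain(cls, domain: DomainSpec, disc: Discretization,
                    params: ModelParameters, **kw) -> "ForwardModel":
        mesh = build_mesh(domain, disc)
        tag_mats = {
            MCTS: domain.materials["mcts"],
            ALGINATE: domain.materials["alginate"],
            2: domain.materials["exterior"],
        }
        model = cls(mesh, tag_mats, disc, params,
                    seed_radius=domain.R_seed, **kw)
        model.domain = domain
        return model

    @classmethod
    def consolidation_column(
        cls, L: float, p0: float, material: SubdomainMaterial,
        phases: PhaseProperties, disc: Discretization,
        params: ModelParameters | None = None,
    ) -> "ForwardModel":
        """Cartesian single-fluid column under a drained surface load."""
        import math

        n = max(2, math.ceil(L / disc.dh))
        mesh = RadialMesh(np.linspace(0.0, L, n + 1), np.zeros(n, dtype=int))
        params = params or ModelParameters(phases=phases)
        params = ModelParameters(cell_line=params.cell_line, phases=phases)
        model = cls(
            mesh, {0: material}, disc, params,
            geometry="cartesian", single_fluid=True, traction=p0,
            update_geometry=False, p_l_scale=max(p0, 1.0),
        )
        model.domain = None
        return model

    def _setup_dirichlet(self) -> None:
        off = self.off
        dofs: list[int] = []
        vals: list[float] = []
        u0, uN = 0, self.n_u - 1
        sN = self.n_s - 1
        if self.geometry == "spherical":
            dofs += [off["u"] + u0, off["u"] + uN]
            vals += [0.0, 0.0]
            dofs += [off["p_l"] + sN]
            vals += [0.0]
            if self.single_fluid:
                dofs += list(off["p_tl"] + np.arange(self.n_s))
                vals += [0.0] * self.n_s
                dofs += list(off["w"] + np.arange(self.n_s))
                vals += [self.params.cell_line.omega_env] * self.n_s
            else:
                dofs += [off["p_tl"] + sN, off["w"] + sN]
                vals += [0.0, self.params.cell_line.omega_env]
        else:  # consolidation column: fixed bottom, drained loaded top
            dofs += [off["u"] + u0, off["p_l"] + sN]
            vals += [0.0, 0.0]
            dofs += list(off["p_tl"] + np.arange(self.n_s))
            vals += [0.0] * self.n_s
            dofs += list(off["w"] + np.arange(self.n_s))
            vals += [self.params.cell_line.omega_env] * self.n_s
        self.dirichlet_dofs = np.array(dofs, dtype=int)
        self.dirichlet_vals = np.array(vals)
        self._is_dirichlet = np.zeros(self.n_dofs, dtype=bool)
        self._is_dirichlet[self.dirichlet_dofs] = True

    def _elem_global_dofs(self, e: int) -> np.ndarray:
        return np.concatenate([
            self.off["u"] + self.U.elem_dofs[e],
            self.off["p_l"] + self.S.elem_dofs[e],
            self.off["p_tl"] + self.S.elem_dofs[e],
            self.off["w"] + self.S.elem_dofs[e],
        ])

    def _setup_sparsity(self) -> None:
        """Column coloring of the element-connectivity graph for FD Jacobian."""
        ne = self.mesh.n_elements
        dof_elems: list[list[int]] = [[] for _ in range(self.n_dofs)]
        elem_dofs = [self._elem_global_dofs(e) for e in range(ne)]
        for e in range(ne):
            for d in elem_dofs[e]:
                dof_elems[d].append(e)
        col_rows = []
        for j in range(self.n_dofs):
            rows = np.unique(np.concatenate(
                [elem_dofs[e] for e in dof_elems[j]] or [np.array([j])]
            ))
            col_rows.append(rows)
        # greedy coloring: two columns conflict if some row depends on
        # both, i.e. if they lie in the same or in adjacent elements
        color = np.full(self.n_dofs, -1, dtype=int)
        for j in range(self.n_dofs):
            used = set()
            for e in dof_elems[j]:
                for en in (e - 1, e, e + 1):
                    if 0 <= en < ne:
                        for d in elem_dofs[en]:
                            if color[d] >= 0:
                                used.add(color[d])
            c = 0
            while c in used:
                c += 1
            color[j] = c
        self.n_colors = int(color.max()) + 1
        indptr = np.zeros(self.n_dofs + 1, dtype=int)
        for j in range(self.n_dofs):
            indptr[j + 1] = indptr[j] + len(col_rows[j])
        indices = np.concatenate(col_rows)
        self._csc_indptr = indptr
        self._csc_indices = indices
        self._color_cols = [np.flatnonzero(color == c) for c in range(self.n_colors)]
        self._color_positions = []
        self._color_rows = []
        for c in range(self.n_colors):
            cols = self._color_cols[c]
            pos = np.concatenate([np.arange(indptr[j], indptr[j + 1]) for j in cols])
            self._color_positions.append(pos)
            self._color_rows.append(indices[pos])

    def _find_wall_band(self) -> np.ndarray:
        if self.geometry != "spherical":
            return np.array([], dtype=int)
        mcts_elems = self.mesh.elements_with_tag(MCTS)
        if len(mcts_elems) == 0:
            return np.array([], dtype=int)
        return mcts_elems[-self.wall_band_elements:]

    # -- geometry helpers --------------------------------------------------
    def _metric(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(r at Gauss pts, metric g at Gauss pts, r at storage pts)."""
        r_q = self.S.quad_coords()
        v = self.mesh.vertices
        r_s = v[:-1, None] + np.diff(v)[:, None] * self.xi_s[None, :]
        if self.geometry == "spherical":
            return r_q, r_q ** 2, r_s
        return r_q, np.ones_like(r_q), r_s

    def _lumped_weights(self, g: np.ndarray) -> np.ndarray:
        """Row-sum lumped weights V[e, i] = int_e N_i g dr, shape (ne, k+1)."""
        h = self.S.jacobians()[:, None]
        return np.einsum("eq,iq,q->ei", g * h, self.S.N, self.S.w_q)

    def _lumped_assemble(self, vals_s: np.ndarray, Vloc: np.ndarray) -> np.ndarray:
        out = np.zeros(self.n_s)
        np.add.at(out, self.S.elem_dofs, vals_s * Vloc)
        return out

    def _storage_scalar(self, vec: np.ndarray) -> np.ndarray:
        """Scalar field at storage points = its element-local nodal values."""
        return vec[self.S.elem_dofs]

    def _storage_u(self, du: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Displacement and its gradient at storage points."""
        loc = du[self.U.elem_dofs]
        du_s = np.einsum("el,ls->es", loc, self.Nu_s)
        du_r_s = np.einsum("el,ls->es", loc, self.dNu_s) / self.S.jacobians()[:, None]
        return du_s, du_r_s

    # -- state ------------------------------------------------------------
    def initial_state(self) -> SimState:
        cl_par = self.params.cell_line
        ne, nq = self.mesh.n_elements, len(self.S.xi_q)
        r_nodes = self.S.node_coords()
        if self.single_fluid:
            p_tl = np.zeros(self.n_s)
        else:
            p_tl0 = cl.cell_saturation_inverse(self.S_t0, 0.0, cl_par.a)
            p_tl = p_tl0 * _seed_profile(r_nodes, self.seed_radius, self.seed_width)
        w = np.full(self.n_s, cl_par.omega_env)
        state = SimState(
            t=0.0,
            u=np.zeros(self.n_u),
            p_l=np.zeros(self.n_s),
            p_tl=p_tl,
            w=w,
            eps_g=self.eps0_g.copy(),
            eps_s=self.eps0_s.copy(),
            omega_Nt_g=np.zeros((ne, nq)),
            omega_Nt_s=np.zeros((ne, self.n_sloc)),
            e_rr=np.zeros((ne, nq)),
            e_tt=np.zeros((ne, nq)),
            m_t=np.zeros((ne, self.n_sloc)),
            m_w=np.zeros((ne, self.n_sloc)),
        )
        ptl_s = self._storage_scalar(p_tl)
        S_t = self.cell_capable * cl.cell_saturation(ptl_s, 0.0, cl_par.a)
        state.m_t = state.eps_s * S_t
        state.m_w = state.eps_s * (1.0 - S_t) * self._storage_scalar(w)
        return state

    # -- residual ---------------------------------------------------------
    def _fields(self, X: np.ndarray, state: SimState, dt: float) -> dict:
        """Evaluate all trial fields at Gauss and storage points."""
        p = self.params
        cl_par, ph = p.cell_line, p.phases
        du = X[: self.n_u]
        pl = X[self.off["p_l"]: self.off["p_l"] + self.n_s]
        ptl = X[self.off["p_tl"]: self.off["p_tl"] + self.n_s]
        wv = X[self.off["w"]:]

        r_q, g, r_s = self._metric()
        # --- Gauss-point kinematics and coefficients (fluxes, momentum)
        du_q = self.U.values(du)
        du_r = self.U.gradients(du)
        pl_q, pl_r = self.S.values(pl), self.S.gradients(pl)
        ptl_q, ptl_r = self.S.values(ptl), self.S.gradients(ptl)
        w_q, w_r = self.S.values(wv), self.S.gradients(wv)
        du_s, du_r_s = self._storage_u(du)
        pl_s = self._storage_scalar(pl)
        ptl_s = self._storage_scalar(ptl)
        w_s = self._storage_scalar(wv)

        if self.geometry == "spherical":
            du_over_r = du_q / r_q
            du_over_r_s = np.where(r_s > 1e-15, du_s / np.maximum(r_s, 1e-15), du_r_s)
            div_du = du_r + 2.0 * du_over_r
            div_du_s = du_r_s + 2.0 * du_over_r_s
            J_g = (1.0 + du_r) * (1.0 + du_over_r) ** 2
            J_s = (1.0 + du_r_s) * (1.0 + du_over_r_s) ** 2
        else:
            du_over_r = np.zeros_like(du_q)
            div_du, div_du_s = du_r, du_r_s
            J_g, J_s = 1.0 + du_r, 1.0 + du_r_s

        J_g_safe = np.clip(J_g, 0.05, None)
        J_s_safe = np.clip(J_s, 0.05, None)
        eps_g = np.clip(1.0 - (1.0 - state.eps_g) / J_g_safe, 1e-4, 1.0 - 1e-4)
        eps_s = np.clip(1.0 - (1.0 - state.eps_s) / J_s_safe, 1e-4, 1.0 - 1e-4)

        if self.single_fluid:
            omega_Nt_g, omega_Nt_s = state.omega_Nt_g, state.omega_Nt_s
            S_t_g = np.zeros_like(ptl_q)
            S_t_s = np.zeros_like(ptl_s)
            S_t_src = S_t_s
            M_gr = np.zeros_like(ptl_s)
            sink = np.zeros_like(ptl_s)
        else:
            # Gauss side: saturation for mobilities and the Biot split
            w_g_cl = np.maximum(w_q, 0.0)
            H_g = cl.growth_switch_H(w_g_cl, cl_par.omega_crit, cl_par.omega_env)
            Hp_g = cl.pressure_switch_Hp(pl_q + ptl_q, cl_par.p1, cl_par.p_crit)
            Ht_g = cl.metabolism_switch_Htilde(w_g_cl, cl_par.omega_env)
            omega_Nt_g = _necrosis_backward_euler(
                state.omega_Nt_g, dt,
                cl_par.gamma_Nt * (1.0 - Ht_g) / ph.rho_t,
                cl_par.gamma_gt * H_g * (1.0 - Hp_g) / ph.rho_t,
            )
            S_t_g = self.cell_capable * _saturation_smooth(ptl_q, omega_Nt_g, cl_par.a)
            # storage side: saturation, sources, necrosis at local nodes
            w_s_cl = np.maximum(w_s, 0.0)
            H_s = cl.growth_switch_H(w_s_cl, cl_par.omega_crit, cl_par.omega_env)
            Hp_s = cl.pressure_switch_Hp(pl_s + ptl_s, cl_par.p1, cl_par.p_crit)
            Ht_s = cl.metabolism_switch_Htilde(w_s_cl, cl_par.omega_env)
            omega_Nt_s = _necrosis_backward_euler(
                state.omega_Nt_s, dt,
                cl_par.gamma_Nt * (1.0 - Ht_s) / ph.rho_t,
                cl_par.gamma_gt * H_s * (1.0 - Hp_s) / ph.rho_t,
            )
            S_t_s = self.cell_capable * _saturation_smooth(ptl_s, omega_Nt_s, cl_par.a)
            # sources see the exact clamped saturation: the smoothing floor
            # must not seed autocatalytic growth in cell-free regions
            S_t_src = self.cell_capable * cl.cell_saturation(ptl_s, omega_Nt_s, cl_par.a)
            M_gr = cl_par.gamma_gt * H_s * (1.0 - Hp_s) * (1.0 - omega_Nt_s) \
                * eps_s * S_t_src
            sink = (
                cl_par.gamma_gnl * H_s * (1.0 - Hp_s) + cl_par.gamma_0nl * Ht_s
            ) * (1.0 - omega_Nt_s) * eps_s * S_t_src

        S_l_g = 1.0 - S_t_g
        S_l_s = 1.0 - S_t_s
        p_s_g = S_t_g * (pl_q + ptl_q) + S_l_g * pl_q

        e_rr = state.e_rr + du_r
        e_tt = state.e_tt + du_over_r
        tr = e_rr + 2.0 * e_tt if self.geometry == "spherical" else e_rr
        s_rr = self.lam * tr + 2.0 * self.mu * e_rr - p_s_g
        s_tt = self.lam * tr + 2.0 * self.mu * e_tt - p_s_g

        K_t = self.k_cell * S_t_g ** ph.A_t / cl_par.mu_t
        K_l = self.k * S_l_g ** ph.A_l / ph.mu_l
        D_w = ph.D0_nl * (eps_g * S_l_g) ** ph.delta

        return dict(
            r_q=r_q, g=g, r_s=r_s,
            du_q=du_q, du_r=du_r, div_du=div_du, div_du_s=div_du_s,
            J_g=J_g, J_s=J_s, eps_g=eps_g, eps_s=eps_s,
            omega_Nt_g=omega_Nt_g, omega_Nt_s=omega_Nt_s,
            S_t_g=S_t_g, S_t_s=S_t_s, S_l_g=S_l_g, S_l_s=S_l_s,
            p_l_g=pl_q, p_tl_g=ptl_q, p_s_g=p_s_g,
            p_l_s=pl_s, p_tl_s=ptl_s, w_s=w_s,
            w_g=w_q, w_r=w_r, pl_r=pl_r, ptl_r=ptl_r,
            e_rr=e_rr, e_tt=e_tt, s_rr=s_rr, s_tt=s_tt,
            K_t=K_t, K_l=K_l, D_w=D_w, M_gr=M_gr, sink=sink,
        )

    def residual(self, X: np.ndarray, state: SimState, dt: float,
                 fields: dict | None = None, raw: bool = False) -> np.ndarray:
        """Weak-form residual of the monolithic implicit-Euler step.

        ``raw`` returns the unconstrained physical residual (no Dirichlet
        row replacement, no storage regularization); its row sums are the
        discrete mass-budget statements used by the diagnostics.
        """
        f = fields or self._fields(X, state, dt)
        ph = self.params.phases
        g = f["g"]
        if not np.all(np.isfinite(f["S_t_g"])) or not np.all(np.isfinite(f["s_rr"])):
            raise FloatingPointError("non-finite coefficient in residual assembly")
        Vloc = self._lumped_weights(g)

        # momentum of the multiphase system (Biot split)
        if self.geometry == "spherical":
            R_u = self.U.assemble(2.0 * f["s_tt"] / f["r_q"], f["s_rr"], g)
        else:
            R_u = self.U.assemble(None, f["s_rr"], g)
        if self.traction:
            # compressive surface load: total stress = -p0 at the outer face
            R_u[-1] += self.traction * (
                self.mesh.vertices[-1] ** 2 if self.geometry == "spherical" else 1.0
            )

        # summed (solid + both fluids) mass balance -> p_l equation
        # (consistent quadrature in single-fluid mode, where there is no
        # saturation front and lumping would only cost accuracy)
        grad_pt = f["pl_r"] + f["ptl_r"]
        exch = f["M_gr"] * (1.0 / ph.rho_t - 1.0 / ph.rho_l)
        if self.single_fluid:
            R_pl = self.S.assemble(f["div_du"] / dt, None, g)
        else:
            R_pl = self._lumped_assemble(f["div_du_s"] / dt - exch, Vloc)
        R_pl += self.S.assemble(None, f["K_t"] * grad_pt + f["K_l"] * f["pl_r"], g)

        # tumor-cell phase mass balance -> p_tl equation.  A tiny storage
        # regularization keeps the equation non-degenerate where the cell
        # phase is absent (saturation clamped at zero): there it simply
        # freezes p_tl at its previous value.
        if self.single_fluid:
            R_ptl = np.zeros(self.n_s)
        else:
            stor_t = (f["eps_s"] * f["S_t_s"] - state.m_t) / dt \
                + f["eps_s"] * f["S_t_s"] * f["div_du_s"] / dt
            if not raw:
                c_reg = self.reg_eps * f["eps_s"] * 2.0 / (np.pi * self.params.cell_line.a)
                ptl_prev = self._storage_scalar(state.p_tl)
                stor_t = stor_t + c_reg * (f["p_tl_s"] - ptl_prev) / dt
            R_ptl = self._lumped_assemble(stor_t - f["M_gr"] / ph.rho_t, Vloc)
            R_ptl += self.S.assemble(None, f["K_t"] * grad_pt, g)

        # oxygen advection-diffusion -> omega equation
        if self.single_fluid:
            R_w = np.zeros(self.n_s)
        else:
            stor_w = (f["eps_s"] * f["S_l_s"] * f["w_s"] - state.m_w) / dt \
                + f["eps_s"] * f["S_l_s"] * f["w_s"] * f["div_du_s"] / dt
            R_w = self._lumped_assemble(stor_w + f["sink"] / ph.rho_l, Vloc)
            R_w += self.S.assemble(
                None,
                f["eps_g"] * f["S_l_g"] * f["D_w"] * f["w_r"]
                + f["w_g"] * f["K_l"] * f["pl_r"],
                g,
            )

        R = np.concatenate([R_u, R_pl, R_ptl, R_w])
        if not raw:
            R[self.dirichlet_dofs] = X[self.dirichlet_dofs] - self.dirichlet_vals
        return R

    # -- Jacobian by colored finite differences ----------------------------
    def _fd_jacobian(self, X: np.ndarray, R0: np.ndarray, state: SimState,
                     dt: float) -> sp.csc_matrix:
        h = 1e-6 * self.scales
        data = np.zeros(len(self._csc_indices))
        for c in range(self.n_colors):
            cols = self._color_cols[c]
            Xp = X.copy()
            Xp[cols] += h[cols]
            Rp = self.residual(Xp, state, dt)
            dR = Rp - R0
            pos = self._color_positions[c]
            rows = self._color_rows[c]
            hcol = np.repeat(h[cols], np.diff(self._csc_indptr)[cols])
            data[pos] = dR[rows] / hcol
        return sp.csc_matrix(
            (data, self._csc_indices, self._csc_indptr),
            shape=(self.n_dofs, self.n_dofs),
        )

    # -- Newton step -------------------------------------------------------
    def newton_solve(self, X0: np.ndarray, state: SimState, dt: float) -> np.ndarray:
        disc = self.disc
        X = X0.copy()
        R = self.residual(X, state, dt)
        lu = Dr = None
        fresh = False
        for it in range(disc.newton_maxit):
            if self.linear and self._lu_cache is not None:
                lu, Dr = self._lu_cache
                fresh = True
            elif lu is None:
                # modified Newton: reuse the factorization while the
                # iteration contracts; rebuild when the line search damps
                J = self._fd_jacobian(X, R, state, dt)
                Dc = sp.diags(self.scales)
                Js = (J @ Dc).tocsr()
                row_max = np.maximum(np.abs(Js).max(axis=1).toarray().ravel(), 1e-300)
                Dr = sp.diags(1.0 / row_max)
                lu = spla.splu((Dr @ Js).tocsc())
                fresh = True
                if self.linear:
                    self._lu_cache = (lu, Dr)
            y = lu.solve(-(Dr @ R))
            dX = self.scales * y
            step_norm = np.max(np.abs(y))
            # backtracking line search on the scaled Newton-step norm
            alpha = 1.0
            ok = False
            for _ in range(8):
                Xt = X + alpha * dX
                try:
                    Rt = self.residual(Xt, state, dt)
                except FloatingPointError:
                    alpha *= 0.5
                    continue
                nt = np.max(np.abs(lu.solve(-(Dr @ Rt))))
                contract = 0.5 if fresh else 0.2
                if nt <= max((1.0 - contract * alpha) * step_norm, 0.1 * disc.newton_tol):
                    ok = True
                    break
                alpha *= 0.5
            if not ok:
                if fresh:
                    raise NewtonError(f"line search stalled at t={state.t:.0f}s")
                lu = None  # stale Jacobian: rebuild and retry
                continue
            X, R = Xt, Rt
            self._last_newton_iters = it + 1
            if alpha * step_norm < disc.newton_tol or nt < disc.newton_tol:
                return X
            if not self.linear:
                # keep the factorization only while it contracts strongly
                if alpha < 1.0 or nt > 0.3 * step_norm:
                    lu = None
                else:
                    fresh = False
        raise NewtonError(
            f"no convergence in {disc.newton_maxit} iterations at t={state.t:.0f}s "
            f"(scaled step {step_norm:.2e})"
        )

    # -- time stepping -----------------------------------------------------
    def step(self, state: SimState, dt: float) -> tuple[SimState, dict]:
        """Advance one implicit-Euler step; returns (new_state, diagnostics)."""
        X0 = np.concatenate([
            np.zeros(self.n_u), state.p_l, state.p_tl, state.w,
        ])
        X = self.newton_solve(X0, state, dt)
        f = self._fields(X, state, dt)
        if np.any(f["J_g"] <= 0.05) or np.any(f["J_s"] <= 0.05):
            raise NewtonError("deformation Jacobian collapsed during step")

        diag = self._diagnostics(X, f, state, dt)

        new = state.copy()
        new.t = state.t + dt
        du = X[: self.n_u]
        new.u = state.u + du
        new.p_l = X[self.off["p_l"]: self.off["p_l"] + self.n_s]
        new.p_tl = X[self.off["p_tl"]: self.off["p_tl"] + self.n_s]
        new.w = X[self.off["w"]:]
        new.eps_g = f["eps_g"]
        new.eps_s = f["eps_s"]
        new.omega_Nt_g = f["omega_Nt_g"]
        new.omega_Nt_s = f["omega_Nt_s"]
        new.e_rr = f["e_rr"]
        new.e_tt = f["e_tt"]
        new.m_t = f["eps_s"] * f["S_t_s"]
        new.m_w = f["eps_s"] * f["S_l_s"] * np.maximum(f["w_s"], 0.0)
        if self.update_geometry:
            vert_dofs = np.arange(0, self.n_u, self.disc.order_u)
            self.mesh.vertices += du[vert_dofs]
        diag["newton_iters"] = self._last_newton_iters
        diag["sigma_rr_wall"] = self._wall_average(f["s_rr"])
        diag["p_t_wall"] = self._wall_average(f["p_l_g"] + f["p_tl_g"])
        diag["p_s_wall"] = self._wall_average(f["p_s_g"])
        return new, diag

    def _diagnostics(self, X: np.ndarray, f: dict, state: SimState,
                     dt: float) -> dict:
        """Per-step mass budgets from the unconstrained residual.

        Because the Lagrange basis is a partition of unity (and the
        lumped weights sum to the element volume), the sum of the
        physical (raw) residual rows of a mass-balance equation over the
        free dofs is exactly the discrete budget "storage change -
        sources + boundary flux" with the variationally consistent
        (reaction) boundary flux.  At convergence it measures the true
        conservation defect of the accepted step, including the effect
        of the storage regularization (excluded from the raw form).
        """
        raw = self.residual(X, state, dt, fields=f, raw=True)
        free = ~self._is_dirichlet
        total_volume = self.S.integrate(np.ones_like(f["g"]), f["g"])
        sl = slice(self.off["p_tl"], self.off["p_tl"] + self.n_s)
        budget_cell = abs(dt * raw[sl][free[sl]].sum()) / total_volume
        sl2 = slice(self.off["p_l"], self.off["p_l"] + self.n_s)
        budget_tot = abs(dt * raw[sl2][free[sl2]].sum()) / total_volume
        return {"mass_budget_cell": budget_cell, "mass_budget_total": budget_tot}

    def _wall_average(self, quad_field: np.ndarray) -> float:
        if len(self._wall_elements) == 0:
            return float("nan")
        return float(np.mean(quad_field[self._wall_elements]))

    # -- summaries ---------------------------------------------------------
    def storage_saturation(self, state: SimState) -> np.ndarray:
        """Cell saturation at storage points (exact clamped law,
        restricted to cell-capable subdomains), shape (ne, k+1)."""
        ptl_s = self._storage_scalar(state.p_tl)
        return self.cell_capable * cl.cell_saturation(
            ptl_s, state.omega_Nt_s, self.params.cell_line.a
        )

    def nodal_saturation(self, state: SimState) -> np.ndarray:
        return self.storage_to_nodes(self.storage_saturation(state))

    def storage_to_nodes(self, arr_s: np.ndarray) -> np.ndarray:
        """Average element-local storage-point values onto scalar nodes."""
        out = np.zeros(self.n_s)
        cnt = np.zeros(self.n_s)
        np.add.at(out, self.S.elem_dofs, arr_s)
        np.add.at(cnt, self.S.elem_dofs, 1.0)
        return out / cnt

    def tumor_volume(self, state: SimState) -> float:
        """Full-sphere tumor volume, the lumped integral of eps*S_t (m^3)."""
        _, g, _ = self._metric()
        Vloc = self._lumped_weights(g)
        integral = float((Vloc * state.eps_s * self.storage_saturation(state)).sum())
        return 4.0 * np.pi * integral if self.geometry == "spherical" else integral

    def mcts_radius(self, state: SimState) -> float:
        """Outermost radius where S_t >= half its maximum.

        Uses the one-sided (element-local maximum) nodal projection so a
        node on the tissue/shell interface carries the tissue-side
        saturation; plain averaging would halve it and keep the detected
        front permanently short of the wall.
        """
        arr_s = self.storage_saturation(state)
        s = np.zeros(self.n_s)
        np.maximum.at(s, self.S.elem_dofs, arr_s)
        r = self.S.node_coords()
        thresh = 0.5 * s.max()
        if s.max() <= 0:
            return 0.0
        above = np.flatnonzero(s >= thresh)
        i = above[-1]
        if i == len(s) - 1:
            return float(r[-1])
        s0, s1 = s[i], s[i + 1]
        frac = (thresh - s0) / (s1 - s0) if s1 != s0 else 0.0
        return float(r[i] + frac * (r[i + 1] - r[i]))


def _seed_profile(r: np.ndarray, R_seed: float, width: float) -> np.ndarray:
    """Smoothed indicator of the initial spheroid: 1 in the core, cosine
    ramp to 0 over ``width`` ending at R_seed."""
    inner = R_seed - width
    x = np.clip((r - inner) / max(width, 1e-12), 0.0, 1.0)
    return 0.5 + 0.5 * np.cos(np.pi * x)


def _saturation_smooth(p_tl: np.ndarray, omega_Nt: np.ndarray, a: float,
                       rel_width: float = 1e-4) -> np.ndarray:
    """Saturation closure with a softplus-smoothed clamp at p_tl = 0.

    Identical to the piecewise law away from the origin; the C-infinity
    rounding over a width of ``rel_width * a`` (fractions of a pascal)
    keeps the Newton iteration quadratically convergent at the cell
    front, where the exact clamp has a derivative jump.
    """
    w = rel_width * a
    p_eff = w * np.logaddexp(0.0, p_tl / w)
    return (2.0 / np.pi) * np.arctan(p_eff / ((1.0 - omega_Nt) * a))


def _necrosis_backward_euler(w_old: np.ndarray, dt: float, g: np.ndarray,
                             c: np.ndarray) -> np.ndarray:
    """Implicit update of d(omega_Nt)/dt = g (1-w) - c w (1-w).

    ``g`` is the specific necrosis rate (gamma_Nt/rho_t)(1 - Htilde),
    ``c`` the dilution rate by growth; the backward-Euler equation is
    quadratic in the new value and solved in closed form (stable root
    in [0, 1)).
    """
    A = dt * c
    B = -(1.0 + dt * g + dt * c)
    C = w_old + dt * g
    disc = np.maximum(B * B - 4.0 * A * C, 0.0)
    denom = -B + np.sqrt(disc)
    small = A < 1e-14
    w = np.where(small, C / np.maximum(-B, 1e-300), 2.0 * C / np.maximum(denom, 1e-300))
    return np.clip(w, 0.0, 1.0 - 1e-9)


# ---------------------------------------------------------------------------
# Spec-level operations


def initialize_state(domain: DomainSpec, disc: Discretization,
                     params: ModelParameters, **kw) -> tuple[ForwardModel, SimState]:
    """Build the forward model for a domain and its initial state."""
    model = ForwardModel.from_domain(domain, disc, params, **kw)
    return model, model.initial_state()


def assemble_residual(model: ForwardModel, X: np.ndarray, state: SimState,
                      dt: float) -> np.ndarray:
    """Weak-form residual for unknown vector X about ``state``."""
    return model.residual(X, state, dt)


def advance_step(model: ForwardModel, state: SimState,
                 dt: float | None = None) -> tuple[SimState, dict]:
    """Advance one time step with Newton; dt defaults to the base step."""
    return model.step(state, dt if dt is not None else model.disc.dt)


def _snapshot(model: ForwardModel, state: SimState) -> dict:
    cl_par = model.params.cell_line
    S_t = model.nodal_saturation(state)
    snap = {
        "time_s": state.t,
        "r_m": model.S.node_coords().copy(),
        "r_u_m": model.U.node_coords().copy(),
        "u_m": state.u.copy(),
        "p_l": state.p_l.copy(),
        "p_tl": state.p_tl.copy(),
        "omega_nl": state.w.copy(),
        "S_t": S_t,
        "omega_Nt": model.storage_to_nodes(state.omega_Nt_s),
        "omega_grow": cl.growing_fraction(state.w, S_t, cl_par),
        "eps": model.storage_to_nodes(state.eps_s),
    }
    return snap


def run_simulation(
    domain: DomainSpec,
    disc: Discretization,
    params: ModelParameters,
    *,
    snapshot_every: int = 20,
    t_end_after_confluence: float | None = None,
    model_kw: dict | None = None,
) -> SimulationResult:
    """Run a free or encapsulated growth simulation.

    ``t_end_after_confluence`` (seconds), when given, stops the run that
    long after the tumor front reaches the capsule inner wall; the
    discretization ``t_end`` then acts as a hard ceiling.
    """
    model = ForwardModel.from_domain(domain, disc, params, **(model_kw or {}))
    state = model.initial_state()
    i_in = int(np.argmin(np.abs(model.mesh.vertices0 - domain.R_in)))
    i_out = int(np.argmin(np.abs(model.mesh.vertices0 - domain.R_out))) \
        if domain.encapsulated else i_in

    rows: list[dict] = []
    snapshots = [_snapshot(model, state)]
    confluence_t = float("nan")
    status = "ok"
    dt = disc.dt
    dt_floor = disc.dt / 2 ** disc.max_dt_halvings
    t_end = disc.t_end
    n_done = 0
    rows.append(_series_row(model, state, domain, i_in, i_out, {}))
    while state.t < t_end - 1e-6:
        dt_try = min(dt, t_end - state.t)
        try:
            new_state, diag = model.step(state, dt_try)
        except NewtonError as err:
            if dt_try / 2 < dt_floor:
                status = f"partial: {err}"
                warnings.warn(f"stopping early: {err}")
                break
            dt = dt_try / 2
            continue
        state = new_state
        n_done += 1
        if dt < disc.dt:
            dt = min(disc.dt, 2 * dt)
        rows.append(_series_row(model, state, domain, i_in, i_out, diag))
        if domain.encapsulated and np.isnan(confluence_t):
            if model.mcts_radius(state) >= model.mesh.vertices[i_in] * (1 - 1e-12):
                # interpolate the exact front/wall crossing between steps
                f_now = rows[-1]["R_mcts_m"] - rows[-1]["R_in_m"]
                f_prev = rows[-2]["R_mcts_m"] - rows[-2]["R_in_m"] \
                    if len(rows) > 1 else f_now
                if f_now > f_prev and f_prev < 0:
                    frac = -f_prev / (f_now - f_prev)
                else:
                    frac = 1.0
                t_prev = rows[-2]["time_s"] if len(rows) > 1 else state.t
                confluence_t = t_prev + frac * (state.t - t_prev)
                if t_end_after_confluence is not None:
                    t_end = min(t_end, confluence_t + t_end_after_confluence)
        if n_done % snapshot_every == 0:
            snapshots.append(_snapshot(model, state))
    if snapshots[-1]["time_s"] < state.t:
        snapshots.append(_snapshot(model, state))
    series = pd.DataFrame(rows)
    return SimulationResult(
        series=series,
        snapshots=snapshots,
        confluence_time_s=confluence_t,
        status=status,
        R_in0_m=domain.R_in if domain.encapsulated else float("nan"),
        R_out0_m=domain.R_out if domain.encapsulated else float("nan"),
        encapsulated=domain.encapsulated,
    )


def _series_row(model: ForwardModel, state: SimState, domain: DomainSpec,
                i_in: int, i_out: int, diag: dict) -> dict:
    v = model.mesh.vertices
    return {
        "time_s": state.t,
        "V_tumor_m3": model.tumor_volume(state),
        "R_mcts_m": model.mcts_radius(state),
        "R_in_m": v[i_in] if domain.encapsulated else float("nan"),
        "R_out_m": v[i_out] if domain.encapsulated else float("nan"),
        "p_t_wall_Pa": diag.get("p_t_wall", float("nan")),
        "p_s_wall_Pa": diag.get("p_s_wall", float("nan")),
        "sigma_rr_wall_Pa": diag.get("sigma_rr_wall", float("nan")),
        "p_l_min_Pa": float(state.p_l.min()),
        "p_l_max_Pa": float(state.p_l.max()),
        "omega_center": float(state.w[0]),
        "newton_iters": diag.get("newton_iters", 0),
        "mass_budget_cell": diag.get("mass_budget_cell", 0.0),
        "mass_budget_total": diag.get("mass_budget_total", 0.0),
    }


def probe_radial(result: SimulationResult, time: float, field: str,
                 radii: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Sample a snapshot field along the radius at the given time.

    Returns (radii, values) using linear interpolation between nodes of
    the snapshot whose time is nearest to ``time``.
    """
    times = np.array([s["time_s"] for s in result.snapshots])
    if not (times.min() - 1e-9 <= time <= times.max() + 1e-9):
        raise ValueError(
            f"time {time} outside snapshot range [{times.min()}, {times.max()}]"
        )
    snap = result.snapshots[int(np.argmin(np.abs(times - time)))]
    if field == "u_s":
        r, vals = snap["r_u_m"], snap["u_m"]
    elif field in snap and field not in ("time_s", "r_m", "r_u_m", "u_m"):
        r, vals = snap["r_m"], snap[field]
    else:
        available = sorted(set(_SNAPSHOT_FIELDS) | {"u_s"})
        raise KeyError(f"unknown field {field!r}; available: {available}")
    if radii is None:
        return r.copy(), np.asarray(vals).copy()
    radii = np.asarray(radii, dtype=float)
    return radii, np.interp(radii, r, vals)
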