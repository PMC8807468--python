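"""Vectorized P1 (linear triangle) finite-element kernels.

All operators are rebuilt from the mesh's *current* coordinates, so ALE
motion amounts to moving nodes and calling :meth:`P1Operators.rebuild`.
Mass is lumped throughout (row-sum), which keeps explicit updates diagonal
and the implicit velocity system symmetric positive definite.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import Mesh


class P1Operators:
    """Geometric quantities and discrete operators on a triangle mesh."""

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        self.rebuild()

    def rebuild(self) -> None:
        self._mass_lu = None
        mesh = self.mesh
        tris = mesh.tris
        p = mesh.nodes[tris]  # (nc, 3, 2)
        x, y = p[..., 0], p[..., 1]
        # edge vectors opposite each vertex
        bx = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
        by = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
        area2 = x[:, 0] * bx[:, 0] + x[:, 1] * bx[:, 1] + x[:, 2] * bx[:, 2]
        self.area = 0.5 * area2
        if np.any(self.area <= 0):
            raise ValueError(f"{int(np.sum(self.area <= 0))} inverted cells")
        inv = 1.0 / area2
        self.gradx = bx * inv[:, None]  # dN_i/dx per cell, (nc, 3)
        self.grady = by * inv[:, None]
        # lumped mass
        m = np.zeros(mesh.n_nodes)
        np.add.at(m, tris, (self.area / 3.0)[:, None])
        self.lumped_mass = m
        self.hcell = np.sqrt(2.0 * self.area)  # representative cell size
        # directional extents (anisotropic CFL measure)
        self.hx = x.max(axis=1) - x.min(axis=1)
        self.hy = y.max(axis=1) - y.min(axis=1)
        # boundary edge geometry
        e = mesh.edges
        d = mesh.nodes[e[:, 1]] - mesh.nodes[e[:, 0]]
        self.edge_len = np.hypot(d[:, 0], d[:, 1])
        with np.errstate(invalid="ignore", divide="ignore"):
            self.edge_normal = np.column_stack([d[:, 1], -d[:, 0]]) / self.edge_len[:, None]

    # -- evaluation ---------------------------------------------------------
    def cell_mean(self, f: np.ndarray) -> np.ndarray:
        return f[self.mesh.tris].mean(axis=1)

    def cell_grad(self, f: np.ndarray) -> np.ndarray:
        """Constant gradient of a nodal field per cell, (nc, 2)."""
        fv = f[self.mesh.tris]
        return np.stack(
            [(fv * self.gradx).sum(axis=1), (fv * self.grady).sum(axis=1)], axis=1
        )

    def velocity_gradient(self, u: np.ndarray) -> np.ndarray:
        """Per-cell velocity gradient tensor G[c, i, j] = du_i/dx_j."""
        gu = self.cell_grad(u[:, 0])
        gv = self.cell_grad(u[:, 1])
        return np.stack([gu, gv], axis=1)

    def scatter_cells(self, vals: np.ndarray) -> np.ndarray:
        """Return nodal r_i = sum_c (A_c/3) vals_c  (weak form of a
        cellwise-constant integrand against N_i)."""
        out = np.zeros(self.mesh.n_nodes)
        np.add.at(out, self.mesh.tris, (vals * self.area / 3.0)[:, None])
        return out

    def recover_nodal(self, cell_vals: np.ndarray) -> np.ndarray:
        """Area-weighted cell -> node recovery."""
        return self.scatter_cells(cell_vals) / self.lumped_mass

    # -- matrices -----------------------------------------------------------
    def stiffness(self, coef: np.ndarray | float) -> sp.csr_matrix:
        """K_ij = sum_c coef_c A_c grad N_i . grad N_j  (coef per cell)."""
        nc = self.mesh.n_cells
        coef = np.broadcast_to(np.asarray(coef, float), (nc,))
        tris = self.mesh.tris
        w = coef * self.area
        gx, gy = self.gradx, self.grady
        rows = np.repeat(tris, 3, axis=1).ravel()
        cols = np.tile(tris, (1, 3)).ravel()
        vals = (
            w[:, None, None] * (gx[:, :, None] * gx[:, None, :]
                                + gy[:, :, None] * gy[:, None, :])
        ).ravel()
        n = self.mesh.n_nodes
        return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()

    def consistent_mass(self) -> sp.csr_matrix:
        """Consistent P1 mass matrix (A/12 off-diagonal, A/6 diagonal)."""
        tris = self.mesh.tris
        rows = np.repeat(tris, 3, axis=1).ravel()
        cols = np.tile(tris, (1, 3)).ravel()
        loc = (np.ones((3, 3)) + np.eye(3)) / 12.0
        vals = (self.area[:, None, None] * loc).ravel()
        n = self.mesh.n_nodes
        return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()

    def mass_solve(self, b: np.ndarray) -> np.ndarray:
        """Solve M x = b with the consistent mass matrix (factorization
        cached until the next rebuild)."""
        if getattr(self, "_mass_lu", None) is None:
            self._mass_lu = spla.splu(self.consistent_mass().tocsc())
        return self._mass_lu.solve(b)

    def directional_stiffness(self, coef: np.ndarray | float,
                              direction: np.ndarray) -> sp.csr_matrix:
        """Streamline-diffusion matrix: sum_c coef_c A_c (d.grad N_i)(d.grad N_j)
        with d the unit direction per cell (rows of *direction*)."""
        nc = self.mesh.n_cells
        coef = np.broadcast_to(np.asarray(coef, float), (nc,))
        tris = self.mesh.tris
        gd = direction[:, 0:1] * self.gradx + direction[:, 1:2] * self.grady
        w = coef * self.area
        rows = np.repeat(tris, 3, axis=1).ravel()
        cols = np.tile(tris, (1, 3)).ravel()
        vals = (w[:, None, None] * gd[:, :, None] * gd[:, None, :]).ravel()
        n = self.mesh.n_nodes
        return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()

    # -- weak boundary integrals -------------------------------------------
    def boundary_flux_vector(self, edge_idx: np.ndarray, q: np.ndarray | float) -> np.ndarray:
        """Nodal vector of ∫_Γ q N_i ds over the listed boundary edges
        (trapezoidal: q constant per edge)."""
        out = np.zeros(self.mesh.n_nodes)
        q = np.broadcast_to(np.asarray(q, float), (len(edge_idx),))
        half = 0.5 * q * self.edge_len[edge_idx]
        np.add.at(out, self.mesh.edges[edge_idx, 0], half)
        np.add.at(out, self.mesh.edges[edge_idx, 1], half)
        return out

    def boundary_integral(self, edge_idx: np.ndarray, f: np.ndarray) -> float:
        """∫_Γ f ds for a nodal field over the listed edges."""
        e = self.mesh.edges[edge_idx]
        return float(np.sum(0.5 * (f[e[:, 0]] + f[e[:, 1]]) * self.edge_len[edge_idx]))

    def boundary_normal_flux(self, edge_idx: np.ndarray, u: np.ndarray) -> float:
        """∫_Γ u . n ds (outward normal) over the listed edges."""
        e = self.mesh.edges[edge_idx]
        un = 0.5 * (u[e[:, 0]] + u[e[:, 1]])
        n = self.edge_normal[edge_idx]
        return float(np.sum((un * n).sum(axis=1) * self.edge_len[edge_idx]))


def apply_dirichlet(A: sp.csr_matrix, b: np.ndarray, nodes: np.ndarray,
                    values: np.ndarray | float) -> sp.csr_matrix:
    """Row-replacement Dirichlet conditions; returns the modified matrix
    and updates *b* in place."""
    n = A.shape[0]
    keep = np.ones(n)
    keep[nodes] = 0.0
    A2 = (sp.diags(keep) @ A + sp.diags(1.0 - keep)).tocsr()
    b[nodes] = np.broadcast_to(np.asarray(values, float), (len(nodes),))
    return A2
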