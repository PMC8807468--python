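"""Pulsatile incompressible flow on a moving mesh with a thrombus sink.

The solver integrates the Navier-Stokes momentum balance

    rho du/dt + rho ((u - w) . grad) u = div(mu grad u) - grad p - F

with an incremental pressure-correction (projection) scheme on P1
triangles: semi-implicit viscous term, explicit convection with a
Peclet-gated upwind artificial viscosity (which vanishes on resolved
flows), and a nodally implicit treatment of the Brinkman-type thrombus
momentum sink F = k_M BP^2/(BP^2 + BP_t^2) u, which is stiff (k_M = 1e7
kg m^-3 s^-1).  ``w`` is the ALE mesh velocity; transport uses u - w.

Boundary machinery: a flat pulsatile inlet profile, a three-element
Windkessel pressure at the true-lumen outlet, and no-slip walls that track
the mesh velocity (the closed false-lumen end is an ordinary no-slip wall).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fem import P1Operators, apply_dirichlet
from .geometry import Mesh, TAG
from .rheology import FluidProperties, shear_rate_magnitude

# ---------------------------------------------------------------------------
# Inlet waveform
# ---------------------------------------------------------------------------


def _default_shape_coefficients(n_harmonics: int = 12) -> np.ndarray:
    """One-sided Fourier coefficients of the default aortic-like waveform
    shape (cycle mean exactly 1): a systolic peak near 4x the mean followed
    by a brief reverse-flow phase in early diastole."""
    theta = np.arange(4096) / 4096.0

    def bump(c: float, s: float) -> np.ndarray:
        # periodic Gaussian bump
        d = (theta - c + 0.5) % 1.0 - 0.5
        return np.exp(-0.5 * (d / s) ** 2)

    raw = 0.18 + 1.0 * bump(0.16, 0.055) - 0.25 * bump(0.36, 0.045)
    raw /= raw.mean()
    c = np.fft.rfft(raw) / len(raw)
    return c[: n_harmonics + 1]


@dataclass
class InletWaveform:
    """Periodic flow-rate waveform imposed as a flat inlet velocity profile.

    ``shape_coefficients`` are one-sided Fourier coefficients of the
    dimensionless shape s(t) with s-bar = 1, so the cycle-mean inlet
    velocity equals ``mean_velocity``.
    """

    frequency: float = 1.02  # Hz
    mean_velocity: float = 0.09  # m/s
    shape_coefficients: np.ndarray = field(default_factory=_default_shape_coefficients)

    @property
    def period(self) -> float:
        return 1.0 / self.frequency

    def shape(self, t: np.ndarray | float) -> np.ndarray | float:
        c = self.shape_coefficients
        k = np.arange(1, len(c))
        tt = np.atleast_1d(np.asarray(t, float))
        e = np.exp(2.0j * np.pi * self.frequency * np.outer(tt, k))
        out = c[0].real + 2.0 * (e @ c[1:]).real
        return float(out[0]) if np.isscalar(t) else out

    def velocity(self, t: np.ndarray | float) -> np.ndarray | float:
        return self.mean_velocity * self.shape(t)

    def flow_rate(self, t: np.ndarray | float, inlet_width: float) -> np.ndarray | float:
        """Per-unit-depth flow rate, m^2/s."""
        return self.velocity(t) * inlet_width


def inlet_velocity(t: float, waveform: InletWaveform, inlet_width: float) -> float:
    """Flat-profile inlet velocity whose integral over the inlet equals the
    instantaneous waveform flow rate."""
    return float(waveform.flow_rate(t, inlet_width) / inlet_width)


# ---------------------------------------------------------------------------
# Windkessel outlet
# ---------------------------------------------------------------------------


@dataclass
class WindkesselParams:
    """Three-element Windkessel (per unit depth in 2D): characteristic
    impedance R_c, peripheral resistance R_p, compliance C; P_wk is the
    stored (capacitor) pressure."""

    C: float = 2.0e-7  # m^2/Pa per unit depth
    R_p: float = 7.2e6  # Pa s / m^2
    R_c: float = 4.0e5  # Pa s / m^2
    P_wk: float = 1.28e4  # Pa, initial stored pressure (~96 mmHg)

    def __post_init__(self) -> None:
        if min(self.C, self.R_p, self.R_c) <= 0:
            raise ValueError("Windkessel C, R_p, R_c must all be positive")


def windkessel_step(Q_out: float, wk: WindkesselParams, dt: float) -> float:
    """Advance C dP_wk/dt = Q - P_wk/R_p exactly over *dt* (Q held constant)
    and return the outlet pressure P = P_wk + Q R_c.  Updates wk.P_wk."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    tau = wk.R_p * wk.C
    decay = np.exp(-dt / tau)
    p_inf = Q_out * wk.R_p
    wk.P_wk = p_inf + (wk.P_wk - p_inf) * decay
    return float(wk.P_wk + Q_out * wk.R_c)


# ---------------------------------------------------------------------------
# Thrombus momentum sink
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BodyForceField:
    k_M: float = 1.0e7  # kg/(m^3 s)
    BP_t: float = 20.0  # nmol/L


def fictitious_force(BP: np.ndarray | float, u: np.ndarray,
                     k_M: float = 1.0e7, BP_t: float = 20.0) -> np.ndarray:
    """Brinkman-type momentum sink F = k_M BP^2/(BP^2 + BP_t^2) u, N/m^3.

    Applied with a negative sign in the momentum balance; antiparallel to
    the local velocity, saturating at |F| = k_M |u| for BP >> BP_t."""
    BP = np.asarray(BP, float)
    coef = k_M * BP**2 / (BP**2 + BP_t**2)
    u = np.asarray(u, float)
    if u.ndim == 2 and np.ndim(coef) == 1:
        return coef[:, None] * u
    return coef * u


# ---------------------------------------------------------------------------
# Flow solver
# ---------------------------------------------------------------------------

@dataclass
class FlowState:
    """Velocity/pressure/viscosity fields on the (possibly moving) mesh."""

    u: np.ndarray  # (N, 2) m/s
    p: np.ndarray  # (N,) Pa
    w: np.ndarray  # (N, 2) mesh velocity m/s
    gamma_nodal: np.ndarray  # (N,) 1/s
    mu_nodal: np.ndarray  # (N,) Pa.s
    t: float = 0.0


class FlowSolver:
    """Projection Navier-Stokes solver on a tagged triangle mesh.

    *bc* maps tag name -> one of
      ``("wall",)``                      no-slip, velocity follows the mesh;
      ``("velocity", fn)``               Dirichlet; fn(t) -> scalar (flat,
                                         x-directed) or (u, v) tuple;
      ``("pressure", fn)``               traction/pressure outlet; fn(t) -> Pa.
    Tags absent from *bc* default to walls.
    """

    def __init__(
        self,
        mesh: Mesh,
        fluid: FluidProperties,
        bc: dict[str, tuple] | None = None,
        force: BodyForceField | None = None,
        body_accel: Callable[[float], tuple[float, float]] | None = None,
        stabilize: bool = True,
        reynolds_warn: float = 4000.0,
    ):
        self.mesh = mesh
        self.fluid = fluid
        self.force = force or BodyForceField()
        self.body_accel = body_accel
        self.stabilize = stabilize
        self.reynolds_warn = reynolds_warn
        self.ops = P1Operators(mesh)

        bc = dict(bc or {})
        present_names = [name for name, code in TAG.items()
                         if code in set(int(c) for c in np.unique(mesh.edge_tags))]
        for name in present_names:
            bc.setdefault(name, ("wall",))
        self.bc = bc

        n = mesh.n_nodes
        self.u = np.zeros((n, 2))
        self.p = np.zeros(n)
        self.w = np.zeros((n, 2))
        self.BP = np.zeros(n)
        self.t = 0.0
        self.log: dict[str, float] = {}
        self._area_prev = self.ops.area.sum()
        self._pressure_lu = None
        self._vel_cache = None
        self._mesh_version = 0
        self._classify_bc_nodes()

    # -- boundary bookkeeping ----------------------------------------------
    def _classify_bc_nodes(self) -> None:
        mesh = self.mesh
        self.vel_tags = [t for t, m in self.bc.items() if m[0] == "velocity"]
        self.wall_tags_active = [t for t, m in self.bc.items() if m[0] == "wall"]
        self.pres_tags = [t for t, m in self.bc.items() if m[0] == "pressure"]
        self.vel_nodes = {t: mesh.boundary_node_set(t) for t in self.vel_tags}
        wall_nodes = (mesh.boundary_node_set(*self.wall_tags_active)
                      if self.wall_tags_active else np.array([], np.int64))
        # wall overrides inlet at shared corners
        self.wall_nodes = wall_nodes
        self.pres_nodes = (mesh.boundary_node_set(*self.pres_tags)
                           if self.pres_tags else np.array([], np.int64))
        self.pres_nodes = np.setdiff1d(self.pres_nodes, wall_nodes)
        alln = [nodes for nodes in self.vel_nodes.values()] + [wall_nodes]
        self.dirichlet_nodes = (np.unique(np.concatenate(alln))
                                if alln else np.array([], np.int64))

    def mesh_updated(self) -> None:
        """Call after ALE node motion: rebuilds operators and factorizations."""
        self.ops.rebuild()
        self._pressure_lu = None
        self._vel_cache = None
        self._mesh_version += 1

    def _dirichlet_values(self, t: float) -> np.ndarray:
        vals = np.zeros((self.mesh.n_nodes, 2))
        for tag in self.vel_tags:
            fn = self.bc[tag][1]
            v = fn(t) if callable(fn) else fn
            if np.isscalar(v):
                v = (v, 0.0)
            vals[self.vel_nodes[tag]] = v
        vals[self.wall_nodes] = self.w[self.wall_nodes]
        return vals

    # -- state views ---------------------------------------------------------
    def state(self) -> FlowState:
        G = self.ops.velocity_gradient(self.u)
        gamma_c = shear_rate_magnitude(G)
        gamma_n = self.ops.recover_nodal(gamma_c)
        mu_n = np.asarray(self.fluid.viscosity(gamma_n), float)
        return FlowState(self.u.copy(), self.p.copy(), self.w.copy(),
                         gamma_n, mu_n, self.t)

    def boundary_flow(self, *tags: str) -> float:
        """Outward volume flux (per unit depth) through the tagged facets."""
        idx = self.mesh.edges_with_tag(*tags)
        return self.ops.boundary_normal_flux(idx, self.u)

    # -- time step -----------------------------------------------------------
    def step(self, dt: float) -> None:
        if dt <= 0:
            raise ValueError("dt must be positive")
        ops, rho = self.ops, self.fluid.density
        t_new = self.t + dt

        G = ops.velocity_gradient(self.u)
        gamma_c = shear_rate_magnitude(G)
        mu_c = np.asarray(self.fluid.viscosity(gamma_c), float)

        adv = ops.cell_mean(self.u[:, 0] - self.w[:, 0]), \
            ops.cell_mean(self.u[:, 1] - self.w[:, 1])
        speed = np.hypot(adv[0], adv[1])
        nu_c = mu_c / rho

        m = ops.lumped_mass
        sink = self.force.k_M * self.BP**2 / (self.BP**2 + self.force.BP_t**2) / rho
        bp_stamp = (float(self.BP.sum()), float(np.dot(self.BP, self.BP)))
        cache_ok = (self.fluid.constant_viscosity is not None
                    and not self.stabilize)
        key = (dt, self._mesh_version, bp_stamp)
        if cache_ok and self._vel_cache is not None and self._vel_cache[0] == key:
            lu_vel = self._vel_cache[1]
        else:
            K = ops.stiffness(mu_c / rho)
            if self.stabilize:
                # streamline-only upwind diffusion: treated implicitly it
                # renders the explicit central advection stable for CFL <= 1
                # and adds nothing in developed channel flow (d2u/dx2 = 0)
                h = ops.hcell
                nu_sd = 0.5 * speed * h
                with np.errstate(invalid="ignore", divide="ignore"):
                    dirs = np.column_stack([adv[0], adv[1]]) / (speed[:, None] + 1e-300)
                    K = K + ops.directional_stiffness(nu_sd, dirs)
            A = sp.diags(m * (1.0 / dt + sink)) + K
            A_bc = apply_dirichlet(A, np.zeros(self.mesh.n_nodes),
                                   self.dirichlet_nodes, 0.0)
            lu_vel = spla.splu(A_bc.tocsc())
            if cache_ok:
                self._vel_cache = (key, lu_vel)

        conv_x = ops.scatter_cells(adv[0] * G[:, 0, 0] + adv[1] * G[:, 0, 1])
        conv_y = ops.scatter_cells(adv[0] * G[:, 1, 0] + adv[1] * G[:, 1, 1])
        gp = ops.cell_grad(self.p)
        gpx = ops.scatter_cells(gp[:, 0]) / rho
        gpy = ops.scatter_cells(gp[:, 1]) / rho
        bx = m * self.u[:, 0] / dt - conv_x - gpx
        by = m * self.u[:, 1] / dt - conv_y - gpy
        if self.body_accel is not None:
            gx, gy = self.body_accel(t_new)
            bx += m * gx
            by += m * gy

        dvals = self._dirichlet_values(t_new)
        bx[self.dirichlet_nodes] = dvals[self.dirichlet_nodes, 0]
        by[self.dirichlet_nodes] = dvals[self.dirichlet_nodes, 1]
        ustar = np.column_stack([lu_vel.solve(bx), lu_vel.solve(by)])

        # pressure increment
        if self._pressure_lu is None:
            L = ops.stiffness(1.0)
            rhs_probe = np.zeros(self.mesh.n_nodes)
            if len(self.pres_nodes):
                L = apply_dirichlet(L, rhs_probe, self.pres_nodes, 0.0)
            else:  # pin one node against the pressure nullspace
                L = apply_dirichlet(L, rhs_probe, np.array([0]), 0.0)
            self._pressure_L = L
            self._pressure_lu = spla.splu(L.tocsc())
        div_c = (ops.cell_grad(ustar[:, 0])[:, 0]
                 + ops.cell_grad(ustar[:, 1])[:, 1])
        rhs_p = -(rho / dt) * ops.scatter_cells(div_c)
        if len(self.pres_nodes):
            pset = np.zeros(self.mesh.n_nodes)
            for tag in self.pres_tags:
                fn = self.bc[tag][1]
                val = fn(t_new) if callable(fn) else fn
                pset[self.mesh.boundary_node_set(tag)] = val
            rhs_p[self.pres_nodes] = pset[self.pres_nodes] - self.p[self.pres_nodes]
        else:
            rhs_p[0] = 0.0
        phi = self._pressure_lu.solve(rhs_p)

        gphi = ops.cell_grad(phi)
        self.u = ustar - (dt / rho) * np.column_stack(
            [ops.scatter_cells(gphi[:, 0]) / m, ops.scatter_cells(gphi[:, 1]) / m]
        )
        self.u[self.dirichlet_nodes] = dvals[self.dirichlet_nodes]
        self.p = self.p + phi
        self.t = t_new

        # diagnostics
        area = ops.area.sum()
        q_net = self.boundary_flow(*[t for t in self.bc])
        dvdt = (area - self._area_prev) / dt
        self._area_prev = area
        umax = float(np.max(np.hypot(self.u[:, 0], self.u[:, 1]), initial=0.0))
        hmin = float(ops.hcell.min())
        self.log = {
            "t": self.t,
            "cfl": umax * dt / hmin,
            "umax": umax,
            "mass_residual": abs(q_net - dvdt) / max(abs(q_net), 1e-12),
            "net_outflow": q_net,
            "kinetic_energy": float(0.5 * rho * np.sum(
                m * (self.u[:, 0] ** 2 + self.u[:, 1] ** 2))),
        }
        if not np.isfinite(umax) or umax > 1e3:
            raise FloatingPointError(
                f"flow solve diverged: max|u| = {umax:.3g} m/s at t = {self.t:.4g} s "
                f"(CFL = {self.log['cfl']:.3g})"
            )

    # -- wall shear stress ----------------------------------------------------
    def wall_shear_stress(self, edge_idx: np.ndarray) -> np.ndarray:
        """Per-facet WSS magnitude (Pa) on the listed boundary facets, by
        one-sided quadratic extrapolation of the tangential velocity along
        the precomputed wall-normal node stencils (exact for parabolic
        profiles)."""
        return wall_shear_stress(self, edge_idx)


class WallShearEvaluator:
    """Vectorized WSS on a fixed set of boundary facets.

    For each facet endpoint the tangential velocity is sampled at the wall
    node and two interior nodes along the precomputed wall-normal stencil;
    the wall-normal derivative is the slope at the wall of the quadratic
    through the three samples (exact for parabolic profiles).  Facet WSS is
    the endpoint average, with the viscosity evaluated at the recovered
    wall shear rate."""

    def __init__(self, solver: "FlowSolver", edge_idx: np.ndarray):
        self.solver = solver
        self.edge_idx = np.asarray(edge_idx, np.int64)
        mesh = solver.mesh
        ends = mesh.edges[self.edge_idx]  # (ne, 2)
        sten = np.zeros((len(ends), 2, 3), np.int64)
        have = np.zeros((len(ends), 2), bool)
        for r, (a, b) in enumerate(ends):
            for c, n in enumerate((int(a), int(b))):
                st = mesh.wall_stencils.get(n)
                if st is not None:
                    sten[r, c] = st
                    have[r, c] = True
        self.sten = sten
        self.have = have

    def __call__(self) -> np.ndarray:
        solver, mesh = self.solver, self.solver.mesh
        x = mesh.nodes
        ends = mesh.edges[self.edge_idx]
        d = x[ends[:, 1]] - x[ends[:, 0]]
        tang = d / np.hypot(d[:, 0], d[:, 1])[:, None]
        out = np.zeros((len(ends), 2))
        for c in (0, 1):
            s = self.sten[:, c, :]  # (ne, 3)
            p0, p1, p2 = x[s[:, 0]], x[s[:, 1]], x[s[:, 2]]
            d1 = np.hypot(*(p1 - p0).T)
            d2 = np.hypot(*(p2 - p0).T)
            f = np.einsum("nkj,nj->nk", solver.u[s], tang)  # (ne, 3)
            dudn = (-(d1 + d2) / (d1 * d2) * f[:, 0]
                    + d2 / (d1 * (d2 - d1)) * f[:, 1]
                    - d1 / (d2 * (d2 - d1)) * f[:, 2])
            dudn = np.where(self.have[:, c], dudn, 0.0)
            mu_w = np.asarray(solver.fluid.viscosity(np.abs(dudn)), float)
            out[:, c] = np.abs(mu_w * dudn)
        return out.mean(axis=1)


def wall_shear_stress(solver: FlowSolver, edge_idx: np.ndarray) -> np.ndarray:
    key = np.asarray(edge_idx, np.int64).tobytes()
    cache = getattr(solver, "_wss_cache", None)
    if cache is None:
        cache = solver._wss_cache = {}
    ev = cache.get(key)
    if ev is None:
        ev = cache[key] = WallShearEvaluator(solver, edge_idx)
    return ev()
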