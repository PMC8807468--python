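"""Four-species shear-driven thrombosis model.

Species and their transport:

* resting platelets RP (relative units)    — advected + diffusing + reacting
* activated platelets AP (relative units)  — advected + diffusing + reacting
* coagulant C (nmol/L)                     — diffusion only (never advected),
                                             with a shear-gated diffusivity
                                             D_C = D_C_base * phi_gamma
* bound platelets BP (nmol/L)              — immobile (local ODE only);
                                             BP is the growing thrombus.

Reactions (source terms):

    S_RP = k_RP [AP][RP]                                (k_RP < 0)
    S_AP = k_AP [AP][RP]
    S_C  = k_C1 phi_C(BP) [AP] + k_C2 phi_C(C) [AP] (1 - phi_gamma)
    S_BP = k_BP phi_BP(AP, C) phi_gamma [AP]            (>= 0: no lysis)

with sigmoid switches phi(x) = x^2/(x^2 + x_t^2) (products for multi-argument
switches) and the shear switch phi_gamma = gamma_t^2/(gamma^2 + gamma_t^2).
The shear switch is implemented in this dimensionally consistent quadratic
form (the half-point sits exactly at gamma = gamma_t = 50 1/s); a
``literal_shear_switch`` option restores the mixed-units linear-denominator
variant for sensitivity checks.

Coagulant enters the domain only through a wall flux of magnitude k_c_wall
on facets whose previous-cycle TAWSS is below 0.15 Pa while local BP is
still below BP_t; the cascade cannot self-start without it.

Advection of RP/AP uses a two-step Taylor-Galerkin (Lax-Wendroff) scheme,
second order on smooth fields, with positivity clipping (logged).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fem import P1Operators
from .geometry import TAG, Mesh

REACTIVE_WALL_TAGS = ("outer_wall", "fl_endwall", "flap_tl_side",
                      "flap_fl_side", "tear_edge")


@dataclass(frozen=True)
class ThrombosisParams:
    """Kinetic constants, diffusivities and thresholds of the model."""

    D_RP: float = 1.6e-13  # m^2/s
    D_AP: float = 1.6e-11  # m^2/s
    D_C_base: float = 1.0e-8  # m^2/s, multiplied by phi_gamma
    k_RP: float = -0.15  # 1/s
    k_AP: float = 3.0  # 1/s
    k_C1: float = 16.0  # nmol/(L s)
    k_C2: float = -6.0  # nmol/(L s)
    k_BP: float = 12.0  # nmol/(L s)
    k_c_wall: float = 16.0  # nmol/(L m s), coagulant wall influx
    gamma_t: float = 50.0  # 1/s
    AP_t: float = 15.0  # relative
    C_t: float = 10.0  # nmol/L
    BP_t: float = 20.0  # nmol/L
    tawss_threshold: float = 0.15  # Pa
    wall_value: float = 2.0  # relative RP/AP wall concentration
    inlet_value: float = 1.0  # relative RP/AP at the inflow
    literal_shear_switch: bool = False

    def __post_init__(self) -> None:
        for name in ("D_RP", "D_AP", "D_C_base"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("gamma_t", "AP_t", "C_t", "BP_t", "tawss_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.k_RP >= 0 or self.k_C2 >= 0:
            raise ValueError("k_RP and k_C2 must be negative")
        if self.k_AP <= 0 or self.k_C1 <= 0 or self.k_BP <= 0:
            raise ValueError("k_AP, k_C1 and k_BP must be positive")


def switching(x: np.ndarray | float, x_t: float) -> np.ndarray | float:
    """Sigmoid switch x^2/(x^2 + x_t^2) in [0, 1); 0.5 at x = x_t."""
    x = np.asarray(x, float)
    out = x**2 / (x**2 + x_t**2)
    return float(out) if out.ndim == 0 else out


def shear_switch(gamma: np.ndarray | float, gamma_t: float,
                 literal: bool = False) -> np.ndarray | float:
    """Shear-gating coefficient: 1 at rest, 0.5 at gamma_t, -> 0 at high
    shear.  ``literal=True`` uses the linear-denominator variant
    gamma_t^2/(gamma + gamma_t^2)."""
    g = np.asarray(gamma, float)
    if literal:
        out = gamma_t**2 / (g + gamma_t**2)
    else:
        out = gamma_t**2 / (g**2 + gamma_t**2)
    return float(out) if out.ndim == 0 else out


def phi_BP(AP: np.ndarray | float, C: np.ndarray | float,
           params: ThrombosisParams) -> np.ndarray | float:
    """Product switch gating thrombus deposition on AP and C levels."""
    return switching(AP, params.AP_t) * switching(C, params.C_t)


def source_terms(RP, AP, C, BP, phi_gamma, params: ThrombosisParams):
    """Reaction source terms (S_RP, S_AP, S_C, S_BP)."""
    apr = np.asarray(AP, float) * np.asarray(RP, float)
    S_RP = params.k_RP * apr
    S_AP = params.k_AP * apr
    S_C = (params.k_C1 * switching(BP, params.BP_t) * AP
           + params.k_C2 * switching(C, params.C_t) * AP * (1.0 - phi_gamma))
    S_BP = params.k_BP * phi_BP(AP, C, params) * phi_gamma * AP
    return S_RP, S_AP, S_C, S_BP


def coagulant_flux(tawss: np.ndarray | float, BP: np.ndarray | float,
                   params: ThrombosisParams) -> np.ndarray | float:
    """Inward coagulant wall-flux magnitude: k_c_wall where the facet's
    previous-cycle TAWSS < 0.15 Pa AND local BP < BP_t, else zero."""
    on = (np.asarray(tawss, float) < params.tawss_threshold) \
        & (np.asarray(BP, float) < params.BP_t)
    out = np.where(on, params.k_c_wall, 0.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class SpeciesState:
    """Nodal concentration fields."""

    RP: np.ndarray
    AP: np.ndarray
    C: np.ndarray
    BP: np.ndarray

    @classmethod
    def initial(cls, n: int) -> "SpeciesState":
        """Fresh blood: RP = AP = 1 (relative), C = BP = 0."""
        return cls(np.ones(n), np.ones(n), np.zeros(n), np.zeros(n))

    def copy(self) -> "SpeciesState":
        return SpeciesState(self.RP.copy(), self.AP.copy(),
                            self.C.copy(), self.BP.copy())


@dataclass
class CycleLedger:
    """Per-cycle accumulators and the published previous-cycle averages.

    The TAWSS used to gate the coagulant wall flux during cycle n is the
    one published at the end of cycle n-1.  Before the first completed
    cycle the flux is disabled (TAWSS treated as +inf).
    """

    n_edges: int
    n_nodes: int
    cycle_index: int = 0
    tawss_prev: np.ndarray = None  # type: ignore[assignment]
    gamma_avg: np.ndarray = None  # type: ignore[assignment]
    ap_avg: np.ndarray = None  # type: ignore[assignment]
    mu_avg: np.ndarray = None  # type: ignore[assignment]
    _wss_acc: np.ndarray = None  # type: ignore[assignment]
    _gamma_acc: np.ndarray = None  # type: ignore[assignment]
    _ap_acc: np.ndarray = None  # type: ignore[assignment]
    _mu_acc: np.ndarray = None  # type: ignore[assignment]
    _t_acc: float = 0.0
    volume_trace: list = field(default_factory=list)  # (t, cm^3, FL fraction)

    def __post_init__(self) -> None:
        self.tawss_prev = np.full(self.n_edges, np.inf)
        self.gamma_avg = np.zeros(self.n_nodes)
        self.ap_avg = np.zeros(self.n_nodes)
        self.mu_avg = np.zeros(self.n_nodes)
        self.reset_accumulators()

    def reset_accumulators(self) -> None:
        self._wss_acc = np.zeros(self.n_edges)
        self._gamma_acc = np.zeros(self.n_nodes)
        self._ap_acc = np.zeros(self.n_nodes)
        self._mu_acc = np.zeros(self.n_nodes)
        self._t_acc = 0.0

    def accumulate(self, wss_edges: np.ndarray, gamma_nodal: np.ndarray,
                   ap: np.ndarray, mu_nodal: np.ndarray, dt: float) -> None:
        self._wss_acc += np.abs(wss_edges) * dt
        self._gamma_acc += gamma_nodal * dt
        self._ap_acc += ap * dt
        self._mu_acc += mu_nodal * dt
        self._t_acc += dt

    def complete_cycle(self) -> None:
        """Publish cycle averages and swap the TAWSS gating buffer."""
        if self._t_acc <= 0:
            raise ValueError("no accumulated time in this cycle")
        self.tawss_prev = self._wss_acc / self._t_acc
        self.gamma_avg = self._gamma_acc / self._t_acc
        self.ap_avg = self._ap_acc / self._t_acc
        self.mu_avg = self._mu_acc / self._t_acc
        self.cycle_index += 1
        self.reset_accumulators()


def thrombus_mask(BP: np.ndarray, BP_t: float,
                  ops: P1Operators) -> tuple[np.ndarray, float]:
    """Nodal thrombus indicator (BP >= BP_t) and thrombus volume in cm^3
    (2D area x 1 m unit depth)."""
    ind = (np.asarray(BP, float) >= BP_t).astype(float)
    frac = ind[ops.mesh.tris].mean(axis=1)
    vol_m3 = float(np.sum(frac * ops.area))  # x 1 m depth
    return ind, vol_m3 * 1e6


class SpeciesSolver:
    """Advances the four species one flow time step (operator splitting:
    transport, then sub-stepped reactions, then boundary conditions)."""

    def __init__(self, mesh: Mesh, ops: P1Operators, params: ThrombosisParams,
                 reactive_tags: tuple[str, ...] = REACTIVE_WALL_TAGS,
                 inlet_tag: str | None = "inlet",
                 outlet_tag: str = "tl_outlet"):
        self.mesh = mesh
        self.ops = ops
        self.params = params
        present = set(int(c) for c in np.unique(mesh.edge_tags))
        self.wall_edge_idx = mesh.edges_with_tag(
            *[t for t in reactive_tags if TAG[t] in present])
        self.wall_nodes = (mesh.boundary_node_set(
            *[t for t in reactive_tags if TAG[t] in present])
            if len(self.wall_edge_idx) else np.array([], np.int64))
        self.inlet_nodes = (mesh.boundary_node_set(inlet_tag)
                            if inlet_tag is not None and TAG[inlet_tag] in present
                            else np.array([], np.int64))
        self.inlet_nodes = np.setdiff1d(self.inlet_nodes, self.wall_nodes)
        self.clip_events = 0

    # -- boundary conditions -------------------------------------------------
    def apply_species_bcs(self, species: SpeciesState, ledger: CycleLedger) -> np.ndarray:
        """Apply RP/AP Dirichlet walls and inlet values in place; return the
        assembled nodal coagulant wall-flux vector (weak-form units)."""
        p = self.params
        species.RP[self.wall_nodes] = p.wall_value
        species.AP[self.wall_nodes] = p.wall_value
        species.RP[self.inlet_nodes] = p.inlet_value
        species.AP[self.inlet_nodes] = p.inlet_value
        e = self.mesh.edges[self.wall_edge_idx]
        bp_edge = 0.5 * (species.BP[e[:, 0]] + species.BP[e[:, 1]])
        q = coagulant_flux(ledger.tawss_prev[self.wall_edge_idx], bp_edge, p)
        return self.ops.boundary_flux_vector(self.wall_edge_idx, q)

    # -- transport -----------------------------------------------------------
    def _advect_tg(self, c: np.ndarray, adv_cell: np.ndarray,
                   dt: float) -> np.ndarray:
        """One-step Taylor-Galerkin (Lax-Wendroff FEM) advection increment:
        M dc = dt [ -int N_i (a.grad c) - (dt/2) int (a.grad N_i)(a.grad c) ].
        Consistent mass gives the scheme its third-order phase accuracy;
        inflow boundaries are closed by the Dirichlet values applied after
        the step."""
        ops = self.ops
        g = ops.cell_grad(c)
        adv_g = adv_cell[:, 0] * g[:, 0] + adv_cell[:, 1] * g[:, 1]  # (a.grad c)_c
        r = -ops.scatter_cells(adv_g)
        # Lax-Wendroff correction term, assembled directly
        w = 0.5 * dt * ops.area * adv_g
        contrib = (w * adv_cell[:, 0])[:, None] * ops.gradx \
            + (w * adv_cell[:, 1])[:, None] * ops.grady
        np.add.at(r, self.mesh.tris, -contrib)
        return dt * ops.mass_solve(r)

    def step(self, species: SpeciesState, u: np.ndarray, w: np.ndarray,
             gamma_nodal: np.ndarray, ledger: CycleLedger, dt: float) -> SpeciesState:
        """One species step: RP/AP advect-diffuse, C diffuses (gated
        diffusivity, wall flux), BP stays put; then reactions; then BCs."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        p, ops = self.params, self.ops
        s = species.copy()

        adv = np.column_stack([ops.cell_mean(u[:, 0] - w[:, 0]),
                               ops.cell_mean(u[:, 1] - w[:, 1])])

        # advection substeps under a CFL-0.4 cap (directional: the mesh is
        # strongly anisotropic in the flap band)
        cfl_rate = np.abs(adv[:, 0]) / ops.hx + np.abs(adv[:, 1]) / ops.hy
        cfl = float(np.max(cfl_rate, initial=0.0)) * dt
        nsub = max(1, int(np.ceil(cfl / 0.4)))
        dts = dt / nsub
        for _ in range(nsub):
            s.RP = s.RP + self._advect_tg(s.RP, adv, dts)
            s.AP = s.AP + self._advect_tg(s.AP, adv, dts)

        # diffusion (explicit; diffusivities are small)
        gamma_cell = ops.cell_mean(gamma_nodal)
        phi_g_cell = shear_switch(gamma_cell, p.gamma_t, p.literal_shear_switch)
        flux_vec = self.apply_species_bcs(s, ledger)  # also sets RP/AP Dirichlet
        if p.D_RP > 0:
            s.RP -= dt * (ops.stiffness(p.D_RP) @ s.RP) / ops.lumped_mass
        if p.D_AP > 0:
            s.AP -= dt * (ops.stiffness(p.D_AP) @ s.AP) / ops.lumped_mass
        D_C = p.D_C_base * phi_g_cell
        s.C = s.C + dt * (flux_vec - ops.stiffness(D_C) @ s.C) / ops.lumped_mass

        # reactions: nodal RK4, sub-stepped
        phi_g = shear_switch(gamma_nodal, p.gamma_t, p.literal_shear_switch)
        nrk = max(1, int(np.ceil(dt / 0.05)))
        h = dt / nrk

        def rates(rp, ap, c, bp):
            return source_terms(rp, ap, c, bp, phi_g, p)

        rp, ap, c, bp = s.RP, s.AP, s.C, s.BP
        for _ in range(nrk):
            k1 = rates(rp, ap, c, bp)
            k2 = rates(rp + 0.5 * h * k1[0], ap + 0.5 * h * k1[1],
                       c + 0.5 * h * k1[2], bp + 0.5 * h * k1[3])
            k3 = rates(rp + 0.5 * h * k2[0], ap + 0.5 * h * k2[1],
                       c + 0.5 * h * k2[2], bp + 0.5 * h * k2[3])
            k4 = rates(rp + h * k3[0], ap + h * k3[1],
                       c + h * k3[2], bp + h * k3[3])
            rp = rp + (h / 6) * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            ap = ap + (h / 6) * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            c = c + (h / 6) * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
            bp = bp + (h / 6) * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
        s.RP, s.AP, s.C, s.BP = rp, ap, c, bp

        # re-impose boundary values after transport+reaction
        s.RP[self.wall_nodes] = p.wall_value
        s.AP[self.wall_nodes] = p.wall_value
        s.RP[self.inlet_nodes] = p.inlet_value
        s.AP[self.inlet_nodes] = p.inlet_value

        # positivity: mass-conserving clip (negatives zeroed, positive part
        # rescaled so the lumped-mass integral is unchanged); events logged.
        # BP is monotone by construction but guard it against regression.
        m = ops.lumped_mass
        for name in ("RP", "AP", "C"):
            f = getattr(s, name)
            neg = f < 0
            if np.any(neg):
                self.clip_events += int(neg.sum())
                mass0 = float(m @ f)
                f[neg] = 0.0
                mass1 = float(m @ f)
                if mass1 > 0 and mass0 > 0:
                    f *= mass0 / mass1
        s.BP = np.maximum(s.BP, species.BP)
        if not (np.all(np.isfinite(s.RP)) and np.all(np.isfinite(s.AP))
                and np.all(np.isfinite(s.C)) and np.all(np.isfinite(s.BP))):
            raise FloatingPointError("species step produced non-finite values")
        return s
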