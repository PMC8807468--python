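"""Reduced-order mobile intimal flap.

The flap is modelled as a quasi-static, pressure-loaded Euler-Bernoulli
beam clamped at both ends of the dissected segment, with per-unit-depth
bending stiffness E_flap * I, I = thickness^3 / 12.  Tear gaps carry no
material: stations inside a tear are pinned at zero displacement, so each
flap segment behaves as a beam clamped/supported at the dissection ends
and the tear edges and the displacement field is continuous with w = 0
over the gaps.  Flap inertia and damping are neglected (the beam's natural
frequency at the given stiffness is far above the ~1 Hz forcing).

Stiffness presets: "flexible" (6.75 MPa), "stiffer" (60 MPa) and "rigid"
(no motion), matching the comparison scenarios the simulator is built for.
Mesh coupling is an analytic ALE column stretch: the flap band translates
with the beam, the TL and FL node columns compress/stretch linearly, and
the resulting node velocity is handed to the flow and species solvers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import Mesh, REGION_FL, REGION_FLAP, REGION_TL

E_PRESETS = {"flexible": 6.75e6, "stiffer": 60.0e6, "rigid": np.inf}


@dataclass
class FlapParams:
    """Flap stiffness and coupling controls (SI units)."""

    E_flap: float = 6.75e6  # Pa; np.inf -> rigid
    thickness: float = 0.8e-3  # m
    span: float = 0.2  # m, dissected length
    n_stations: int = 257
    displacement_cap: float | None = None  # m; default 40% of narrower lumen
    under_relaxation: float = 0.5
    #: Winkler-foundation stiffness (Pa/m).  The planar beam misses the
    #: flap's circumferential attachment; a foundation k_s = 384 E I / b^4
    #: (plate bending across the transverse span b) restores that restoring
    #: force and keeps the quasi-static response E-dependent.  Zero disables.
    foundation: float = 0.0

    @classmethod
    def preset(cls, name: str, **kw) -> "FlapParams":
        return cls(E_flap=E_PRESETS[name], **kw)

    @property
    def rigid(self) -> bool:
        return not np.isfinite(self.E_flap)

    @property
    def I_per_depth(self) -> float:
        return self.thickness**3 / 12.0

    def __post_init__(self) -> None:
        if not self.rigid and self.E_flap <= 0:
            raise ValueError("E_flap must be positive (or inf for rigid)")
        if not 0.0 < self.under_relaxation <= 1.0:
            raise ValueError("under_relaxation must lie in (0, 1]")


@dataclass
class FlapState:
    """Beam displacement (positive toward the FL) per axial station."""

    stations: np.ndarray  # m, measured from the proximal dissection end
    displacement: np.ndarray  # m
    velocity: np.ndarray  # m/s
    load: np.ndarray  # Pa, transmural dP = P_TL - P_FL

    @classmethod
    def zero(cls, stations: np.ndarray) -> "FlapState":
        z = np.zeros_like(stations)
        return cls(stations.copy(), z.copy(), z.copy(), z.copy())


def transmural_load(p_tl_side: np.ndarray, p_fl_side: np.ndarray,
                    stations: np.ndarray,
                    tear_intervals: list[tuple[float, float]]) -> np.ndarray:
    """Transmural pressure dP(x) = P_TL(x) - P_FL(x) per station, zeroed
    over the tear gaps (no flap material there)."""
    dp = np.asarray(p_tl_side, float) - np.asarray(p_fl_side, float)
    dp = dp.copy()
    for a, b in tear_intervals:
        dp[(stations >= a) & (stations <= b)] = 0.0
    return dp


def _beam_matrix(n: int, h: float,
                 pinned: np.ndarray) -> sp.csr_matrix:
    """Pentadiagonal clamped-clamped biharmonic operator w'''' on a uniform
    grid of n interior+boundary stations; rows in *pinned* (boolean mask,
    includes both clamped ends) are replaced by identity."""
    main = np.full(n, 6.0)
    off1 = np.full(n - 1, -4.0)
    off2 = np.full(n - 2, 1.0)
    A = sp.diags([off2, off1, main, off1, off2], [-2, -1, 0, 1, 2],
                 format="lil") / h**4
    # clamped ends: w = 0 and w' = 0 (ghost reflection on rows 1 and n-2)
    A[1, 1] += 1.0 / h**4
    A[n - 2, n - 2] += 1.0 / h**4
    A = A.tocsr()
    keep = np.ones(n)
    keep[pinned] = 0.0
    return (sp.diags(keep) @ A + sp.diags(1.0 - keep)).tocsr()


def solve_flap(load: np.ndarray, params: FlapParams,
               tear_intervals: list[tuple[float, float]] | None = None,
               stations: np.ndarray | None = None) -> FlapState:
    """Quasi-static beam deflection E I w'''' = dP(x) with clamped ends and
    pinned tear-gap stations; load in Pa (per unit depth)."""
    if stations is None:
        stations = np.linspace(0.0, params.span, params.n_stations)
    load = np.asarray(load, float)
    if load.shape != stations.shape:
        raise ValueError("load and stations must have matching shapes")
    if not np.all(np.isfinite(load)):
        raise ValueError("non-finite flap load")
    state = FlapState.zero(stations)
    state.load = load.copy()
    if params.rigid:
        return state
    n = len(stations)
    h = stations[1] - stations[0]
    pinned = np.zeros(n, bool)
    pinned[0] = pinned[-1] = True
    q = load.copy()
    for a, b in tear_intervals or []:
        gap = (stations >= a) & (stations <= b)
        pinned |= gap
        q[gap] = 0.0
    A = _beam_matrix(n, h, pinned)
    if params.foundation > 0:
        keep = np.ones(n)
        keep[pinned] = 0.0
        A = A + sp.diags(keep * params.foundation
                         / (params.E_flap * params.I_per_depth))
    rhs = q / (params.E_flap * params.I_per_depth)
    rhs[pinned] = 0.0
    w = spla.spsolve(A.tocsc(), rhs)
    w[pinned] = 0.0
    state.displacement = w
    return state


def max_flap_displacement(history: np.ndarray, stations: np.ndarray,
                          cut_positions: dict[str, float] | None = None
                          ) -> dict[str, float]:
    """Maxima of |displacement| (reported in mm) over a displacement
    history of shape (n_times, n_stations): global and at named stations."""
    history = np.atleast_2d(np.asarray(history, float))
    out = {"global": float(np.max(np.abs(history), initial=0.0) * 1e3)}
    for name, x in (cut_positions or {}).items():
        j = int(np.argmin(np.abs(stations - x)))
        out[name] = float(np.max(np.abs(history[:, j]), initial=0.0) * 1e3)
    return out


# ---------------------------------------------------------------------------
# ALE mesh motion
# ---------------------------------------------------------------------------


def flap_displacement_at(mesh: Mesh, flap: FlapState) -> np.ndarray:
    """Beam displacement interpolated to each mesh node's axial position;
    zero outside the dissected segment."""
    xd0, xd1, _ = mesh.x_marks_m
    x = mesh.ref_nodes[:, 0]
    w = np.interp(x - xd0, flap.stations, flap.displacement, left=0.0, right=0.0)
    w[(x < xd0) | (x > xd1)] = 0.0
    return w


def move_mesh(mesh: Mesh, flap: FlapState, dt: float) -> np.ndarray:
    """Apply the beam displacement to the mesh by analytic column
    stretching; returns the nodal mesh velocity w = dx/dt.

    TL columns stretch linearly between the fixed outer wall and the flap
    underside; the flap band translates; FL columns stretch between the
    flap top and the fixed outer wall.  Raises on (impossible under the
    displacement cap) cell inversion.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if mesh.y_levels_m is None:
        raise ValueError("mesh lacks band metadata (not a dissection mesh)")
    disp = flap_displacement_at(mesh, flap)
    old = mesh.nodes.copy()
    reg = mesh.node_region
    fr = mesh.node_yfrac
    # delta form relative to the reference coordinates: exact identity at
    # zero displacement (TL stretches by fr*d, flap band translates by d,
    # FL stretches by (1-fr)*d)
    dy = np.where(reg == REGION_TL, fr * disp,
                  np.where(reg == REGION_FLAP, disp, (1.0 - fr) * disp))
    ynew = mesh.ref_nodes[:, 1] + dy
    mesh.nodes = np.column_stack([mesh.ref_nodes[:, 0], ynew])
    vel = (mesh.nodes - old) / dt
    areas = mesh.signed_areas()
    if np.any(areas <= 0):
        mesh.nodes = old
        raise ValueError(
            f"mesh motion inverted {int(np.sum(areas <= 0))} cells "
            f"(max |w| = {np.max(np.abs(disp)):.3g} m)"
        )
    return vel
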