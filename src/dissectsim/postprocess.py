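"""Derived quantities: vorticity, vortex identification, cut-plane pressure
differences, thrombus growth-phase segmentation, displacement-volume
regression and cycle-averaged region summaries.

All functions are pure functions of saved state: re-running them on stored
snapshots reproduces identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .fem import P1Operators
from .geometry import Mesh

# ---------------------------------------------------------------------------
# Velocity-gradient diagnostics
# ---------------------------------------------------------------------------


def vorticity_field(ops: P1Operators, u: np.ndarray) -> np.ndarray:
    """Out-of-plane vorticity omega = dv/dx - du/dy, recovered at nodes."""
    G = ops.velocity_gradient(u)
    return ops.recover_nodal(G[:, 1, 0] - G[:, 0, 1])


def lambda2_field(ops: P1Operators, u: np.ndarray) -> np.ndarray:
    """2D vortex criterion: the lower eigenvalue of S^2 + Omega^2 per cell
    (equal to -Q in 2D for incompressible flow); negative inside vortices."""
    G = ops.velocity_gradient(u)
    S = 0.5 * (G + np.swapaxes(G, 1, 2))
    W = 0.5 * (G - np.swapaxes(G, 1, 2))
    M = np.einsum("cij,cjk->cik", S, S) + np.einsum("cij,cjk->cik", W, W)
    tr = 0.5 * (M[:, 0, 0] + M[:, 1, 1])
    det = M[:, 0, 0] * M[:, 1, 1] - M[:, 0, 1] * M[:, 1, 0]
    disc = np.sqrt(np.maximum(tr**2 - det, 0.0))
    return tr - disc  # lower eigenvalue


def vortex_regions(ops: P1Operators, u: np.ndarray,
                   threshold: float = -10.0) -> tuple[np.ndarray, list[float]]:
    """Cells with lambda2 < threshold (s^-2), grouped into edge-connected
    components.  Returns (labels per cell, -1 outside; list of region
    areas in m^2)."""
    lam = lambda2_field(ops, u)
    flagged = lam < threshold
    labels = np.full(ops.mesh.n_cells, -1, np.int64)
    idx = np.flatnonzero(flagged)
    if len(idx) == 0:
        return labels, []
    # adjacency via shared (sorted) edges among flagged cells
    tris = ops.mesh.tris[idx]
    edges = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    edges.sort(axis=1)
    owner = np.tile(np.arange(len(idx)), 3)
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    e_sorted, o_sorted = edges[order], owner[order]
    same = np.all(e_sorted[1:] == e_sorted[:-1], axis=1)
    a, b = o_sorted[:-1][same], o_sorted[1:][same]
    adj = coo_matrix((np.ones(len(a)), (a, b)), shape=(len(idx), len(idx)))
    ncomp, comp = connected_components(adj, directed=False)
    labels[idx] = comp
    areas = [float(ops.area[idx[comp == k]].sum()) for k in range(ncomp)]
    return labels, areas


# ---------------------------------------------------------------------------
# Region masks and cut planes
# ---------------------------------------------------------------------------


def region_cell_masks(mesh: Mesh, ops: P1Operators) -> dict[str, np.ndarray]:
    """Boolean cell masks for the TL, FL and flap-band (tear) regions by
    cell centroid."""
    if mesh.y_levels_m is None:
        raise ValueError("not a dissection mesh")
    _, y1, y2, _ = mesh.y_levels_m
    yc = mesh.nodes[mesh.tris][:, :, 1].mean(axis=1)
    return {"TL": yc < y1, "flap_band": (yc >= y1) & (yc <= y2), "FL": yc > y2}


@dataclass(frozen=True)
class CutPlane:
    """Named transverse cut at an axial position, restricted to one lumen."""

    name: str  # proximal | middle | distal
    x: float  # m
    lumen: str  # "TL" or "FL"


def default_cut_planes(mesh: Mesh) -> list[CutPlane]:
    """Proximal cut at the entry-tear level, distal at the re-entry level,
    middle halfway between (mirroring the reference placement scaled to
    this domain), one per lumen."""
    xd0, xd1, _ = mesh.x_marks_m
    # tear centres are 1/8 in from each end by default; recover from tags
    x = mesh.edge_midpoints()[:, 0]
    from .geometry import TAG
    tear = mesh.edge_tags == TAG["tear_edge"]
    if tear.any():
        xt = np.sort(np.unique(np.round(x[tear], 9)))
        prox = 0.5 * (xt[0] + xt[1])
        dist = 0.5 * (xt[-2] + xt[-1])
    else:
        prox, dist = xd0 + 0.125 * (xd1 - xd0), xd1 - 0.125 * (xd1 - xd0)
    mid = 0.5 * (prox + dist)
    cuts = []
    for name, xc in (("proximal", prox), ("middle", mid), ("distal", dist)):
        for lumen in ("TL", "FL"):
            cuts.append(CutPlane(name, float(xc), lumen))
    return cuts


def _cut_mean_pressure(mesh: Mesh, p: np.ndarray, cut: CutPlane) -> float:
    _, y1, y2, _ = mesh.y_levels_m
    xd0, xd1, xl = mesh.x_marks_m
    if not 0.0 <= cut.x <= xl:
        raise ValueError(f"cut plane {cut.name} at x = {cut.x} m outside domain")
    x = mesh.nodes[:, 0]
    cols = np.unique(x[np.argsort(np.abs(x - cut.x))][:1])
    on_col = np.isclose(x, cols[0])
    y = mesh.nodes[:, 1]
    in_lumen = (y < y1) if cut.lumen == "TL" else (y > y2)
    sel = on_col & in_lumen
    if not sel.any():
        raise ValueError(f"cut {cut.name}/{cut.lumen} intersects no nodes")
    return float(p[sel].mean())


def cut_plane_dp(mesh: Mesh, p: np.ndarray,
                 cuts: list[CutPlane] | None = None) -> dict[str, float]:
    """Spatially averaged pressure difference dP = mean(P_TL) - mean(P_FL)
    at each named cut location (Pa)."""
    cuts = cuts or default_cut_planes(mesh)
    by_name: dict[str, dict[str, float]] = {}
    for c in cuts:
        by_name.setdefault(c.name, {})[c.lumen] = _cut_mean_pressure(mesh, p, c)
    return {name: v["TL"] - v["FL"] for name, v in by_name.items()
            if "TL" in v and "FL" in v}


# ---------------------------------------------------------------------------
# Growth phases and regression
# ---------------------------------------------------------------------------


@dataclass
class GrowthPhases:
    lag_end: float  # s
    accelerated_end: float  # s
    plateau_value: float  # cm^3
    rates: dict  # per-phase mean growth rate, cm^3/s
    degenerate: bool = False


def growth_phase_segmentation(t: np.ndarray, volume: np.ndarray,
                              window: float | None = None,
                              rate_fraction: float = 0.1) -> GrowthPhases:
    """Segment a non-decreasing thrombus-volume trace into time-lag,
    accelerated and plateau phases.

    The lag ends when the growth rate first exceeds ``rate_fraction`` of its
    maximum; the plateau starts at the last time it falls below that level
    for good.  Rates are central differences over a one-cycle window."""
    t = np.asarray(t, float)
    v = np.asarray(volume, float)
    if np.any(np.diff(v) < -1e-9 * max(v.max(initial=0.0), 1.0)):
        raise ValueError("thrombus volume trace must be non-decreasing")
    if v.max(initial=0.0) <= 0:
        return GrowthPhases(t[-1], t[-1], 0.0, {}, degenerate=True)
    if window is None:
        window = max((t[-1] - t[0]) / 20.0, t[1] - t[0])
    rate = np.gradient(v, t)
    # smooth over the window
    nwin = max(1, int(round(window / max(t[1] - t[0], 1e-12))))
    if nwin > 1:
        kern = np.ones(nwin) / nwin
        rate = np.convolve(rate, kern, mode="same")
    rmax = rate.max()
    above = rate > rate_fraction * rmax
    if not above.any():
        return GrowthPhases(t[-1], t[-1], float(v[-1]), {}, degenerate=True)
    i0 = int(np.argmax(above))
    i1 = len(above) - 1 - int(np.argmax(above[::-1]))
    lag_end, acc_end = float(t[i0]), float(t[i1])
    rates = {}
    for name, (a, b) in (("lag", (0, i0)), ("accelerated", (i0, i1)),
                         ("plateau", (i1, len(t) - 1))):
        if b > a:
            rates[name] = float((v[b] - v[a]) / (t[b] - t[a]))
    return GrowthPhases(lag_end, acc_end, float(v[-1]), rates)


def displacement_volume_regression(points: list[tuple[float, float]]) -> dict:
    """OLS of plateau thrombus volume (cm^3) on maximum flap displacement
    (mm): slope (cm^3/mm), intercept (cm^3), R^2."""
    if len(points) < 2:
        raise ValueError("need at least two runs")
    x = np.asarray([p[0] for p in points], float)
    y = np.asarray([p[1] for p in points], float)
    if np.ptp(x) == 0:
        raise ValueError("displacements are identical; regression undefined")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "n": len(points),
        "under_determined": len(points) == 2,
    }


def field_cycle_summary(ops: P1Operators, masks: dict[str, np.ndarray],
                        fields: dict[str, np.ndarray]) -> dict[str, dict[str, float | None]]:
    """Area-weighted means of nodal *fields* over each cell-mask region.
    Empty regions report None (missing, not zero)."""
    out: dict[str, dict[str, float | None]] = {}
    for rname, mask in masks.items():
        row: dict[str, float | None] = {}
        a = ops.area[mask]
        if a.sum() <= 0:
            out[rname] = {fname: None for fname in fields}
            continue
        for fname, f in fields.items():
            cell_vals = f[ops.mesh.tris].mean(axis=1)[mask]
            row[fname] = float((cell_vals * a).sum() / a.sum())
        out[rname] = row
    return out
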