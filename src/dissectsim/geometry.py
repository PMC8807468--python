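"""Planar dissection analog geometry and structured triangle meshing.

The 3D tube-in-tube dissection is reduced to a planar two-channel analog:
a true lumen (TL) and a false lumen (FL) running in parallel, separated by
a thin intimal flap interrupted by an entry and a re-entry tear.  Channel
widths stand in for the lumen diameters.  Geometry is specified in mm;
meshes are emitted in SI metres (single explicit conversion at build time).

The mesher is a deterministic masked-structured triangulator: a tensor grid
of quads covering the bounding box is masked by the fluid region and split
into right triangles.  Boundary facets are discovered topologically and
tagged geometrically.  Because the mesh is logically structured, every
boundary node carries a wall-normal stencil (two interior nodes along its
grid line) used for second-order wall-shear recovery, and every node carries
the band metadata needed for analytic ALE column stretching when the flap
moves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

MM = 1e-3  # mm -> m

# boundary tag codes
TAGS = (
    "inlet",
    "tl_outlet",
    "fl_endwall",
    "outer_wall",
    "flap_tl_side",
    "flap_fl_side",
    "tear_edge",
)
TAG = {name: i for i, name in enumerate(TAGS)}

# node region codes (vertical band)
REGION_TL, REGION_FLAP, REGION_FL = 0, 1, 2


class InvalidGeometryError(ValueError):
    """Raised when a geometry description violates its invariants."""


@dataclass
class DissectionGeometry:
    """Dimensions of the 2D dissection analog, in mm.

    ``tl_width`` / ``fl_width`` are the channel-normal extents standing in
    for the TL / FL diameters; ``tear_length`` is the axial extent of each
    tear (the 2D analog of tear diameter).  Axial positions not printed in
    the source literature (tear centres, dissected length, extensions) are
    explicit parameters with documented defaults.
    """

    tl_width: float = 19.4
    fl_width: float = 23.0
    flap_thickness: float = 0.8
    tear_length: float = 10.0
    dissected_length: float = 200.0
    inlet_extension: float = 40.0
    outlet_extension: float = 40.0
    entry_tear_center: float | None = None
    reentry_tear_center: float | None = None

    def __post_init__(self) -> None:
        if self.entry_tear_center is None:
            self.entry_tear_center = self.inlet_extension + 25.0
        if self.reentry_tear_center is None:
            self.reentry_tear_center = (
                self.inlet_extension + self.dissected_length - 25.0
            )
        self.validate()

    # -- derived marks (mm) -------------------------------------------------
    @property
    def y_levels(self) -> tuple[float, float, float, float]:
        y1 = self.tl_width
        y2 = y1 + self.flap_thickness
        y3 = y2 + self.fl_width
        return 0.0, y1, y2, y3

    @property
    def x_marks(self) -> tuple[float, float, float]:
        xd0 = self.inlet_extension
        xd1 = xd0 + self.dissected_length
        return xd0, xd1, xd1 + self.outlet_extension

    def tear_intervals(self) -> list[tuple[float, float]]:
        h = 0.5 * self.tear_length
        return [
            (self.entry_tear_center - h, self.entry_tear_center + h),
            (self.reentry_tear_center - h, self.reentry_tear_center + h),
        ]

    def validate(self) -> None:
        lengths = {
            "tl_width": self.tl_width,
            "fl_width": self.fl_width,
            "flap_thickness": self.flap_thickness,
            "tear_length": self.tear_length,
            "dissected_length": self.dissected_length,
            "inlet_extension": self.inlet_extension,
            "outlet_extension": self.outlet_extension,
        }
        for name, val in lengths.items():
            if not np.isfinite(val) or val <= 0:
                raise InvalidGeometryError(f"{name} must be strictly positive, got {val}")
        if self.entry_tear_center >= self.reentry_tear_center:
            raise InvalidGeometryError(
                "entry_tear_center must lie proximal of reentry_tear_center "
                f"(got {self.entry_tear_center} >= {self.reentry_tear_center})"
            )
        (e0, e1), (r0, r1) = self.tear_intervals()
        if e1 > r0:
            raise InvalidGeometryError(
                f"tear intervals overlap: [{e0}, {e1}] and [{r0}, {r1}] mm"
            )
        xd0, xd1, _ = self.x_marks
        if e0 <= xd0 or r1 >= xd1:
            raise InvalidGeometryError(
                f"tears [{e0}, {e1}], [{r0}, {r1}] mm must lie strictly inside the "
                f"dissected extent ({xd0}, {xd1}) mm"
            )

    @property
    def total_height(self) -> float:
        """Channel-normal extent between outer walls, mm."""
        return self.tl_width + self.flap_thickness + self.fl_width


@dataclass
class DissectionDomain:
    """Planar domain description: fluid predicate, tagged boundary, area."""

    params: DissectionGeometry

    def fluid(self, x: float, y: float) -> bool:
        """Is (x, y) [mm] inside the fluid region?"""
        p = self.params
        _, y1, y2, y3 = p.y_levels
        xd0, xd1, xl = p.x_marks
        if 0.0 < y < y1:  # TL channel, full axial length
            return 0.0 < x < xl
        if y1 < y < y2:  # flap band: fluid only in the tears
            return any(a < x < b for a, b in p.tear_intervals())
        if y2 < y < y3:  # FL channel, dissected segment only
            return xd0 < x < xd1
        return False

    def area_mm2(self) -> float:
        p = self.params
        _, _, xl = p.x_marks
        return (
            p.tl_width * xl
            + p.fl_width * p.dissected_length
            + 2.0 * p.tear_length * p.flap_thickness
        )

    def classify_edge(self, xm: float, ym: float, horizontal: bool) -> int:
        """Tag a boundary facet by its midpoint (mm)."""
        p = self.params
        _, y1, y2, y3 = p.y_levels
        xd0, xd1, xl = p.x_marks
        tol = 1e-9
        if not horizontal:
            if abs(xm) < tol:
                return TAG["inlet"]
            if abs(xm - xl) < tol:
                return TAG["tl_outlet"]
            if y1 - tol < ym < y2 + tol:
                return TAG["tear_edge"]
            return TAG["fl_endwall"]
        # horizontal facets
        if abs(ym) < tol or abs(ym - y3) < tol:
            return TAG["outer_wall"]
        if abs(ym - y1) < tol:
            if xd0 - tol < xm < xd1 + tol:
                return TAG["flap_tl_side"]
            return TAG["outer_wall"]  # TL upper wall in the extensions
        if abs(ym - y2) < tol:
            return TAG["flap_fl_side"]
        raise InvalidGeometryError(f"unclassifiable boundary facet at ({xm}, {ym}) mm")

    def boundary_polylines(self) -> dict[str, list[np.ndarray]]:
        """Tagged boundary polylines (mm) for inspection/export."""
        p = self.params
        _, y1, y2, y3 = p.y_levels
        xd0, xd1, xl = p.x_marks
        (e0, e1), (r0, r1) = p.tear_intervals()
        seg = lambda *pts: np.asarray(pts, float)
        return {
            "inlet": [seg((0, 0), (0, y1))],
            "tl_outlet": [seg((xl, 0), (xl, y1))],
            "outer_wall": [
                seg((0, 0), (xl, 0)),
                seg((xd0, y3), (xd1, y3)),
                seg((0, y1), (xd0, y1)),
                seg((xd1, y1), (xl, y1)),
            ],
            "fl_endwall": [seg((xd0, y2), (xd0, y3)), seg((xd1, y2), (xd1, y3))],
            "flap_tl_side": [
                seg((xd0, y1), (e0, y1)),
                seg((e1, y1), (r0, y1)),
                seg((r1, y1), (xd1, y1)),
            ],
            "flap_fl_side": [
                seg((xd0, y2), (e0, y2)),
                seg((e1, y2), (r0, y2)),
                seg((r1, y2), (xd1, y2)),
            ],
            "tear_edge": [
                seg((e0, y1), (e0, y2)),
                seg((e1, y1), (e1, y2)),
                seg((r0, y1), (r0, y2)),
                seg((r1, y1), (r1, y2)),
            ],
        }


def build_dissection_geometry(params: DissectionGeometry) -> DissectionDomain:
    """Validate *params* and return the planar domain description."""
    params.validate()
    return DissectionDomain(params)


# ---------------------------------------------------------------------------
# Mesh container
# ---------------------------------------------------------------------------


@dataclass
class Mesh:
    """Unstructured triangle mesh (SI metres) with tagged boundary facets.

    ``nodes`` are current (possibly ALE-deformed) coordinates; ``ref_nodes``
    the undeformed reference.  ``edges``/``edge_tags`` list boundary facets.
    ``node_ij`` holds the logical (column, row) grid index of each node,
    ``node_region`` its vertical band and ``node_yfrac`` the normalized
    position within that band (used for analytic flap-driven stretching).
    ``wall_stencils`` maps boundary-node index -> (n0, n1, n2) node indices
    along the inward grid line, n0 on the wall.
    """

    nodes: np.ndarray
    tris: np.ndarray
    edges: np.ndarray
    edge_tags: np.ndarray
    ref_nodes: np.ndarray = field(default=None)  # type: ignore[assignment]
    node_ij: np.ndarray | None = None
    node_region: np.ndarray | None = None
    node_yfrac: np.ndarray | None = None
    y_levels_m: tuple[float, float, float, float] | None = None
    x_marks_m: tuple[float, float, float] | None = None
    wall_stencils: dict[int, tuple[int, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref_nodes is None:
            self.ref_nodes = self.nodes.copy()

    # -- queries ------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_cells(self) -> int:
        return len(self.tris)

    def signed_areas(self) -> np.ndarray:
        p = self.nodes[self.tris]
        return 0.5 * (
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )

    def area(self) -> float:
        return float(self.signed_areas().sum())

    def edge_lengths(self) -> np.ndarray:
        d = self.nodes[self.edges[:, 1]] - self.nodes[self.edges[:, 0]]
        return np.hypot(d[:, 0], d[:, 1])

    def edge_midpoints(self) -> np.ndarray:
        return 0.5 * (self.nodes[self.edges[:, 0]] + self.nodes[self.edges[:, 1]])

    def edges_with_tag(self, *names: str) -> np.ndarray:
        codes = [TAG[n] for n in names]
        return np.flatnonzero(np.isin(self.edge_tags, codes))

    def boundary_node_set(self, *names: str) -> np.ndarray:
        idx = self.edges_with_tag(*names)
        return np.unique(self.edges[idx].ravel())

    def check_invariants(self) -> None:
        sa = self.signed_areas()
        if not np.all(sa > 0):
            raise InvalidGeometryError(
                f"mesh has {int(np.sum(sa <= 0))} non-positively oriented cells"
            )
        # every boundary facet tagged exactly once (tags stored densely)
        if len(self.edge_tags) != len(self.edges):
            raise InvalidGeometryError("boundary facet tags do not partition the boundary")


# ---------------------------------------------------------------------------
# Structured masked triangulation
# ---------------------------------------------------------------------------


def _band_points(a: float, b: float, h: float, min_cells: int, wall_layers: int,
                 refine_lo: bool = True, refine_hi: bool = True) -> np.ndarray:
    """1D point distribution on [a, b]: uniform core plus optional graded
    wall-layer rows (each layer halves the adjacent spacing)."""
    n = max(int(np.ceil((b - a) / h)), min_cells)
    pts = np.linspace(a, b, n + 1)
    for _ in range(wall_layers):
        extra = []
        if refine_lo:
            extra.append(0.5 * (pts[0] + pts[1]))
        if refine_hi:
            extra.append(0.5 * (pts[-2] + pts[-1]))
        if extra:
            pts = np.sort(np.concatenate([pts, extra]))
    return pts


def _segmented_axis(marks: list[float], h: float) -> np.ndarray:
    """Axis points hitting every mark, uniform within each segment."""
    marks = sorted(set(round(m, 9) for m in marks))
    pts = [marks[0]]
    for a, b in zip(marks[:-1], marks[1:]):
        n = max(int(np.ceil((b - a) / h)), 1)
        pts.extend(np.linspace(a, b, n + 1)[1:])
    return np.asarray(pts)


def _triangulate_masked_grid(
    xs: np.ndarray,
    ys: np.ndarray,
    fluid: Callable[[float, float], bool],
    classify: Callable[[float, float, bool], int],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Mask a tensor grid of quads by *fluid*, split into triangles, find and
    tag boundary facets.  Returns (nodes_mm, tris, edges, tags, node_ij)."""
    nx, ny = len(xs), len(ys)
    xc = 0.5 * (xs[:-1] + xs[1:])
    yc = 0.5 * (ys[:-1] + ys[1:])
    mask = np.zeros((nx - 1, ny - 1), bool)
    for i in range(nx - 1):
        for j in range(ny - 1):
            mask[i, j] = fluid(xc[i], yc[j])
    if not mask.any():
        raise InvalidGeometryError("empty fluid region: no cells generated")

    used = np.zeros((nx, ny), bool)
    ii, jj = np.nonzero(mask)
    for di in (0, 1):
        for dj in (0, 1):
            used[ii + di, jj + dj] = True
    node_id = -np.ones((nx, ny), np.int64)
    gi, gj = np.nonzero(used)
    node_id[gi, gj] = np.arange(len(gi))
    nodes = np.column_stack([xs[gi], ys[gj]])
    node_ij = np.column_stack([gi, gj])

    tris = []
    for i, j in zip(ii, jj):
        n00, n10 = node_id[i, j], node_id[i + 1, j]
        n01, n11 = node_id[i, j + 1], node_id[i + 1, j + 1]
        # fixed diagonal (lower-left to upper-right): deterministic
        tris.append((n00, n10, n11))
        tris.append((n00, n11, n01))
    tris = np.asarray(tris, np.int64)

    # boundary facets: quad-grid edges with exactly one fluid neighbour
    edges, tags = [], []
    padded = np.zeros((nx + 1, ny + 1), bool)
    padded[1:nx, 1:ny] = mask
    # vertical facets between cell (i-1,j) and (i,j)
    for i in range(nx):
        for j in range(ny - 1):
            left, right = padded[i, j + 1], padded[i + 1, j + 1]
            if left != right:
                a, b = node_id[i, j], node_id[i, j + 1]
                # store so the outward normal is (dy, -dx)/|d|
                edges.append((b, a) if right else (a, b))
                tags.append(classify(xs[i], 0.5 * (ys[j] + ys[j + 1]), False))
    # horizontal facets between cell (i,j-1) and (i,j)
    for j in range(ny):
        for i in range(nx - 1):
            below, above = padded[i + 1, j], padded[i + 1, j + 1]
            if below != above:
                a, b = node_id[i, j], node_id[i + 1, j]
                edges.append((a, b) if above else (b, a))
                tags.append(classify(0.5 * (xs[i] + xs[i + 1]), ys[j], True))
    return nodes, tris, np.asarray(edges, np.int64), np.asarray(tags, np.int64), node_ij


def _wall_stencils(mesh: Mesh) -> None:
    """Precompute inward 3-node stencils along grid lines for wall nodes."""
    lookup = {(int(i), int(j)): k for k, (i, j) in enumerate(mesh.node_ij)}
    horiz_tags = {TAG["outer_wall"], TAG["flap_tl_side"], TAG["flap_fl_side"]}
    vert_tags = {TAG["fl_endwall"], TAG["tear_edge"]}
    node_set = set()
    for e, t in zip(mesh.edges, mesh.edge_tags):
        if int(t) in horiz_tags | vert_tags:
            node_set.update((int(e[0]), int(e[1])))
    for n in sorted(node_set):
        i, j = int(mesh.node_ij[n, 0]), int(mesh.node_ij[n, 1])
        # prefer the inward direction whose first step leaves the wall-node
        # set (strictly interior); corner nodes fall back to any grid line
        fallback = None
        chosen = None
        for di, dj in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            n1 = lookup.get((i + di, j + dj))
            n2 = lookup.get((i + 2 * di, j + 2 * dj))
            if n1 is None or n2 is None:
                continue
            if fallback is None:
                fallback = (n, n1, n2)
            if n1 not in node_set:
                chosen = (n, n1, n2)
                break
        if chosen or fallback:
            mesh.wall_stencils[n] = chosen or fallback


def generate_mesh(
    domain: DissectionDomain,
    target_edge_length: float,
    wall_layers: int = 0,
) -> Mesh:
    """Mesh the dissection domain; *target_edge_length* in mm.

    Guarantees >= 3 cells across the flap thickness and across each tear
    opening, and >= 4 cells across each channel.
    """
    p = domain.params
    if not np.isfinite(target_edge_length) or target_edge_length <= 0:
        raise InvalidGeometryError(
            f"target_edge_length must be positive, got {target_edge_length}"
        )
    if wall_layers < 0:
        raise InvalidGeometryError("wall_layers must be >= 0")
    h = float(target_edge_length)
    _, y1, y2, y3 = p.y_levels
    xd0, xd1, xl = p.x_marks
    (e0, e1), (r0, r1) = p.tear_intervals()

    # axial: hit every feature mark; >= 3 cells across each tear
    ht = min(h, p.tear_length / 3.0)
    xs = _segmented_axis([0.0, xd0, e0, e1, r0, r1, xd1, xl], 0.0 + h)
    if (e1 - e0) / h < 3 or (r1 - r0) / h < 3:
        xs = _segmented_axis([0.0, xd0, e0, e1, r0, r1, xd1, xl], ht)

    ys_tl = _band_points(0.0, y1, h, 4, wall_layers)
    ys_flap = _band_points(y1, y2, min(h, p.flap_thickness / 3.0), 3, 0)
    ys_fl = _band_points(y2, y3, h, 4, wall_layers)
    ys = np.unique(np.concatenate([ys_tl, ys_flap, ys_fl]))

    nodes_mm, tris, edges, tags, node_ij = _triangulate_masked_grid(
        xs, ys, domain.fluid, domain.classify_edge
    )

    mesh = Mesh(
        nodes=nodes_mm * MM,
        tris=tris,
        edges=edges,
        edge_tags=tags,
        node_ij=node_ij,
    )
    mesh.y_levels_m = tuple(v * MM for v in p.y_levels)
    mesh.x_marks_m = tuple(v * MM for v in p.x_marks)

    # band metadata for ALE stretching
    yv = nodes_mm[:, 1]
    region = np.full(len(yv), REGION_FLAP, np.int8)
    region[yv <= y1 + 1e-9] = REGION_TL
    region[yv >= y2 - 1e-9] = REGION_FL
    yfrac = np.empty(len(yv))
    tl = region == REGION_TL
    fl = region == REGION_FL
    fp = region == REGION_FLAP
    yfrac[tl] = yv[tl] / y1
    yfrac[fl] = (y3 - yv[fl]) / (y3 - y2)  # 0 at outer wall... no: 0 at y3
    yfrac[fl] = (yv[fl] - y2) / (y3 - y2)
    yfrac[fp] = (yv[fp] - y1) / (y2 - y1)
    mesh.node_region = region
    mesh.node_yfrac = yfrac

    mesh.check_invariants()
    _wall_stencils(mesh)
    return mesh


def benchmark_channel(
    length: float,
    width: float,
    target_edge_length: float,
    nx: int | None = None,
    ny: int | None = None,
) -> Mesh:
    """Rectangular verification channel (dimensions in mm, mesh in m) with
    inlet (x=0), tl_outlet (x=L) and outer_wall (y=0, y=W) tags.

    Explicit ``nx``/``ny`` force an exact structured cell count.
    """
    for name, val in (("length", length), ("width", width),
                      ("target_edge_length", target_edge_length)):
        if not np.isfinite(val) or val <= 0:
            raise InvalidGeometryError(f"{name} must be positive, got {val}")
    h = target_edge_length
    nx = nx if nx is not None else max(int(round(length / h)), 1)
    ny = ny if ny is not None else max(int(round(width / h)), 1)
    xs = np.linspace(0.0, length, nx + 1)
    ys = np.linspace(0.0, width, ny + 1)

    def fluid(x: float, y: float) -> bool:
        return 0 < x < length and 0 < y < width

    def classify(xm: float, ym: float, horizontal: bool) -> int:
        if horizontal:
            return TAG["outer_wall"]
        if abs(xm) < 1e-12:
            return TAG["inlet"]
        return TAG["tl_outlet"]

    nodes_mm, tris, edges, tags, node_ij = _triangulate_masked_grid(
        xs, ys, fluid, classify
    )
    mesh = Mesh(
        nodes=nodes_mm * MM,
        tris=tris,
        edges=edges,
        edge_tags=tags,
        node_ij=node_ij,
    )
    mesh.node_region = np.zeros(mesh.n_nodes, np.int8)
    mesh.node_yfrac = nodes_mm[:, 1] / width
    mesh.check_invariants()
    _wall_stencils(mesh)
    return mesh
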