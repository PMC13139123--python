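"""Parametric vertebro-subclavian bifurcation geometry and meshing.

The idealised lumen is modelled in its bifurcation plane: a straight
subclavian (SCA) channel of width ``d_sca`` with a vertebral (VA) side branch
of width ``d_va`` leaving the far wall at angle ``theta`` (measured between
the VA take-off and the distal SCA direction) and running ``l_vao`` along its
centerline to the VA outlet.  Channel widths equal the vessel diameters, so
the in-plane separation / recirculation physics at the ostium is retained at
desk scale.

Meshing is a deterministic structured transfinite triangulation: the SCA is a
tensor grid whose upper-wall nodes conform exactly to the VA base nodes, and
the VA is a ruled (transfinite) quadrilateral grid between its two wall
lines, each quad split into two triangles.  Junction corners are rounded by a
configurable fillet radius (boundary nodes are snapped onto the tangent
arcs).  "Patient-like" variants are produced by a smooth, seeded
displacement field of the VA centerline and width.

Boundary facets carry one tag each:  ``inlet``, ``sca_outlet``, ``va_outlet``,
``wall_medial`` (the VA wall on the flow-divider side, continuous with the
SCA wall downstream of the ostium), ``wall_lateral`` (the opposite,
ostium-upstream side) and ``wall_other``.  All coordinates are in mm.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "BifurcationSpec", "MeshLevel", "LabeledMesh", "Outline", "GeometryError",
    "build_bifurcation", "generate_mesh", "tag_regions", "perturb_geometry",
    "measured_branch_angle", "channel_outline", "monitor_section",
]

WALL_TAGS = ("wall_medial", "wall_lateral", "wall_other")
ALL_TAGS = ("inlet", "sca_outlet", "va_outlet") + WALL_TAGS


class GeometryError(ValueError):
    """Raised when requested parameters produce an invalid outline or mesh."""


@dataclass(frozen=True)
class BifurcationSpec:
    """Geometric parameters of the idealised VA-SCA bifurcation (mm, deg).

    Defaults follow the published idealised model: SCA diameter 8.4 mm, VA
    diameter 3.3 mm, VAO length 40 mm; inlet/outlet extensions of three SCA
    diameters and a 0.5 mm junction fillet are package choices (the source
    model does not state them).  Wall thickness (0.5 mm in the source) is
    recorded but unused: the solver is rigid-wall, only the lumen is meshed.
    """

    theta: float = 70.0
    d_sca: float = 8.4
    d_va: float = 3.3
    l_vao: float = 40.0
    l_inlet: Optional[float] = None       # default 3 * d_sca
    l_sca_outlet: Optional[float] = None  # default 3 * d_sca
    fillet_radius: float = 0.5
    wall_thickness: float = 0.5  # recorded only

    def __post_init__(self) -> None:
        if not (0.0 < self.theta < 180.0):
            raise GeometryError(f"theta must lie in (0, 180), got {self.theta}")
        if self.d_va >= self.d_sca:
            raise GeometryError("d_va must be smaller than d_sca")
        for name in ("d_sca", "d_va", "l_vao"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if self.fillet_radius < 0:
            raise GeometryError("fillet_radius must be non-negative")

    @property
    def inlet_length(self) -> float:
        return 3.0 * self.d_sca if self.l_inlet is None else self.l_inlet

    @property
    def outlet_length(self) -> float:
        return 3.0 * self.d_sca if self.l_sca_outlet is None else self.l_sca_outlet

    # --- derived junction frame -------------------------------------------
    @property
    def theta_rad(self) -> float:
        return math.radians(self.theta)

    @property
    def branch_dir(self) -> np.ndarray:
        """Unit vector along the VA centerline (away from the SCA)."""
        return np.array([math.cos(self.theta_rad), math.sin(self.theta_rad)])

    @property
    def branch_normal(self) -> np.ndarray:
        """Unit cross-channel vector; +normal points to the lateral side."""
        return np.array([-math.sin(self.theta_rad), math.cos(self.theta_rad)])

    @property
    def half_opening(self) -> float:
        """Half-length of the ostium footprint on the SCA wall."""
        return 0.5 * self.d_va / math.sin(self.theta_rad)

    @property
    def junction_center(self) -> np.ndarray:
        """Ostium centerline point on the SCA upper wall."""
        return np.array([self.inlet_length + self.half_opening, self.d_sca])

    @property
    def sca_length(self) -> float:
        return self.inlet_length + 2.0 * self.half_opening + self.outlet_length


@dataclass(frozen=True)
class MeshLevel:
    """One rung of a refinement ladder: characteristic size and counts."""

    h: float
    n_elements: int
    n_nodes: int


@dataclass
class Outline:
    """Closed, tagged boundary polyline of the lumen.

    ``segments`` is an ordered list of (tag, points) with consecutive
    segments sharing endpoints; traversal is counter-clockwise (fluid on the
    left).  ``fillets`` stores (center, radius) of the junction rounding arcs
    so meshes can snap onto them.  ``displacement`` carries the smooth
    perturbation field of a patient-like variant (None for the idealised
    model).
    """

    spec: BifurcationSpec
    segments: list  # [(tag, (n,2) ndarray), ...]
    fillets: list = field(default_factory=list)  # [(center(2,), radius), ...]
    displacement: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def points(self) -> np.ndarray:
        return np.vstack([pts for _, pts in self.segments])

    def segment(self, tag: str) -> np.ndarray:
        for t, pts in self.segments:
            if t == tag:
                return pts
        raise KeyError(tag)


@dataclass
class LabeledMesh:
    """Conforming planar triangle mesh with tagged boundary facets (mm).

    nodes : (N, 2) coordinates
    triangles : (M, 3) CCW vertex indices
    boundary_edges : (E, 2) vertex indices along the boundary
    edge_tags : length-E array of tag strings
    edge_arclength : length-E array; arc-length from the ostium for VAO wall
        facets (midpoint value), NaN elsewhere
    """

    nodes: np.ndarray
    triangles: np.ndarray
    boundary_edges: np.ndarray
    edge_tags: np.ndarray
    edge_arclength: np.ndarray
    spec: Optional[BifurcationSpec] = None
    h: Optional[float] = None

    # -- basic integrity ----------------------------------------------------
    def triangle_areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        return 0.5 * ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                      - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))

    def edge_lengths(self) -> np.ndarray:
        p = self.nodes[self.boundary_edges]
        return np.linalg.norm(p[:, 1] - p[:, 0], axis=1)

    def edge_midpoints(self) -> np.ndarray:
        p = self.nodes[self.boundary_edges]
        return 0.5 * (p[:, 0] + p[:, 1])

    def quality(self) -> np.ndarray:
        """Per-triangle inradius/circumradius ratio (0.5 for equilateral)."""
        p = self.nodes[self.triangles]
        a = np.linalg.norm(p[:, 1] - p[:, 2], axis=1)
        b = np.linalg.norm(p[:, 2] - p[:, 0], axis=1)
        c = np.linalg.norm(p[:, 0] - p[:, 1], axis=1)
        s = 0.5 * (a + b + c)
        area = np.abs(self.triangle_areas())
        inr = area / s
        circ = a * b * c / (4.0 * np.maximum(area, 1e-300))
        return inr / circ

    @property
    def level(self) -> MeshLevel:
        return MeshLevel(h=self.h if self.h else float("nan"),
                         n_elements=len(self.triangles), n_nodes=len(self.nodes))

    def boundary_node_set(self) -> np.ndarray:
        return np.unique(self.boundary_edges)


# ---------------------------------------------------------------------------
# outline construction
# ---------------------------------------------------------------------------

def _fillet_arc(p_prev: np.ndarray, corner: np.ndarray, p_next: np.ndarray,
                r: float, n_arc: int = 9):
    """Tangent arc rounding the corner between two straight walls.

    Returns (arc_points, center, tangent_distance).  Raises GeometryError if
    the tangent distance exceeds 80% of either adjacent segment.
    """
    u = corner - p_prev
    v = p_next - corner
    lu, lv = np.linalg.norm(u), np.linalg.norm(v)
    u, v = u / lu, v / lv
    # interior turn angle between incoming and outgoing directions
    cosang = float(np.clip(np.dot(-u, v), -1.0, 1.0))
    beta = math.acos(cosang)  # wedge angle between the two wall rays
    if beta < 1e-9 or abs(math.pi - beta) < 1e-9:
        return np.array([corner]), None, 0.0  # straight through, nothing to do
    d_t = r / math.tan(0.5 * beta)
    if d_t > 0.8 * min(lu, lv):
        raise GeometryError(
            f"fillet_radius={r} too large for corner geometry "
            f"(tangent distance {d_t:.2f} mm vs segments {lu:.2f}/{lv:.2f} mm)")
    t0 = corner - u * d_t
    t1 = corner + v * d_t
    bis = (-u + v)
    bis = bis / np.linalg.norm(bis)
    center = corner + bis * (r / math.sin(0.5 * beta))
    a0 = math.atan2(*(t0 - center)[::-1])
    a1 = math.atan2(*(t1 - center)[::-1])
    # shorter way around
    da = (a1 - a0 + math.pi) % (2 * math.pi) - math.pi
    ang = a0 + da * np.linspace(0.0, 1.0, n_arc)
    arc = center + r * np.column_stack([np.cos(ang), np.sin(ang)])
    return arc, center, d_t


def _polyline(p0, p1, max_step: float = 2.0) -> np.ndarray:
    n = max(1, int(math.ceil(np.linalg.norm(np.asarray(p1) - np.asarray(p0)) / max_step)))
    t = np.linspace(0.0, 1.0, n + 1)[:, None]
    return (1 - t) * np.asarray(p0)[None, :] + t * np.asarray(p1)[None, :]


def build_bifurcation(spec: BifurcationSpec) -> Outline:
    """Closed tagged outline of the bifurcation lumen (CCW, mm)."""
    D, w, L = spec.d_sca, spec.d_va, spec.sca_length
    C = spec.junction_center
    d, n = spec.branch_dir, spec.branch_normal
    half = spec.half_opening
    A = np.array([C[0] - half, D])          # lateral junction corner
    B = np.array([C[0] + half, D])          # medial junction corner (divider)
    T_lat = C + spec.l_vao * d + 0.5 * w * n
    T_med = C + spec.l_vao * d - 0.5 * w * n

    fillets = []
    r = spec.fillet_radius
    if r > 0:
        arc_med, cen_med, dt_med = _fillet_arc(np.array([L, D]), B, T_med, r)
        arc_lat, cen_lat, dt_lat = _fillet_arc(T_lat, A, np.array([0.0, D]), r)
        if cen_med is not None:
            fillets.append((cen_med, r, B, dt_med))
        if cen_lat is not None:
            fillets.append((cen_lat, r, A, dt_lat))
    else:
        arc_med, arc_lat = np.array([B]), np.array([A])

    segments = [
        ("wall_other", _polyline([0.0, 0.0], [L, 0.0])),
        ("sca_outlet", _polyline([L, 0.0], [L, D], max_step=D)),
        ("wall_other", np.vstack([_polyline([L, D], B)[:-1], arc_med[:1]])),
        ("wall_medial", np.vstack([arc_med, _polyline(arc_med[-1], T_med)[1:]])),
        ("va_outlet", _polyline(T_med, T_lat, max_step=w)),
        ("wall_lateral", np.vstack([_polyline(T_lat, arc_lat[0])[:-1], arc_lat])),
        ("wall_other", np.vstack([arc_lat[-1:], _polyline(A, [0.0, D])[1:]])),
        ("inlet", _polyline([0.0, D], [0.0, 0.0], max_step=D)),
    ]
    out = Outline(spec=spec, segments=segments, fillets=fillets)
    _check_no_self_intersection(out)
    return out


def _check_no_self_intersection(outline: Outline) -> None:
    pts = outline.points()
    # cheap sanity: consecutive duplicate removal, then shoelace area > 0
    d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    pts = np.vstack([pts[:1], pts[1:][d > 1e-12]])
    x, y = pts[:, 0], pts[:, 1]
    area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if area <= 0:
        raise GeometryError("outline is not a positively oriented simple loop "
                            f"(theta={outline.spec.theta}, "
                            f"fillet_radius={outline.spec.fillet_radius})")


def measured_branch_angle(outline: Outline, proximal_fraction: float = 0.35) -> float:
    """Realised VA take-off angle in degrees, from the generated outline.

    Fits the proximal part of each VAO wall (fillet zone excluded) by PCA and
    measures the mean direction against the distal SCA axis (+x).
    """
    spec = outline.spec
    dirs = []
    for tag in ("wall_medial", "wall_lateral"):
        pts = outline.segment(tag)
        # drop points within the junction offset and fillet tangent zone
        s = (pts - spec.junction_center) @ spec.branch_dir
        th = spec.theta_rad
        wedge = min(th, math.pi - th)
        lo = (0.5 * spec.d_va * abs(math.cos(th) / math.sin(th))
              + spec.fillet_radius / max(math.tan(0.5 * wedge), 1e-9) + 0.5)
        keep = (s > lo) & (s < lo + proximal_fraction * spec.l_vao)
        q = pts[keep]
        if len(q) < 2:
            q = pts
        q = q - q.mean(axis=0)
        _, _, vt = np.linalg.svd(q, full_matrices=False)
        v = vt[0]
        if v @ spec.branch_dir < 0:
            v = -v
        dirs.append(v)
    v = np.mean(dirs, axis=0)
    v = v / np.linalg.norm(v)
    return math.degrees(math.atan2(v[1], v[0]))


# ---------------------------------------------------------------------------
# patient-like perturbation
# ---------------------------------------------------------------------------

def perturb_geometry(spec: BifurcationSpec, amplitude: float, seed: int) -> Outline:
    """Smoothly perturbed variant of the idealised outline.

    A low-order sinusoidal displacement field bends the VA centerline and
    modulates its width by up to ``amplitude`` (fraction of the VA diameter),
    vanishing at the ostium and the VA outlet so the junction and boundary
    tags are untouched.  Deterministic given ``seed``; amplitude 0 returns
    the unperturbed outline.
    """
    if not (0.0 <= amplitude <= 0.2):
        raise ValueError("amplitude must lie in [0, 0.2]")
    base = build_bifurcation(spec)
    if amplitude == 0.0:
        return base
    rng = np.random.default_rng(seed)
    k_bend = int(rng.integers(1, 3))
    k_width = int(rng.integers(1, 3))
    a_bend = amplitude * spec.d_va * float(rng.uniform(0.5, 1.0)) * float(rng.choice([-1, 1]))
    a_width = amplitude * float(rng.uniform(0.5, 1.0)) * float(rng.choice([-1, 1]))

    C, d, n = spec.junction_center, spec.branch_dir, spec.branch_normal
    w, L = spec.d_va, spec.l_vao
    D = spec.d_sca

    def displacement(pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        rel = pts - C
        s = rel @ d
        q = rel @ n
        zeta = np.clip((s - w) / max(L - w, 1e-9), 0.0, 1.0)
        in_branch = (pts[:, 1] >= D - 1e-9) & (s > 0) & (np.abs(q) <= 0.75 * w)
        bend = a_bend * np.sin(math.pi * k_bend * zeta)
        widen = q * a_width * np.sin(math.pi * k_width * zeta)
        delta = np.where(in_branch, bend + widen, 0.0)
        return delta[:, None] * n[None, :]

    segments = [(tag, pts + displacement(pts)) for tag, pts in base.segments]
    return Outline(spec=spec, segments=segments, fillets=base.fillets,
                   displacement=displacement)


# ---------------------------------------------------------------------------
# meshing
# ---------------------------------------------------------------------------

def _tri_quality(p0, p1, p2) -> float:
    a = np.linalg.norm(p1 - p2)
    b = np.linalg.norm(p2 - p0)
    c = np.linalg.norm(p0 - p1)
    area = 0.5 * abs((p1[0] - p0[0]) * (p2[1] - p0[1])
                     - (p2[0] - p0[0]) * (p1[1] - p0[1]))
    if area <= 0:
        return 0.0
    s = 0.5 * (a + b + c)
    return (area / s) / (a * b * c / (4.0 * area))


def _grid_to_triangles(nx: int, ny: int, index: Callable[[int, int], int],
                       coords=None):
    """Split an nx*ny structured quad grid into triangles.

    With ``coords`` (callable index -> position) the diagonal of each quad is
    chosen to maximise the worse of the two triangle qualities; otherwise a
    consistent diagonal is used.
    """
    tris = []
    for i in range(nx):
        for j in range(ny):
            a, b = index(i, j), index(i + 1, j)
            c, dd = index(i + 1, j + 1), index(i, j + 1)
            if coords is not None:
                pa, pb, pc, pd = (coords(k) for k in (a, b, c, dd))
                q_ac = min(_tri_quality(pa, pb, pc), _tri_quality(pa, pc, pd))
                q_bd = min(_tri_quality(pa, pb, pd), _tri_quality(pb, pc, pd))
                if q_bd > q_ac:
                    tris.append((a, b, dd))
                    tris.append((b, c, dd))
                    continue
            tris.append((a, b, c))
            tris.append((a, c, dd))
    return tris


def generate_mesh(outline: Outline, h: float) -> LabeledMesh:
    """Structured conforming triangle mesh of the bifurcation at size ``h``.

    Tags are assigned constructively; :func:`tag_regions` is then applied to
    (re)derive the medial/lateral split and the arc-length coordinates from
    the geometry itself.
    """
    if h <= 0:
        raise ValueError("h must be positive")
    spec = outline.spec
    D, w, L = spec.d_sca, spec.d_va, spec.sca_length
    C, d, n = spec.junction_center, spec.branch_dir, spec.branch_normal
    half = spec.half_opening
    A = np.array([C[0] - half, D])
    B = np.array([C[0] + half, D])
    T_lat = C + spec.l_vao * d + 0.5 * w * n
    T_med = C + spec.l_vao * d - 0.5 * w * n

    # VA grid resolution
    n_w = max(3, round(w / h))
    n_l = max(3, round(spec.l_vao / h))
    xi = np.linspace(0.0, 1.0, n_w + 1)
    base = (1 - xi)[:, None] * A[None, :] + xi[:, None] * B[None, :]
    top = (1 - xi)[:, None] * T_lat[None, :] + xi[:, None] * T_med[None, :]

    # SCA x-grid: uniform outside the ostium footprint, base x's inside
    def seg(a, b):
        m = max(1, round((b - a) / h))
        return np.linspace(a, b, m + 1)

    xs = np.unique(np.concatenate([seg(0.0, A[0]), base[:, 0], seg(B[0], L)]))
    ys = np.linspace(0.0, D, max(2, round(D / h)) + 1)
    nx, ny = len(xs), len(ys)

    nodes = [np.array([x, y]) for y in ys for x in xs]  # row-major by y

    def sca_idx(i, j):  # i along x, j along y
        return j * nx + i

    tris = _grid_to_triangles(nx - 1, ny - 1,
                              lambda i, j: sca_idx(i, j))

    # VA nodes: base row (j=0) reuses SCA top-row nodes
    base_cols = [int(np.searchsorted(xs, bx)) for bx in base[:, 0]]
    for ci, bx in zip(base_cols, base[:, 0]):
        if abs(xs[ci] - bx) > 1e-8:
            raise GeometryError("VA base nodes do not conform to SCA grid")
    va_index = np.empty((n_w + 1, n_l + 1), dtype=int)
    for i in range(n_w + 1):
        va_index[i, 0] = sca_idx(base_cols[i], ny - 1)
    eta = np.linspace(0.0, 1.0, n_l + 1)
    for j in range(1, n_l + 1):
        for i in range(n_w + 1):
            p = (1 - eta[j]) * base[i] + eta[j] * top[i]
            va_index[i, j] = len(nodes)
            nodes.append(p)

    node_arr = np.asarray(nodes)
    tris += _grid_to_triangles(n_w, n_l, lambda i, j: int(va_index[i, j]),
                               coords=lambda k: node_arr[k])

    nodes = np.asarray(nodes)
    tris = np.asarray(tris, dtype=int)

    # orientation fix
    p = nodes[tris]
    areas = 0.5 * ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                   - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
    flip = areas < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]

    # boundary edges with constructive tags
    edges, tags = [], []
    i_a, i_b = base_cols[0], base_cols[-1]
    for i in range(nx - 1):  # bottom wall
        edges.append((sca_idx(i, 0), sca_idx(i + 1, 0)))
        tags.append("wall_other")
    for j in range(ny - 1):  # inlet and sca outlet
        edges.append((sca_idx(0, j), sca_idx(0, j + 1)))
        tags.append("inlet")
        edges.append((sca_idx(nx - 1, j), sca_idx(nx - 1, j + 1)))
        tags.append("sca_outlet")
    for i in range(nx - 1):  # top wall outside the ostium
        if i < i_a or i >= i_b:
            edges.append((sca_idx(i, ny - 1), sca_idx(i + 1, ny - 1)))
            tags.append("wall_other")
    for j in range(n_l):  # VA walls
        edges.append((int(va_index[0, j]), int(va_index[0, j + 1])))
        tags.append("wall_lateral")
        edges.append((int(va_index[n_w, j]), int(va_index[n_w, j + 1])))
        tags.append("wall_medial")
    for i in range(n_w):  # VA outlet
        edges.append((int(va_index[i, n_l]), int(va_index[i + 1, n_l])))
        tags.append("va_outlet")

    mesh = LabeledMesh(nodes=nodes, triangles=tris,
                       boundary_edges=np.asarray(edges, dtype=int),
                       edge_tags=np.asarray(tags, dtype=object),
                       edge_arclength=np.full(len(edges), np.nan),
                       spec=spec, h=h)

    _snap_fillets(mesh, outline)
    if outline.displacement is not None:
        mesh.nodes = mesh.nodes + outline.displacement(mesh.nodes)
    if np.any(mesh.triangle_areas() <= 0):
        raise GeometryError("mesh contains inverted elements")
    return tag_regions(mesh, spec)


def _snap_fillets(mesh: LabeledMesh, outline: Outline) -> None:
    """Round the junction corners: wall nodes in each fillet's tangent zone
    are projected radially onto the arc, then nearby interior nodes are
    relaxed (boundary fixed) so no element inverts."""
    if not outline.fillets:
        return
    bnodes = mesh.boundary_node_set()
    bset = set(int(i) for i in bnodes)
    moved_zones = []
    for center, r, apex, d_t in outline.fillets:
        near = bnodes[np.linalg.norm(mesh.nodes[bnodes] - apex, axis=1) < d_t + 1e-9]
        for idx in near:
            v = mesh.nodes[idx] - center
            nv = np.linalg.norm(v)
            if nv < 1e-12:
                continue
            mesh.nodes[idx] = center + v * (r / nv)
        moved_zones.append((apex, 3.0 * max(d_t, r)))
    if not moved_zones:
        return
    # local Laplacian relaxation of interior nodes near the rounded corners
    neigh = {}
    for tri in mesh.triangles:
        for a in tri:
            neigh.setdefault(int(a), set()).update(int(b) for b in tri if b != a)
    relax = [i for i in range(len(mesh.nodes)) if i not in bset
             and any(np.linalg.norm(mesh.nodes[i] - apex) < rad
                     for apex, rad in moved_zones)]
    for _ in range(10):
        for i in relax:
            nb = list(neigh[i])
            mesh.nodes[i] = mesh.nodes[nb].mean(axis=0)


def tag_regions(mesh: LabeledMesh, spec: BifurcationSpec) -> LabeledMesh:
    """Derive medial/lateral VAO wall tags and arc-length coordinates.

    A wall facet belongs to the VAO if its midpoint lies on or above the SCA
    upper wall within the branch corridor; the side of the VA centerline
    (sign of the cross-channel coordinate) decides medial vs lateral, with
    facets in the fillet zone assigned by the nearest arc.  Arc-length is
    measured from the ostium corner along each wall chain.
    """
    C, d, n = spec.junction_center, spec.branch_dir, spec.branch_normal
    D = spec.d_sca
    mids = mesh.edge_midpoints()
    is_wall = np.array([t.startswith("wall") for t in mesh.edge_tags])
    rel = mids - C
    s = rel @ d
    q = rel @ n
    # VAO walls: every wall facet strictly above the SCA upper wall (the
    # straight SCA walls sit exactly on y = d_sca; fillet-zone facets are
    # lifted above it and land on their nearest VA wall arc via the side
    # test below).
    in_branch = is_wall & (mids[:, 1] > D + 1e-9)
    new_tags = mesh.edge_tags.copy()
    new_tags[is_wall] = "wall_other"
    new_tags[in_branch & (q > 0)] = "wall_lateral"
    new_tags[in_branch & (q <= 0)] = "wall_medial"

    arclen = np.full(len(mesh.edge_tags), np.nan)
    for tag, corner_x in (("wall_lateral", C[0] - spec.half_opening),
                          ("wall_medial", C[0] + spec.half_opening)):
        sel = np.where(new_tags == tag)[0]
        if len(sel) == 0:
            continue
        # order facets along the wall by distance along branch axis
        order = np.argsort(s[sel])
        lengths = mesh.edge_lengths()[sel][order]
        cum = np.cumsum(lengths) - 0.5 * lengths
        arclen[sel[order]] = cum
    mesh.edge_tags = new_tags
    mesh.edge_arclength = arclen
    return mesh


# ---------------------------------------------------------------------------
# straight-channel benchmark geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _ChannelSpec:
    width: float
    length: float


def channel_outline(width: float = 3.3, length: float = 33.0):
    """Tagged outline of a straight channel (benchmark domain), mm."""
    seg = [
        ("wall_other", _polyline([0.0, 0.0], [length, 0.0])),
        ("sca_outlet", _polyline([length, 0.0], [length, width], max_step=width)),
        ("wall_other", _polyline([length, width], [0.0, width])),
        ("inlet", _polyline([0.0, width], [0.0, 0.0], max_step=width)),
    ]
    spec = BifurcationSpec(theta=90.0, d_sca=width, d_va=0.5 * width,
                           l_vao=length, l_inlet=0.0, l_sca_outlet=0.0,
                           fillet_radius=0.0)
    return Outline(spec=spec, segments=seg, fillets=[])


def channel_mesh(width: float, length: float, h: float) -> LabeledMesh:
    """Structured triangle mesh of a straight channel with tagged boundary."""
    if h <= 0:
        raise ValueError("h must be positive")
    xs = np.linspace(0.0, length, max(2, round(length / h)) + 1)
    ys = np.linspace(0.0, width, max(2, round(width / h)) + 1)
    nx, ny = len(xs), len(ys)
    nodes = np.array([[x, y] for y in ys for x in xs])

    def idx(i, j):
        return j * nx + i

    tris = np.asarray(_grid_to_triangles(nx - 1, ny - 1, idx), dtype=int)
    edges, tags = [], []
    for i in range(nx - 1):
        edges.append((idx(i, 0), idx(i + 1, 0)))
        tags.append("wall_other")
        edges.append((idx(i, ny - 1), idx(i + 1, ny - 1)))
        tags.append("wall_other")
    for j in range(ny - 1):
        edges.append((idx(0, j), idx(0, j + 1)))
        tags.append("inlet")
        edges.append((idx(nx - 1, j), idx(nx - 1, j + 1)))
        tags.append("sca_outlet")
    return LabeledMesh(nodes=nodes, triangles=tris,
                       boundary_edges=np.asarray(edges, dtype=int),
                       edge_tags=np.asarray(tags, dtype=object),
                       edge_arclength=np.full(len(edges), np.nan),
                       spec=None, h=h)


def monitor_section(spec: BifurcationSpec, offset: float = 1.5) -> tuple:
    """Endpoints (mm) of the monitored cross-section in the VA.

    A section across the VA, ``offset`` VA-diameters downstream of the
    ostium: it cuts through the recirculation zone and is therefore
    sensitive to the flow features of interest.
    """
    C, d, n = spec.junction_center, spec.branch_dir, spec.branch_normal
    s0 = offset * spec.d_va
    p0 = C + s0 * d + 0.49 * spec.d_va * n
    p1 = C + s0 * d - 0.49 * spec.d_va * n
    return p0, p1


def mesh_fingerprint(mesh: LabeledMesh) -> str:
    """Stable hash of the mesh connectivity and tags (determinism checks)."""
    hsh = hashlib.sha256()
    hsh.update(np.ascontiguousarray(np.round(mesh.nodes, 9)).tobytes())
    hsh.update(np.ascontiguousarray(mesh.triangles).tobytes())
    hsh.update("|".join(mesh.edge_tags).encode())
    return hsh.hexdigest()
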