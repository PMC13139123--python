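"""Taylor-Hood (P2 velocity / P1 pressure) finite elements on triangles.

Vectorised assembly of the operators the incompressible flow solver needs:
P2 mass matrix, stress-form viscous stiffness, P1-P2 divergence coupling,
explicit convection and variable-viscosity residuals, boundary flux and
traction integrals, and point sampling of P2 fields.

All lengths entering here are in metres (the mesh, stored in mm, is scaled
by the caller); the inf-sup stable P2/P1 pair needs no pressure
stabilisation, and with the constant pressure mode tested by the continuity
rows, global mass conservation holds to solver precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .geometry import LabeledMesh

# 7-point degree-5 triangle quadrature (barycentric, weights sum to 1)
_A1, _B1, _W1 = 0.0597158717897698, 0.4701420641051151, 0.1323941527885062
_A2, _B2, _W2 = 0.7974269853530873, 0.1012865073234563, 0.1259391805448271
QUAD_BARY = np.array([
    [1 / 3, 1 / 3, 1 / 3],
    [_A1, _B1, _B1], [_B1, _A1, _B1], [_B1, _B1, _A1],
    [_A2, _B2, _B2], [_B2, _A2, _B2], [_B2, _B2, _A2],
])
QUAD_W = np.array([0.225, _W1, _W1, _W1, _W2, _W2, _W2])


def p2_basis(lam: np.ndarray):
    """P2 basis values and barycentric derivatives at barycentric points.

    Local numbering: 0-2 vertices, 3 = mid(0,1), 4 = mid(1,2), 5 = mid(2,0).
    Returns (phi (nq,6), dphi_dlam (nq,6,3)).
    """
    lam = np.atleast_2d(lam)
    l0, l1, l2 = lam[:, 0], lam[:, 1], lam[:, 2]
    phi = np.stack([
        l0 * (2 * l0 - 1), l1 * (2 * l1 - 1), l2 * (2 * l2 - 1),
        4 * l0 * l1, 4 * l1 * l2, 4 * l2 * l0,
    ], axis=1)
    z = np.zeros_like(l0)
    d = np.stack([
        np.stack([4 * l0 - 1, z, z], axis=1),
        np.stack([z, 4 * l1 - 1, z], axis=1),
        np.stack([z, z, 4 * l2 - 1], axis=1),
        np.stack([4 * l1, 4 * l0, z], axis=1),
        np.stack([z, 4 * l2, 4 * l1], axis=1),
        np.stack([4 * l2, z, 4 * l0], axis=1),
    ], axis=1)
    return phi, d


@dataclass
class P2Space:
    """Geometric and basis data for one mesh (coordinates in metres)."""

    mesh: LabeledMesh
    scale: float                 # mm -> m factor actually applied
    verts: np.ndarray            # (nv,2) m
    tris: np.ndarray             # (ne,3)
    tri6: np.ndarray             # (ne,6) P2 connectivity
    coords: np.ndarray           # (np2,2) P2 node coordinates, m
    n_vert: int
    n_p2: int
    area: np.ndarray             # (ne,)
    grad_lam: np.ndarray         # (ne,3,2) gradients of barycentric coords
    phi_q: np.ndarray            # (nq,6)
    gphi_q: np.ndarray           # (ne,nq,6,2) physical P2 gradients
    gphi_x: np.ndarray           # (ne,nq,6) contiguous x-derivative slice
    gphi_y: np.ndarray           # (ne,nq,6)
    wdet: np.ndarray             # (ne,nq) quadrature weights * 2*area

    # boundary facet data (one entry per boundary edge of the mesh)
    b_edges: np.ndarray          # (nf,2) vertex ids
    b_mid: np.ndarray            # (nf,) P2 midpoint node id
    b_tags: np.ndarray
    b_arclength: np.ndarray      # mm, NaN off the VAO walls
    b_length: np.ndarray         # (nf,) m
    b_normal: np.ndarray         # (nf,2) outward unit normal
    b_elem: np.ndarray           # (nf,) adjacent element
    b_gphi: np.ndarray           # (nf,6,2) P2 gradients at facet midpoint
    b_phi6: np.ndarray           # (nf,6) element-local P2 ids (alias tri6 row)


def build_space(mesh: LabeledMesh, scale: float = 1e-3) -> P2Space:
    verts = mesh.nodes * scale
    tris = mesh.triangles
    ne = len(tris)
    nv = len(verts)

    # unique edge numbering for P2 midpoints
    e_all = np.vstack([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    e_sorted = np.sort(e_all, axis=1)
    uniq, inv = np.unique(e_sorted, axis=0, return_inverse=True)
    edge_id = inv.reshape(3, ne).T  # (ne,3): edges (0,1),(1,2),(2,0)
    tri6 = np.hstack([tris, nv + edge_id])
    n_p2 = nv + len(uniq)
    coords = np.vstack([verts, 0.5 * (verts[uniq[:, 0]] + verts[uniq[:, 1]])])

    p = verts[tris]  # (ne,3,2)
    e1 = p[:, 1] - p[:, 0]
    e2 = p[:, 2] - p[:, 0]
    det = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
    area = 0.5 * det
    if np.any(area <= 0):
        raise ValueError("mesh has non-positively-oriented elements")
    # grad lambda: J^{-T} @ ref grads; ref grads: l0=(-1,-1), l1=(1,0), l2=(0,1)
    invJT = np.empty((ne, 2, 2))
    invJT[:, 0, 0] = e2[:, 1]
    invJT[:, 0, 1] = -e1[:, 1]
    invJT[:, 1, 0] = -e2[:, 0]
    invJT[:, 1, 1] = e1[:, 0]
    invJT /= det[:, None, None]
    ref = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])
    grad_lam = np.einsum("eij,kj->eki", invJT, ref)  # (ne,3,2)

    phi_q, dphi_q = p2_basis(QUAD_BARY)  # (nq,6), (nq,6,3)
    gphi_q = np.einsum("qak,ekd->eqad", dphi_q, grad_lam)
    wdet = QUAD_W[None, :] * (2.0 * area)[:, None] * 0.5  # w * area... see note
    # QUAD_W sums to 1 and integrates f over the reference triangle of area
    # 1/2 scaled by det = 2*area, i.e. int f = sum w_q f_q * area.
    wdet = QUAD_W[None, :] * area[:, None]

    # boundary facets
    edge_key = {tuple(e): k for k, e in enumerate(map(tuple, uniq))}
    # adjacency: for each unique edge, elements containing it
    owner = {}
    for loc in range(3):
        for e in range(ne):
            owner.setdefault(int(edge_id[e, loc]), []).append(e)
    b_edges = mesh.boundary_edges
    nf = len(b_edges)
    b_mid = np.empty(nf, dtype=int)
    b_elem = np.empty(nf, dtype=int)
    for k, (a, b) in enumerate(np.sort(b_edges, axis=1)):
        eid = edge_key[(int(a), int(b))]
        b_mid[k] = nv + eid
        own = owner[eid]
        if len(own) != 1:
            raise ValueError("boundary edge shared by more than one element")
        b_elem[k] = own[0]

    pa = verts[b_edges[:, 0]]
    pb = verts[b_edges[:, 1]]
    tang = pb - pa
    b_length = np.linalg.norm(tang, axis=1)
    normal = np.column_stack([tang[:, 1], -tang[:, 0]]) / b_length[:, None]
    # orient outward: away from the adjacent element centroid
    cent = verts[tris[b_elem]].mean(axis=1)
    mid = 0.5 * (pa + pb)
    flip = np.einsum("fd,fd->f", normal, mid - cent) < 0
    normal[flip] *= -1

    # P2 gradients at facet midpoints (barycentric coords of midpoint)
    b_gphi = np.empty((nf, 6, 2))
    for k in range(nf):
        e = b_elem[k]
        tri = tris[e]
        # barycentric of midpoint in element e
        T = np.column_stack([verts[tri[1]] - verts[tri[0]],
                             verts[tri[2]] - verts[tri[0]]])
        xi = np.linalg.solve(T, mid[k] - verts[tri[0]])
        lam = np.array([1 - xi[0] - xi[1], xi[0], xi[1]])
        _, d = p2_basis(lam[None, :])
        b_gphi[k] = np.einsum("ak,kd->ad", d[0], grad_lam[e])

    return P2Space(mesh=mesh, scale=scale, verts=verts, tris=tris, tri6=tri6,
                   coords=coords, n_vert=nv, n_p2=n_p2, area=area,
                   grad_lam=grad_lam, phi_q=phi_q, gphi_q=gphi_q,
                   gphi_x=np.ascontiguousarray(gphi_q[..., 0]),
                   gphi_y=np.ascontiguousarray(gphi_q[..., 1]), wdet=wdet,
                   b_edges=b_edges, b_mid=b_mid, b_tags=mesh.edge_tags,
                   b_arclength=mesh.edge_arclength, b_length=b_length,
                   b_normal=normal, b_elem=b_elem, b_gphi=b_gphi,
                   b_phi6=tri6[b_elem])


# ---------------------------------------------------------------------------
# operator assembly
# ---------------------------------------------------------------------------

def mass_matrix(space: P2Space) -> sp.csr_matrix:
    """P2 scalar mass matrix."""
    loc = np.einsum("eq,qa,qb->eab", space.wdet, space.phi_q, space.phi_q)
    i = np.repeat(space.tri6, 6, axis=1).ravel()
    j = np.tile(space.tri6, (1, 6)).ravel()
    return sp.coo_matrix((loc.ravel(), (i, j)),
                         shape=(space.n_p2, space.n_p2)).tocsr()


def stiffness_blocks(space: P2Space, mu: float):
    """Constant-viscosity stress-form viscous blocks (Kxx, Kxy, Kyx, Kyy).

    a(u,v) = int 2 mu D(u):D(v).
    """
    gx = space.gphi_q[..., 0]
    gy = space.gphi_q[..., 1]
    w = space.wdet * mu
    kxx = np.einsum("eq,eqa,eqb->eab", w, gx, 2 * gx) + \
        np.einsum("eq,eqa,eqb->eab", w, gy, gy)
    kyy = np.einsum("eq,eqa,eqb->eab", w, gy, 2 * gy) + \
        np.einsum("eq,eqa,eqb->eab", w, gx, gx)
    kxy = np.einsum("eq,eqa,eqb->eab", w, gy, gx)  # test x-row, trial uy
    kyx = np.einsum("eq,eqa,eqb->eab", w, gx, gy)
    i = np.repeat(space.tri6, 6, axis=1).ravel()
    j = np.tile(space.tri6, (1, 6)).ravel()

    def mk(loc):
        return sp.coo_matrix((loc.ravel(), (i, j)),
                             shape=(space.n_p2, space.n_p2)).tocsr()

    return mk(kxx), mk(kxy), mk(kyx), mk(kyy)


def divergence_blocks(space: P2Space):
    """Bx, By with (B u)_k = int lambda_k (dux/dx + duy/dy)."""
    lam_q = QUAD_BARY  # P1 basis values at quadrature points
    gx = space.gphi_q[..., 0]
    gy = space.gphi_q[..., 1]
    bx = np.einsum("eq,qk,eqa->eka", space.wdet, lam_q, gx)
    by = np.einsum("eq,qk,eqa->eka", space.wdet, lam_q, gy)
    i = np.repeat(space.tris, 6, axis=1).ravel()
    j = np.tile(space.tri6, (1, 3)).ravel()
    shape = (space.n_vert, space.n_p2)
    Bx = sp.coo_matrix((bx.ravel(), (i, j)), shape=shape).tocsr()
    By = sp.coo_matrix((by.ravel(), (i, j)), shape=shape).tocsr()
    return Bx, By


def quad_fields(space: P2Space, ux: np.ndarray, uy: np.ndarray):
    """Velocity and gradient at quadrature points.

    Returns (u (ne,nq,2), grad (ne,nq,2,2)) with grad[...,i,j] = du_i/dx_j.
    """
    ex = ux[space.tri6]  # (ne,6)
    ey = uy[space.tri6]
    uq = np.stack([np.einsum("qa,ea->eq", space.phi_q, ex),
                   np.einsum("qa,ea->eq", space.phi_q, ey)], axis=-1)
    gx = np.einsum("eqad,ea->eqd", space.gphi_q, ex)
    gy = np.einsum("eqad,ea->eqd", space.gphi_q, ey)
    grad = np.stack([gx, gy], axis=-2)  # (ne,nq,2(comp),2(deriv))
    return uq, grad


def shear_rate(grad: np.ndarray) -> np.ndarray:
    """gamma_dot = sqrt(2 D:D) at quadrature points, (ne,nq)."""
    dxx = grad[..., 0, 0]
    dyy = grad[..., 1, 1]
    dxy = 0.5 * (grad[..., 0, 1] + grad[..., 1, 0])
    return np.sqrt(2.0 * (dxx**2 + dyy**2 + 2.0 * dxy**2))


def convection_vector(space: P2Space, rho: float, wx, wy, ux, uy):
    """Explicit convection residual int rho (w . grad u) . phi."""
    wq, _ = quad_fields(space, wx, wy)
    _, gu = quad_fields(space, ux, uy)
    adv = np.einsum("eqd,eqcd->eqc", wq, gu)  # (ne,nq,2)
    coef = space.wdet[..., None] * rho * adv  # (ne,nq,2)
    rx = np.einsum("eq,qa->ea", coef[..., 0], space.phi_q)
    ry = np.einsum("eq,qa->ea", coef[..., 1], space.phi_q)
    out_x = np.zeros(space.n_p2)
    out_y = np.zeros(space.n_p2)
    np.add.at(out_x, space.tri6.ravel(), rx.ravel())
    np.add.at(out_y, space.tri6.ravel(), ry.ravel())
    return out_x, out_y


def explicit_residual(space: P2Space, rho: float, ux, uy,
                      mu_corr=None):
    """Fused explicit residual: convection plus variable-viscosity stress.

    Returns (rx, ry) with r_i = int [rho (u.grad u).phi_i
    + 2 (mu(gamma)-mu_ref) D(u):D(phi_i)]; ``mu_corr`` maps the shear rate
    at quadrature points to the viscosity correction (None for a purely
    Newtonian run, which skips the stress term entirely).
    """
    ex = ux[space.tri6]
    ey = uy[space.tri6]
    phiT = space.phi_q.T          # (6,nq)
    uqx = ex @ phiT               # (ne,nq)
    uqy = ey @ phiT
    dux_dx = np.einsum("eqa,ea->eq", space.gphi_x, ex)
    dux_dy = np.einsum("eqa,ea->eq", space.gphi_y, ex)
    duy_dx = np.einsum("eqa,ea->eq", space.gphi_x, ey)
    duy_dy = np.einsum("eqa,ea->eq", space.gphi_y, ey)
    w = space.wdet
    cx = w * rho * (uqx * dux_dx + uqy * dux_dy)
    cy = w * rho * (uqx * duy_dx + uqy * duy_dy)
    rx_e = cx @ space.phi_q       # (ne,6)
    ry_e = cy @ space.phi_q
    if mu_corr is not None:
        dxy = 0.5 * (dux_dy + duy_dx)
        gamma = np.sqrt(2.0 * (dux_dx**2 + duy_dy**2 + 2.0 * dxy**2))
        m = 2.0 * w * mu_corr(gamma)
        sxx = m * dux_dx
        syy = m * duy_dy
        sxy = m * dxy
        rx_e += np.einsum("eq,eqa->ea", sxx, space.gphi_x) \
            + np.einsum("eq,eqa->ea", sxy, space.gphi_y)
        ry_e += np.einsum("eq,eqa->ea", sxy, space.gphi_x) \
            + np.einsum("eq,eqa->ea", syy, space.gphi_y)
    idx = space.tri6.ravel()
    rx = np.bincount(idx, weights=rx_e.ravel(), minlength=space.n_p2)
    ry = np.bincount(idx, weights=ry_e.ravel(), minlength=space.n_p2)
    return rx, ry


def convection_matrix(space: P2Space, rho: float, wx, wy) -> sp.csr_matrix:
    """Implicit Oseen convection block int rho (w . grad phi_j) phi_i."""
    wq, _ = quad_fields(space, wx, wy)
    # (w . grad phi_b) at quad points: (ne,nq,6)
    wg = np.einsum("eqd,eqbd->eqb", wq, space.gphi_q)
    loc = np.einsum("eq,qa,eqb->eab", space.wdet * rho, space.phi_q, wg)
    i = np.repeat(space.tri6, 6, axis=1).ravel()
    j = np.tile(space.tri6, (1, 6)).ravel()
    return sp.coo_matrix((loc.ravel(), (i, j)),
                         shape=(space.n_p2, space.n_p2)).tocsr()


def variable_viscosity_vector(space: P2Space, mu_q: np.ndarray, ux, uy):
    """Residual int 2 mu(x) D(u):D(phi) with mu given at quad points."""
    _, gu = quad_fields(space, ux, uy)
    dxx = gu[..., 0, 0]
    dyy = gu[..., 1, 1]
    dxy = 0.5 * (gu[..., 0, 1] + gu[..., 1, 0])
    w = space.wdet * mu_q
    sxx = 2.0 * w * dxx
    syy = 2.0 * w * dyy
    sxy = 2.0 * w * dxy
    gx = space.gphi_q[..., 0]
    gy = space.gphi_q[..., 1]
    rx = np.einsum("eq,eqa->ea", sxx, gx) + np.einsum("eq,eqa->ea", sxy, gy)
    ry = np.einsum("eq,eqa->ea", sxy, gx) + np.einsum("eq,eqa->ea", syy, gy)
    out_x = np.zeros(space.n_p2)
    out_y = np.zeros(space.n_p2)
    np.add.at(out_x, space.tri6.ravel(), rx.ravel())
    np.add.at(out_y, space.tri6.ravel(), ry.ravel())
    return out_x, out_y


# ---------------------------------------------------------------------------
# boundary integrals
# ---------------------------------------------------------------------------

def facet_flux(space: P2Space, ux, uy, sel: np.ndarray) -> float:
    """int u.n over selected boundary facets (Simpson, exact for P2)."""
    e = space.b_edges[sel]
    m = space.b_mid[sel]
    n = space.b_normal[sel]
    ell = space.b_length[sel]
    un0 = ux[e[:, 0]] * n[:, 0] + uy[e[:, 0]] * n[:, 1]
    un1 = ux[e[:, 1]] * n[:, 0] + uy[e[:, 1]] * n[:, 1]
    unm = ux[m] * n[:, 0] + uy[m] * n[:, 1]
    return float(np.sum(ell / 6.0 * (un0 + 4.0 * unm + un1)))


def traction_rhs(space: P2Space, p_out: float, sel: np.ndarray):
    """RHS of the weak natural condition with traction -p_out n."""
    rx = np.zeros(space.n_p2)
    ry = np.zeros(space.n_p2)
    e = space.b_edges[sel]
    m = space.b_mid[sel]
    n = space.b_normal[sel]
    ell = space.b_length[sel]
    # int phi over a straight P2 edge: l/6 per vertex, 2l/3 for midpoint
    for comp, out in ((0, rx), (1, ry)):
        np.add.at(out, e[:, 0], -p_out * n[:, comp] * ell / 6.0)
        np.add.at(out, e[:, 1], -p_out * n[:, comp] * ell / 6.0)
        np.add.at(out, m, -p_out * n[:, comp] * 2.0 * ell / 3.0)
    return rx, ry


def wall_traction(space: P2Space, sel: np.ndarray, ux, uy, mu_of_gamma):
    """Tangential viscous traction (WSS vector, Pa) at selected facets.

    Evaluates grad u at each facet midpoint from the adjacent element,
    computes the full viscous traction 2 mu D n with mu from the local shear
    rate, and removes the normal component.
    """
    idx = np.where(sel)[0]
    gphi = space.b_gphi[idx]          # (nf,6,2)
    dofs = space.b_phi6[idx]          # (nf,6)
    exu = ux[dofs]
    eyu = uy[dofs]
    gxu = np.einsum("fad,fa->fd", gphi, exu)  # grad ux
    gyu = np.einsum("fad,fa->fd", gphi, eyu)
    dxx = gxu[:, 0]
    dyy = gyu[:, 1]
    dxy = 0.5 * (gxu[:, 1] + gyu[:, 0])
    gamma = np.sqrt(2.0 * (dxx**2 + dyy**2 + 2.0 * dxy**2))
    mu = mu_of_gamma(gamma)
    n = space.b_normal[idx]
    tx = 2.0 * mu * (dxx * n[:, 0] + dxy * n[:, 1])
    ty = 2.0 * mu * (dxy * n[:, 0] + dyy * n[:, 1])
    tn = tx * n[:, 0] + ty * n[:, 1]
    return np.column_stack([tx - tn * n[:, 0], ty - tn * n[:, 1]])


# ---------------------------------------------------------------------------
# point sampling
# ---------------------------------------------------------------------------

class FieldSampler:
    """Interpolate P2 fields at arbitrary points via a trapezoid-map locator."""

    def __init__(self, space: P2Space):
        from matplotlib.tri import Triangulation, TrapezoidMapTriFinder
        self.space = space
        self._tri = Triangulation(space.verts[:, 0], space.verts[:, 1],
                                  space.tris)
        self._finder = TrapezoidMapTriFinder(self._tri)

    def locate(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        return self._finder(pts[:, 0], pts[:, 1]).astype(int)

    def prepare(self, pts: np.ndarray):
        """Precompute basis values/dofs for repeated sampling at fixed pts."""
        space = self.space
        pts = np.atleast_2d(pts)
        el = self.locate(pts)
        if np.any(el < 0):
            raise ValueError("sample point outside the mesh")
        tri = space.tris[el]
        p0 = space.verts[tri[:, 0]]
        T = np.stack([space.verts[tri[:, 1]] - p0,
                      space.verts[tri[:, 2]] - p0], axis=-1)
        rhs = pts - p0
        det = T[:, 0, 0] * T[:, 1, 1] - T[:, 0, 1] * T[:, 1, 0]
        xi = (T[:, 1, 1] * rhs[:, 0] - T[:, 0, 1] * rhs[:, 1]) / det
        eta = (-T[:, 1, 0] * rhs[:, 0] + T[:, 0, 0] * rhs[:, 1]) / det
        phi, _ = p2_basis(np.column_stack([1 - xi - eta, xi, eta]))
        return phi, space.tri6[el]

    @staticmethod
    def eval_prepared(field: np.ndarray, prep) -> np.ndarray:
        phi, dofs = prep
        return np.einsum("fa,fa->f", phi, field[dofs])

    def sample(self, field: np.ndarray, pts: np.ndarray,
               strict: bool = True) -> np.ndarray:
        """Values of a P2 nodal field at points (m); NaN outside if not strict."""
        space = self.space
        pts = np.atleast_2d(pts)
        el = self.locate(pts)
        out = np.full(len(pts), np.nan)
        ok = el >= 0
        if strict and not np.all(ok):
            raise ValueError("sample point outside the mesh")
        if not np.any(ok):
            return out
        e = el[ok]
        tri = space.tris[e]
        p0 = space.verts[tri[:, 0]]
        T = np.stack([space.verts[tri[:, 1]] - p0,
                      space.verts[tri[:, 2]] - p0], axis=-1)
        rhs = pts[ok] - p0
        det = T[:, 0, 0] * T[:, 1, 1] - T[:, 0, 1] * T[:, 1, 0]
        xi = (T[:, 1, 1] * rhs[:, 0] - T[:, 0, 1] * rhs[:, 1]) / det
        eta = (-T[:, 1, 0] * rhs[:, 0] + T[:, 0, 0] * rhs[:, 1]) / det
        lam = np.column_stack([1 - xi - eta, xi, eta])
        phi, _ = p2_basis(lam)
        vals = field[space.tri6[e]]
        out[ok] = np.einsum("fa,fa->f", phi, vals)
        return out
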