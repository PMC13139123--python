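"""Hemodynamic wall metrics and flow-pattern diagnostics.

From a recorded wall-shear history this module computes, per wall facet,

* TAWSS  = (1/T) int_0^T |tau(t)| dt          (reported in dyn/cm^2),
* OSI    = 0.5 (1 - |int tau dt| / int |tau| dt)   in [0, 0.5],

and aggregates them into length-weighted medial/lateral region means, the
lateral high-OSI (> 0.2) arc fraction, and the recirculation-vortex core
location found from the streamfunction of a velocity snapshot at the
peak-flow phase.  TAWSS < 4 dyn/cm^2 and OSI > 0.2 are the atherogenic
thresholds used when interpreting the maps.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import fem
from .geometry import BifurcationSpec
from .solver import FlowState, RunResult, WallShearHistory

__all__ = ["WallMetricField", "RegionSummary", "VortexInfo",
           "tawss", "osi", "region_summary", "oscillation_zone_summary",
           "locate_vortex", "streamfunction",
           "OSI_THRESHOLD", "ATHEROGENIC_TAWSS"]

log = logging.getLogger(__name__)

PA_TO_DYN_CM2 = 10.0
#: OSI above this marks significantly oscillatory flow.
OSI_THRESHOLD = 0.2
#: TAWSS below this (dyn/cm^2) is treated as atherogenic.
ATHEROGENIC_TAWSS = 4.0


def _check_history(history: WallShearHistory) -> None:
    t = history.times
    if len(t) < 3:
        raise ValueError("history needs at least 3 recorded steps")
    dt = np.diff(t)
    if np.any(dt <= 0) or np.max(dt) > 2.05 * np.median(dt):
        raise ValueError("history has gaps larger than 2 steps")
    span = t[-1] - t[0]
    if span < 0.9 * history.period * (1 - 1.0 / len(t)):
        raise ValueError("history does not span a full period")


def tawss(history: WallShearHistory) -> np.ndarray:
    """Per-facet time-averaged WSS magnitude, dyn/cm^2."""
    _check_history(history)
    mag = np.hypot(history.tau[..., 0], history.tau[..., 1])
    integral = np.trapezoid(mag, history.times, axis=0)
    span = history.times[-1] - history.times[0]
    return integral / span * PA_TO_DYN_CM2


def osi(history: WallShearHistory) -> np.ndarray:
    """Per-facet oscillatory shear index in [0, 0.5].

    0.5 (1 - |int tau dt| / int |tau| dt); facets with zero shear all cycle
    are defined to have OSI 0 (no direction change can be registered).
    """
    _check_history(history)
    mag = np.hypot(history.tau[..., 0], history.tau[..., 1])
    num = np.linalg.norm(
        np.trapezoid(history.tau, history.times, axis=0), axis=-1)
    den = np.trapezoid(mag, history.times, axis=0)
    out = np.zeros(history.tau.shape[1])
    nz = den > 0
    out[nz] = 0.5 * (1.0 - num[nz] / den[nz])
    # a time-constant vector trivially never changes direction: exactly 0,
    # independent of quadrature round-off
    constant = np.all(history.tau == history.tau[0][None, ...], axis=(0, 2))
    out[constant] = 0.0
    return np.clip(out, 0.0, 0.5)


@dataclass
class WallMetricField:
    """Per-facet wall metrics with geometry metadata."""

    tawss: np.ndarray        # dyn/cm^2
    osi: np.ndarray
    arclength: np.ndarray    # mm from the ostium (NaN off the VAO)
    tags: np.ndarray
    lengths_mm: np.ndarray

    @classmethod
    def from_history(cls, history: WallShearHistory) -> "WallMetricField":
        return cls(tawss=tawss(history), osi=osi(history),
                   arclength=history.arclength, tags=history.tags,
                   lengths_mm=history.lengths_mm)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"tag": self.tags, "arclength_mm": self.arclength,
                             "tawss_dyn_cm2": self.tawss, "osi": self.osi,
                             "facet_length_mm": self.lengths_mm})


@dataclass
class VortexInfo:
    found: bool
    position_mm: Optional[np.ndarray] = None
    label: str = "none"
    strength: float = 0.0


@dataclass
class RegionSummary:
    """Length-weighted medial/lateral summaries for one bifurcation angle."""

    theta: float
    tawss_medial: float
    tawss_lateral: float
    osi_medial: float
    osi_lateral: float
    high_osi_fraction_lateral: float
    vortex: VortexInfo

    def as_dict(self) -> dict:
        return {
            "theta": self.theta,
            "tawss_medial_dyn_cm2": self.tawss_medial,
            "tawss_lateral_dyn_cm2": self.tawss_lateral,
            "osi_medial": self.osi_medial,
            "osi_lateral": self.osi_lateral,
            "high_osi_fraction_lateral": self.high_osi_fraction_lateral,
            "vortex_found": self.vortex.found,
            "vortex_label": self.vortex.label,
            "vortex_x_mm": (self.vortex.position_mm[0]
                            if self.vortex.position_mm is not None else np.nan),
            "vortex_y_mm": (self.vortex.position_mm[1]
                            if self.vortex.position_mm is not None else np.nan),
        }


def _weighted_mean(values, weights, sel) -> float:
    w = weights[sel]
    if w.sum() == 0 or not np.any(sel):
        raise ValueError("empty wall region")
    return float(np.sum(values[sel] * w) / w.sum())


def region_summary(field: WallMetricField, result: Optional[RunResult] = None,
                   spec: Optional[BifurcationSpec] = None,
                   osi_threshold: float = OSI_THRESHOLD) -> RegionSummary:
    """Aggregate per-facet metrics into the medial/lateral region summary.

    If a run result (with snapshots) is supplied, the recirculation vortex is
    located at the peak-flow phase and attached.
    """
    med = field.tags == "wall_medial"
    lat = field.tags == "wall_lateral"
    if not med.any() or not lat.any():
        raise ValueError("mesh has no tagged medial/lateral VAO walls")
    w = field.lengths_mm
    high = field.osi > osi_threshold
    frac = float(np.sum(w[lat & high]) / np.sum(w[lat]))
    vortex = VortexInfo(found=False)
    theta = float("nan")
    if spec is None and result is not None and result.mesh.spec is not None:
        spec = result.mesh.spec
    if spec is not None:
        theta = spec.theta
    if result is not None and len(result.snapshots) and spec is not None:
        vortex = locate_vortex(result, spec)
    return RegionSummary(
        theta=theta,
        tawss_medial=_weighted_mean(field.tawss, w, med),
        tawss_lateral=_weighted_mean(field.tawss, w, lat),
        osi_medial=_weighted_mean(field.osi, w, med),
        osi_lateral=_weighted_mean(field.osi, w, lat),
        high_osi_fraction_lateral=frac,
        vortex=vortex)


def oscillation_zone_summary(field: WallMetricField,
                             threshold: float = OSI_THRESHOLD) -> dict:
    """Metrics averaged over the lateral critical-oscillation zone.

    Optional alternative segmentation: instead of the whole tagged lateral
    wall, average over the largest arc-connected component of lateral facets
    with OSI above ``threshold`` (the oscillation zone near the ostium).
    Returns NaNs when no facet exceeds the threshold.
    """
    lat = np.where(field.tags == "wall_lateral")[0]
    order = lat[np.argsort(field.arclength[lat])]
    hot = field.osi[order] > threshold
    if not hot.any():
        return {"zone_mean_osi": float("nan"),
                "zone_mean_tawss_dyn_cm2": float("nan"),
                "zone_arc_mm": 0.0, "n_facets": 0}
    # largest run of consecutive above-threshold facets along the wall
    best, cur = [], []
    for k, flag in enumerate(hot):
        if flag:
            cur.append(k)
        else:
            if len(cur) > len(best):
                best = cur
            cur = []
    if len(cur) > len(best):
        best = cur
    idx = order[best]
    w = field.lengths_mm[idx]
    return {"zone_mean_osi": float(np.sum(field.osi[idx] * w) / w.sum()),
            "zone_mean_tawss_dyn_cm2":
                float(np.sum(field.tawss[idx] * w) / w.sum()),
            "zone_arc_mm": float(w.sum()), "n_facets": int(len(idx))}


# ---------------------------------------------------------------------------
# streamfunction and vortex core
# ---------------------------------------------------------------------------

def streamfunction(space: fem.P2Space, state: FlowState) -> np.ndarray:
    """Best-fit P1 streamfunction psi with grad psi ~ (-uy, ux).

    Solves the weak Poisson problem int grad psi . grad v =
    int (-uy, ux) . grad v with one pinned node; exact when the velocity is
    divergence-free, and insensitive to through-flow boundaries.
    """
    nv = space.n_vert
    tris = space.tris
    gl = space.grad_lam                      # (ne,3,2)
    area = space.area
    # P1 stiffness
    loc = np.einsum("e,ekd,eld->ekl", area, gl, gl)
    i = np.repeat(tris, 3, axis=1).ravel()
    j = np.tile(tris, (1, 3)).ravel()
    K = sp.coo_matrix((loc.ravel(), (i, j)), shape=(nv, nv)).tocsr()
    # rhs: rotated velocity averaged elementwise from vertex values
    rot = np.column_stack([-state.uy[:nv], state.ux[:nv]])
    r_elem = rot[tris].mean(axis=1)          # (ne,2)
    contrib = np.einsum("e,ekd,ed->ek", area, gl, r_elem)
    rhs = np.bincount(tris.ravel(), weights=contrib.ravel(), minlength=nv)
    # pin node 0
    K = K.tolil()
    K[0, :] = 0.0
    K[0, 0] = 1.0
    rhs[0] = 0.0
    return spla.spsolve(K.tocsc(), rhs)


def _vertex_neighbors(tris: np.ndarray, nv: int):
    neigh = [set() for _ in range(nv)]
    for a, b, c in tris:
        neigh[a].update((b, c))
        neigh[b].update((a, c))
        neigh[c].update((a, b))
    return neigh


def locate_vortex(result: RunResult, spec: BifurcationSpec,
                  snapshot: Optional[FlowState] = None) -> VortexInfo:
    """Vortex core in the VAO/junction region at the peak-flow phase.

    The streamfunction of the chosen snapshot (default: the snapshot with
    the largest mean kinetic energy, i.e. peak flow) is restricted to the
    junction region; interior local extrema of psi are vortex-core
    candidates.  A candidate is a closed recirculation when its psi value
    lies outside the band spanned by the two VAO wall streamlines - such a
    streamline cannot connect to any inlet or outlet, so it must close on
    itself - or, for cores away from walls, when the velocity direction
    winds by +-1 around a small circle.  The strongest core (largest psi
    excursion beyond the through-flow band, a circulation proxy) is returned
    and labelled lateral-proximal / central / medial-proximal by the
    cross-channel coordinate third it falls in.  Returns found=False when no
    closed recirculation exists.
    """
    if len(result.snapshots) < 1:
        raise ValueError("need at least one snapshot")
    space = result.space
    if snapshot is None:
        # peak-flow phase: snapshot with max mean speed
        speeds = [float(np.mean(s.speed())) for s in result.snapshots]
        snapshot = result.snapshots[int(np.argmax(speeds))]
    psi = streamfunction(space, snapshot)
    nv = space.n_vert
    verts_mm = space.verts * 1e3
    C, d, n = spec.junction_center, spec.branch_dir, spec.branch_normal
    rel = verts_mm - C
    s = rel @ d
    q = rel @ n
    w = spec.d_va
    region = (verts_mm[:, 1] > spec.d_sca - 1.5 * w) & (s > -2.0 * w) \
        & (np.abs(q) < 2.0 * w) & (s < spec.l_vao)
    boundary = np.zeros(nv, dtype=bool)
    boundary[np.unique(space.b_edges)] = True

    neigh = _vertex_neighbors(space.tris, nv)
    cands = []
    for v in np.where(region & ~boundary)[0]:
        nb = list(neigh[v])
        if len(nb) < 3:
            continue
        pv = psi[v]
        pn = psi[nb]
        if np.all(pv > pn + 1e-18) or np.all(pv < pn - 1e-18):
            cands.append(v)
    if not cands:
        return VortexInfo(found=False)

    # through-flow streamfunction band: the two VAO wall streamlines
    lat_nodes = np.unique(space.b_edges[space.b_tags == "wall_lateral"])
    med_nodes = np.unique(space.b_edges[space.b_tags == "wall_medial"])
    psi_scale = float(psi.max() - psi.min())
    tol = 1e-6 * max(psi_scale, 1e-300)
    if len(lat_nodes) and len(med_nodes):
        p_lo = min(float(np.median(psi[lat_nodes])),
                   float(np.median(psi[med_nodes])))
        p_hi = max(float(np.median(psi[lat_nodes])),
                   float(np.median(psi[med_nodes])))
    else:  # no tagged branch walls (e.g. plain channel): empty band
        p_lo = p_hi = None

    sampler = fem.FieldSampler(space)
    confirmed = []
    for v in cands:
        pv = psi[v]
        strength = 0.0
        if p_lo is not None:
            strength = float(max(p_lo - pv, pv - p_hi))
            if strength > tol:
                confirmed.append((strength, v))
                continue
        # fallback: velocity-direction winding on a small circle
        centre = space.verts[v]
        local_h = np.mean([np.linalg.norm(space.verts[u] - centre)
                           for u in neigh[v]])
        for radius in (1.2 * local_h, 0.7 * local_h):
            ang = np.linspace(0, 2 * math.pi, 49)[:-1]
            pts = centre + radius * np.column_stack([np.cos(ang), np.sin(ang)])
            try:
                vx = sampler.sample(snapshot.ux, pts)
                vy = sampler.sample(snapshot.uy, pts)
            except ValueError:
                continue
            sp_ang = np.unwrap(np.arctan2(vy, vx))
            winding = (sp_ang[-1] - sp_ang[0]
                       + (sp_ang[1] - sp_ang[0])) / (2 * math.pi)
            if abs(abs(winding) - 1.0) < 0.25:
                confirmed.append((max(strength, tol), v))
                break
    if not confirmed:
        return VortexInfo(found=False)
    if len(confirmed) > 1:
        log.info("multiple vortex cores found (%d); keeping the strongest",
                 len(confirmed))
    strength, v = max(confirmed)
    pos = verts_mm[v]
    qv = (pos - C) @ n
    xi = float(np.clip((qv + 0.5 * w) / w, 0.0, 1.0))
    label = ("medial-proximal" if xi <= 1 / 3
             else "lateral-proximal" if xi >= 2 / 3 else "central")
    return VortexInfo(found=True, position_mm=pos, label=label,
                      strength=strength)
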