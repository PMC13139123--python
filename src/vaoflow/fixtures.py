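"""Small deterministic fixtures for tests and demos.

Everything is generated programmatically from one seed: a coarse 50-degree
bifurcation mesh, a short synthetic wall-shear history with known TAWSS/OSI
(including a perfect-reversal facet with OSI exactly 0.5), an exactly
second-order refinement triple for the GCI machinery, and a 500-artery
cohort.
"""

from __future__ import annotations

import numpy as np

from .clinical import CohortSpec, generate_cohort
from .gci import RefinementStudy
from .geometry import BifurcationSpec, build_bifurcation, generate_mesh
from .solver import WallShearHistory

__all__ = ["make_fixtures", "synthetic_wall_history",
           "second_order_refinement_triple"]


def synthetic_wall_history(n_steps: int = 10, period: float = 0.8
                           ) -> WallShearHistory:
    """Four-facet analytic history with known metric values.

    facet 0: constant 0.2 Pa along +x        -> TAWSS 2 dyn/cm2, OSI 0
    facet 1: 0.3 sin(wt) Pa along +x         -> perfect reversal, OSI 0.5,
                                                TAWSS -> (2/pi)*3 dyn/cm2
    facet 2: 1 + 0.5 sin(wt) Pa along +x     -> OSI 0 (never reverses)
    facet 3: zero shear                      -> TAWSS 0, OSI 0 by convention
    """
    t = np.linspace(0.0, period, n_steps + 1)
    nf = 4
    tau = np.zeros((len(t), nf, 2))
    tau[:, 0, 0] = 0.2
    w = 2 * np.pi / period
    tau[:, 1, 0] = 0.3 * np.sin(w * t)
    tau[:, 2, 0] = 1.0 + 0.5 * np.sin(w * t)
    tags = np.array(["wall_lateral", "wall_lateral", "wall_medial",
                     "wall_medial"], dtype=object)
    return WallShearHistory(times=t, tau=tau, tags=tags,
                            arclength=np.arange(nf, dtype=float),
                            lengths_mm=np.ones(nf), period=period,
                            cap=None)


def second_order_refinement_triple(f_star: float = 4.0, c: float = 0.9,
                                   r: float = 2.0, h0: float = 0.4
                                   ) -> RefinementStudy:
    """f(h) = f* + c h^2 sampled at (h0 r, h0... ) -> observed order 2."""
    hs = np.array([h0 * r * r, h0 * r, h0])
    vals = f_star + c * hs**2
    n = np.round(1000.0 / hs**2).astype(int)
    return RefinementStudy(h=hs, n_elements=n, values=vals)


def make_fixtures(seed: int = 0) -> dict:
    """Bundle of deterministic fixtures; identical for identical seeds."""
    mesh = generate_mesh(build_bifurcation(BifurcationSpec(theta=50.0)), 0.8)
    cohort = generate_cohort(CohortSpec(n_arteries=500, seed=seed))
    return {
        "mesh_theta50_coarse": mesh,
        "wall_history": synthetic_wall_history(),
        "refinement_triple": second_order_refinement_triple(),
        "cohort500": cohort,
    }
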