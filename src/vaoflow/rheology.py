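"""Casson non-Newtonian blood rheology.

Blood is shear-thinning: its apparent viscosity falls from a large value at
low shear (red-cell aggregation) toward an asymptote ``mu_inf`` at high shear.
The Casson model captures this with a yield-like square-root law; here it is
used in apparent-viscosity form

    mu(gdot) = (sqrt(mu_inf) + N_inf / sqrt(gdot))^2
             = mu_inf + 2 sqrt(mu_inf) N_inf gdot^(-1/2) + N_inf^2 / gdot

with ``N_inf = mu_p (1 - Hct)^(-1/4)`` the hematocrit correction built from
the plasma viscosity mu_p.  The 1/gdot singularity at stagnation points is
regularised by clamping the shear rate below at ``gamma_floor``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = ["CassonParams", "n_infinity", "mu_infinity", "apparent_viscosity",
           "shear_thinning_check", "export_viscosity_curve"]

#: Proportionality constant for the sqrt(Hct) form of the asymptotic
#: viscosity, Pa.s.  Calibrated so that Hct = 0.4 gives the standard
#: high-shear blood viscosity 0.0035 Pa.s; kept for sensitivity studies only
#: (the default parameter set pins mu_inf by override instead).
MU_INF_SQRT_HCT_COEFF = 0.0035 / math.sqrt(0.4)


@dataclass(frozen=True)
class CassonParams:
    """Casson blood parameters (SI units).

    mu_p : plasma viscosity, Pa.s
    hct : hematocrit volume fraction in (0, 1)
    gamma_floor : low-shear regularisation floor, 1/s
    mu_infty_override : if set, the high-shear asymptotic viscosity, Pa.s
    newtonian_mu : viscosity used when the model is switched to Newtonian
    density : blood density, kg/m^3
    newtonian : if True, apparent_viscosity is the constant newtonian_mu
    """

    mu_p: float = 0.00145
    hct: float = 0.4
    gamma_floor: float = 1e-3
    mu_infty_override: Optional[float] = 0.0035
    newtonian_mu: float = 0.0035
    density: float = 1060.0
    newtonian: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.hct < 1.0:
            raise ValueError(f"hct must lie in [0, 1), got {self.hct}")
        if self.mu_p <= 0:
            raise ValueError("mu_p must be positive")
        if self.gamma_floor <= 0:
            raise ValueError("gamma_floor must be positive")
        if self.newtonian_mu <= 0:
            raise ValueError("newtonian_mu must be positive")
        if self.density <= 0:
            raise ValueError("density must be positive")

    def reference_viscosity(self) -> float:
        """High-shear viscosity used for linear analytic solutions, Pa.s."""
        return self.newtonian_mu if self.newtonian else mu_infinity(self)


def n_infinity(params: CassonParams) -> float:
    """Hematocrit correction coefficient N_inf = mu_p (1 - Hct)^(-1/4)."""
    if params.hct >= 1.0:
        raise ValueError("hct must be below 1")
    if params.newtonian:
        return 0.0
    return params.mu_p * (1.0 - params.hct) ** (-0.25)


def mu_infinity(params: CassonParams) -> float:
    """Asymptotic high-shear viscosity, Pa.s.

    Uses the explicit override when set (the default, 0.0035 Pa.s); otherwise
    a sqrt(Hct)-proportional form, monotone increasing in red-cell
    concentration as the model requires.
    """
    if params.mu_infty_override is not None:
        mu = float(params.mu_infty_override)
    else:
        mu = MU_INF_SQRT_HCT_COEFF * math.sqrt(max(params.hct, 0.0))
    if mu <= 0:
        raise ValueError("asymptotic viscosity must be positive")
    return mu


def apparent_viscosity(params: CassonParams, gamma_dot):
    """Apparent viscosity mu(gdot) in Pa.s; gdot in 1/s, scalar or array.

    gdot is clamped below at params.gamma_floor; negative shear rates are
    rejected (shear rate is a magnitude).
    """
    g = np.asarray(gamma_dot, dtype=float)
    if np.any(g < 0):
        raise ValueError("shear rate must be non-negative")
    if params.newtonian:
        out = np.full_like(g, params.newtonian_mu, dtype=float)
        return float(out) if g.ndim == 0 else out
    g_r = np.maximum(g, params.gamma_floor)
    mu_inf = mu_infinity(params)
    n_inf = n_infinity(params)
    out = (math.sqrt(mu_inf) + n_inf / np.sqrt(g_r)) ** 2
    return float(out) if g.ndim == 0 else out


def shear_thinning_check(params, grid: Sequence[float]) -> bool:
    """True iff the apparent viscosity is non-increasing along ``grid``.

    ``params`` is a :class:`CassonParams` or any callable mu(gdot) (the
    latter lets corrupted parameterisations, e.g. a negative N_inf, be
    audited).  The grid must be strictly increasing and positive.  A
    non-monotone curve triggers a warning.
    """
    g = np.asarray(grid, dtype=float)
    if g.ndim != 1 or len(g) < 2:
        raise ValueError("grid must be a 1D sequence of at least two rates")
    if np.any(g <= 0) or np.any(np.diff(g) <= 0):
        raise ValueError("grid must be strictly increasing and positive")
    mu_of = params if callable(params) and not isinstance(params, CassonParams) \
        else (lambda x: apparent_viscosity(params, x))
    mu = np.atleast_1d(mu_of(g))
    ok = bool(np.all(np.diff(mu) <= 1e-15 + 1e-12 * np.abs(mu[:-1])))
    if not ok:
        warnings.warn("apparent viscosity is not shear-thinning on this grid",
                      RuntimeWarning, stacklevel=2)
    return ok


def export_viscosity_curve(params: CassonParams, path,
                           gmin: float = 1e-2, gmax: float = 1e4,
                           n: int = 200) -> None:
    """Write mu(gdot) over a log-spaced grid to a 2-column CSV."""
    g = np.logspace(math.log10(gmin), math.log10(gmax), n)
    mu = apparent_viscosity(params, g)
    np.savetxt(path, np.column_stack([g, mu]), delimiter=",",
               header="gamma_dot_1_per_s,mu_Pa_s", comments="")
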