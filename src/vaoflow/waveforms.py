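"""Pulsatile flow-rate and pressure boundary waveforms.

Physiological inlet flow Q(t) and outlet pressure P(t) are represented as a
mean plus four cosine/sine harmonics over one cardiac cycle of period ``T``
(0.8 s at a resting heart rate of 75 bpm).  The module also provides the
derived quantities a solver needs at the inlet: the cross-section-mean
velocity U(t) = Q(t)/A, the analytic oscillatory (Womersley-type) velocity
profile for a plane channel, and the peak Reynolds number used to confirm the
laminar regime.

Units follow clinical convention: flow in cm^3/s, pressure in Pa, lengths in
mm, velocities in cm/s.  Angular frequency is always recomputed as 2*pi/T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .rheology import CassonParams

__all__ = [
    "HarmonicSeries",
    "InletSpec",
    "ProfileKind",
    "evaluate",
    "cycle_mean",
    "inlet_velocity",
    "womersley_profile",
    "peak_reynolds",
    "published_flow_series",
    "published_pressure_series",
]

#: Cardiac cycle period, s (75 beats/min).
DEFAULT_PERIOD = 0.8

# Published waveform coefficients: mean + 4 harmonics for volumetric flow
# (cm^3/s) and for the pulsatile outlet pressure (Pa).
_FLOW_MEAN = 2.6483
_FLOW_A = (0.1007, -0.0034, 0.0294, 0.0195)
_FLOW_B = (0.0764, -0.0092, 0.0337, -0.0129)
_PRESSURE_MEAN = 11328.663
_PRESSURE_A = (-3.3107, -9.8639, 3.0278, 2.2476)
_PRESSURE_B = (-2.2932, 8.0487, 3.8009, -3.2564)

#: Stated fundamental-harmonic peak velocity, cm/s.  Recorded only: it is not
#: consistent with Q/A for either printed vessel diameter and is never used
#: to rescale the series.
NOMINAL_PEAK_VELOCITY_CM_S = 16.0

#: Stated outlet gauge reference, Pa.  Stored but subtracted out: for
#: incompressible rigid-wall flow only pressure differences matter.
OUTLET_GAUGE_REFERENCE_PA = 102_300.0


class ProfileKind(str, Enum):
    PLUG = "plug"
    WOMERSLEY = "womersley"


@dataclass(frozen=True)
class HarmonicSeries:
    """Mean plus exactly four cos/sin harmonics over period ``T``.

    ``series(t) = mean + sum_{n=1..4} a[n-1] cos(n w t) + b[n-1] sin(n w t)``
    with ``w = 2 pi / T`` (never stored; recomputed from ``T``).
    """

    mean: float
    a: tuple[float, float, float, float]
    b: tuple[float, float, float, float]
    period: float = DEFAULT_PERIOD

    def __post_init__(self) -> None:
        if not math.isfinite(self.period) or self.period <= 0:
            raise ValueError(f"period must be positive and finite, got {self.period}")
        if len(self.a) != 4 or len(self.b) != 4:
            raise ValueError("exactly 4 harmonics required (a and b of length 4)")
        object.__setattr__(self, "a", tuple(float(x) for x in self.a))
        object.__setattr__(self, "b", tuple(float(x) for x in self.b))

    @property
    def omega(self) -> float:
        """Angular frequency 2*pi/T, rad/s."""
        return 2.0 * math.pi / self.period

    def __call__(self, t, phase_shift: float = 0.0):
        return evaluate(self, t, phase_shift)

    def complex_amplitudes(self) -> np.ndarray:
        """Per-harmonic complex amplitudes c_n with term Re{c_n e^{i n w t}}."""
        return np.array(self.a) - 1j * np.array(self.b)

    def to_dict(self) -> dict:
        return {"mean": self.mean, "a": list(self.a), "b": list(self.b), "T": self.period}

    @classmethod
    def from_dict(cls, d: dict) -> "HarmonicSeries":
        return cls(mean=float(d["mean"]), a=tuple(d["a"]), b=tuple(d["b"]),
                   period=float(d.get("T", DEFAULT_PERIOD)))


def published_flow_series() -> HarmonicSeries:
    """The published volumetric inlet flow waveform, cm^3/s."""
    return HarmonicSeries(_FLOW_MEAN, _FLOW_A, _FLOW_B, DEFAULT_PERIOD)


def published_pressure_series() -> HarmonicSeries:
    """The published pulsatile outlet pressure waveform, Pa."""
    return HarmonicSeries(_PRESSURE_MEAN, _PRESSURE_A, _PRESSURE_B, DEFAULT_PERIOD)


@dataclass(frozen=True)
class InletSpec:
    """Inlet cross-section description for a vessel of circular lumen.

    ``diameter`` in mm; the area (cm^2) is always derived from it.  The phase
    shift is applied to every harmonic argument (pi/2 for the outlet pressure
    waveform superimposed in quadrature with the flow).
    """

    diameter: float
    profile_kind: ProfileKind = ProfileKind.WOMERSLEY
    phase_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.diameter <= 0 or not math.isfinite(self.diameter):
            raise ValueError(f"diameter must be positive, got {self.diameter}")
        if not 0.0 <= self.phase_shift < 2.0 * math.pi:
            raise ValueError("phase_shift must lie in [0, 2*pi)")

    @property
    def cross_section_area(self) -> float:
        """Lumen area pi (d/2)^2 in cm^2 (diameter given in mm)."""
        r_cm = 0.05 * self.diameter
        return math.pi * r_cm * r_cm


def evaluate(series: HarmonicSeries, t, phase_shift: float = 0.0):
    """Evaluate the series at time(s) ``t`` (s), with optional phase shift.

    t is reduced mod T (periodic extension).  Scalar in, scalar out.
    """
    t_arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t_arr)):
        raise ValueError("t must be finite")
    w = series.omega
    tau = np.mod(t_arr, series.period)
    out = np.full_like(tau, series.mean, dtype=float)
    for n in range(1, 5):
        arg = n * w * tau + phase_shift
        out = out + series.a[n - 1] * np.cos(arg) + series.b[n - 1] * np.sin(arg)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def cycle_mean(series: HarmonicSeries) -> float:
    """Time average (1/T) int_0^T series(t) dt.

    Every harmonic integrates to zero over a full period, so the closed form
    is just the stored mean; callers wanting a numerical cross-check can
    quadrature-integrate :func:`evaluate` (agrees to <1e-9 relative).
    """
    return float(series.mean)


def inlet_velocity(spec: InletSpec, series: HarmonicSeries, t):
    """Cross-section-mean velocity U(t) = Q(t)/A in cm/s."""
    A = spec.cross_section_area
    if A <= 0:
        raise ValueError("cross-section area must be positive")
    return evaluate(series, t, spec.phase_shift) / A


def _channel_harmonic_shape(alpha_sq: complex, y: np.ndarray) -> np.ndarray:
    """Normalised oscillatory profile for a plane channel, one harmonic.

    ``alpha_sq = i n w H^2 / nu`` (complex Womersley parameter squared, with
    H the half-width).  Returns shape(y) with cross-section average exactly 1.
    """
    lam = np.sqrt(alpha_sq)  # principal branch
    # (1 - cosh(lam*y)/cosh(lam)) / (1 - tanh(lam)/lam)
    num = 1.0 - np.cosh(lam * y) / np.cosh(lam)
    den = 1.0 - np.tanh(lam) / lam
    return num / den


def womersley_profile(spec: InletSpec, series: HarmonicSeries,
                      fluid: "CassonParams", y, t: float):
    """Analytic pulsatile laminar profile across a plane channel, cm/s.

    ``y`` is the normalised cross-stream coordinate in [-1, 1] (walls at
    +/-1).  The steady component is plane Poiseuille (parabolic); each
    harmonic contributes the closed-form oscillatory channel solution with
    complex amplitude chosen so that the cross-channel average at every
    instant equals ``inlet_velocity(spec, series, t)`` exactly.

    The linear analytic solution uses the fluid's high-shear (reference)
    viscosity; the channel half-width is taken as spec.diameter/2.
    """
    if spec.profile_kind is not ProfileKind.WOMERSLEY:
        raise ValueError("womersley_profile requires profile_kind=womersley")
    y_arr = np.asarray(y, dtype=float)
    nu = fluid.reference_viscosity() / fluid.density  # m^2/s
    H = 0.5 * spec.diameter * 1e-3  # m
    w = series.omega
    A = spec.cross_section_area
    u_mean_steady = series.mean / A  # cm/s
    u = 1.5 * u_mean_steady * (1.0 - y_arr**2)
    c = series.complex_amplitudes() / A  # cm/s complex amplitudes
    for n in range(1, 5):
        alpha_sq = 1j * n * w * H * H / nu
        if not np.isfinite(alpha_sq.imag):
            raise ValueError("Womersley number is not finite")
        shape = _channel_harmonic_shape(alpha_sq, y_arr)
        phase = np.exp(1j * (n * w * t + spec.phase_shift))
        u = u + np.real(c[n - 1] * phase * shape)
    return float(u) if np.isscalar(y) or y_arr.ndim == 0 else u


def peak_reynolds(spec: InletSpec, series: HarmonicSeries,
                  density: float = 1060.0, viscosity: float = 0.0035,
                  n_samples: int = 4001) -> float:
    """Peak Reynolds number rho * U_peak * D / mu (dimensionless).

    U_peak is the maximum of |Q(t)/A| on a fine grid over one period; D is
    the inlet diameter.  Values below 2300 justify the laminar assumption.
    """
    if viscosity <= 0:
        raise ValueError("viscosity must be positive")
    if density <= 0:
        raise ValueError("density must be positive")
    t = np.linspace(0.0, series.period, n_samples)
    u_peak_cm = float(np.max(np.abs(inlet_velocity(spec, series, t))))
    u_peak = u_peak_cm * 1e-2  # m/s
    d = spec.diameter * 1e-3  # m
    return density * u_peak * d / viscosity


def export_waveform_csv(series: HarmonicSeries, path, n: int = 401,
                        phase_shift: float = 0.0) -> None:
    """Dump t,value samples of one cycle as a 2-column CSV."""
    t = np.linspace(0.0, series.period, n)
    v = evaluate(series, t, phase_shift)
    arr = np.column_stack([t, v])
    np.savetxt(path, arr, delimiter=",", header="t,value", comments="")
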