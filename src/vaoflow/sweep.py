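"""Angle sweep: the main in-silico experiment.

Runs the full pipeline (geometry -> mesh -> pulsatile solve -> wall metrics
-> vortex) for a list of VA-SCA angles under one shared configuration and
tabulates the medial/lateral TAWSS and OSI means, the lateral high-OSI arc
fraction and the vortex core per angle, then annotates monotone-trend
features (argmin / argmax / V- or Lambda-shape) per metric and wall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import BifurcationSpec, build_bifurcation, generate_mesh
from .metrics import WallMetricField, region_summary
from .rheology import CassonParams
from .solver import SolverConfig, run
from .waveforms import HarmonicSeries, published_flow_series, published_pressure_series

__all__ = ["SweepTable", "run_sweep", "trend", "DEFAULT_ANGLES"]

log = logging.getLogger(__name__)

DEFAULT_ANGLES = (30.0, 50.0, 70.0, 90.0, 110.0)

_METRIC_COLS = ("tawss_medial_dyn_cm2", "tawss_lateral_dyn_cm2",
                "osi_medial", "osi_lateral")


@dataclass
class SweepTable:
    """One row per angle (sorted ascending) plus trend annotations."""

    frame: pd.DataFrame
    summaries: list
    failures: dict = field(default_factory=dict)
    results: dict = field(default_factory=dict)   # theta -> RunResult
    fields: dict = field(default_factory=dict)    # theta -> WallMetricField

    @property
    def angles(self) -> np.ndarray:
        return self.frame["theta"].to_numpy()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def run_sweep(angles: Sequence[float] = DEFAULT_ANGLES,
              base_spec: Optional[BifurcationSpec] = None,
              h: float = 0.4,
              flow_series: Optional[HarmonicSeries] = None,
              pressure_series: Optional[HarmonicSeries] = None,
              params: Optional[CassonParams] = None,
              config: Optional[SolverConfig] = None,
              keep_results: bool = False) -> SweepTable:
    """Simulate every angle with identical settings and tabulate metrics.

    Angles outside [30, 110] are rejected.  A failing angle is recorded in
    ``failures`` and its row marked failed; the sweep continues.  The result
    is deterministic (no stochastic elements) and independent of the order
    in which angles are given.
    """
    angles = sorted(float(a) for a in angles)
    if any(not (30.0 <= a <= 110.0) for a in angles):
        raise ValueError("angles must lie within [30, 110] degrees")
    base_spec = base_spec or BifurcationSpec()
    flow_series = flow_series or published_flow_series()
    pressure_series = (published_pressure_series() if pressure_series is None
                       else pressure_series)
    params = params or CassonParams()
    config = config or SolverConfig()

    rows, summaries, failures = [], [], {}
    results, fields = {}, {}
    for theta in angles:
        try:
            spec = BifurcationSpec(
                theta=theta, d_sca=base_spec.d_sca, d_va=base_spec.d_va,
                l_vao=base_spec.l_vao, l_inlet=base_spec.l_inlet,
                l_sca_outlet=base_spec.l_sca_outlet,
                fillet_radius=base_spec.fillet_radius)
            mesh = generate_mesh(build_bifurcation(spec), h)
            result = run(mesh, flow_series, pressure_series, params, config)
            fieldm = WallMetricField.from_history(result.history)
            summ = region_summary(fieldm, result, spec)
            summaries.append(summ)
            row = summ.as_dict()
            row["failed"] = False
            row["flux_defect"] = result.flux_defect
            rows.append(row)
            if keep_results:
                results[theta] = result
                fields[theta] = fieldm
        except Exception as exc:  # keep sweeping, mark the row failed
            log.error("angle %.1f failed: %s", theta, exc)
            failures[theta] = str(exc)
            rows.append({"theta": theta, "failed": True})
    frame = pd.DataFrame(rows).sort_values("theta").reset_index(drop=True)
    return SweepTable(frame=frame, summaries=summaries, failures=failures,
                      results=results, fields=fields)


def _shape(values: np.ndarray) -> str:
    d = np.diff(values)
    if np.allclose(d, 0.0, atol=1e-15):
        return "flat"
    signs = np.sign(d[np.abs(d) > 0])
    changes = int(np.sum(np.diff(signs) != 0))
    if changes == 0:
        return "increasing" if signs[0] > 0 else "decreasing"
    if changes == 1:
        return "V-shape" if signs[0] < 0 else "Lambda-shape"
    return "non-monotone"


def trend(table: SweepTable) -> dict:
    """Per metric/wall argmin, argmax (ties -> smaller angle) and shape."""
    ok = table.frame[~table.frame["failed"].astype(bool)]
    if len(ok) < 3:
        raise ValueError("trend needs at least 3 successful angles")
    ang = ok["theta"].to_numpy()
    out = {}
    for col in _METRIC_COLS:
        v = ok[col].to_numpy(dtype=float)
        i_min = int(np.argmin(v))   # argmin/argmax take the first (smallest
        i_max = int(np.argmax(v))   # angle) on ties
        if np.sum(v == v[i_min]) > 1 or np.sum(v == v[i_max]) > 1:
            log.info("tie in %s broken toward the smaller angle", col)
        out[col] = {"argmin_theta": float(ang[i_min]),
                    "argmax_theta": float(ang[i_max]),
                    "shape": _shape(v)}
    return out
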