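"""Run configuration: one JSON-serialisable object tying all modules together.

A RunConfig aggregates geometry, mesh size(s), waveform coefficients,
rheology, solver settings, the angle list and the cohort spec, plus the
global seed from which every stochastic sub-stream (geometry perturbation,
cohort generation) is derived.  It round-trips losslessly through JSON and
carries a content hash that output artefacts embed so runs can be audited
for configuration mixing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from .clinical import CohortSpec
from .geometry import BifurcationSpec
from .rheology import CassonParams
from .solver import SolverConfig
from .waveforms import (HarmonicSeries, NOMINAL_PEAK_VELOCITY_CM_S,
                        OUTLET_GAUGE_REFERENCE_PA, ProfileKind,
                        published_flow_series, published_pressure_series)

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]


@dataclass
class RunConfig:
    geometry: BifurcationSpec = field(default_factory=BifurcationSpec)
    mesh_h: float = 0.4
    mesh_levels: tuple = (1.2, 0.8, 0.55, 0.4)
    flow: HarmonicSeries = field(default_factory=published_flow_series)
    pressure: HarmonicSeries = field(default_factory=published_pressure_series)
    flow_multiplier: float = 1.0
    rheology: CassonParams = field(default_factory=CassonParams)
    solver: SolverConfig = field(default_factory=SolverConfig)
    angles: tuple = (30.0, 50.0, 70.0, 90.0, 110.0)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    output_dir: str = "vaoflow_out"
    seed: int = 0
    # recorded reference constants (not used by the solver)
    nominal_peak_velocity_cm_s: float = NOMINAL_PEAK_VELOCITY_CM_S
    outlet_gauge_reference_pa: float = OUTLET_GAUGE_REFERENCE_PA

    def scaled_flow(self) -> HarmonicSeries:
        m = self.flow_multiplier
        if m == 1.0:
            return self.flow
        return HarmonicSeries(self.flow.mean * m,
                              tuple(a * m for a in self.flow.a),
                              tuple(b * m for b in self.flow.b),
                              self.flow.period)

    def substream_seed(self, name: str) -> int:
        """Deterministic per-module seed derived from the global seed."""
        digest = hashlib.sha256(f"{self.seed}:{name}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31 - 1)

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        def enc(obj):
            if isinstance(obj, HarmonicSeries):
                return obj.to_dict()
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, ProfileKind):
                return obj.value
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        out = {}
        for f in dataclasses.fields(self):
            out[f.name] = enc(getattr(self, f.name))
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw = dict(d)
        kw["geometry"] = BifurcationSpec(**_tupled(d.get("geometry", {})))
        kw["flow"] = HarmonicSeries.from_dict(d["flow"]) if "flow" in d \
            else published_flow_series()
        kw["pressure"] = HarmonicSeries.from_dict(d["pressure"]) \
            if "pressure" in d else published_pressure_series()
        kw["rheology"] = CassonParams(**d.get("rheology", {}))
        sv = dict(d.get("solver", {}))
        if "profile_kind" in sv:
            sv["profile_kind"] = ProfileKind(sv["profile_kind"])
        kw["solver"] = SolverConfig(**sv)
        ch = dict(d.get("cohort", {}))
        for key in ("p_tortuosity", "glucose_mmol", "ldl_mmol", "hcy_mmol",
                    "tg_mmol"):
            if key in ch:
                ch[key] = tuple(ch[key])
        kw["cohort"] = CohortSpec(**ch)
        for key in ("angles", "mesh_levels"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return cls(**kw)


def _tupled(d: dict) -> dict:
    return dict(d)


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(json.dumps(cfg.to_dict(), indent=2, sort_keys=True))


def load_config(path) -> RunConfig:
    return RunConfig.from_dict(json.loads(Path(path).read_text()))
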