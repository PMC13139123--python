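"""Shared fixtures.

The two expensive session fixtures (the five-angle sweep and the pulsatile
channel benchmark) are computed once and shared by the acceptance tests and
the solver/metric unit tests that need a realistic flow.
"""

import numpy as np
import pytest

from vaoflow.geometry import channel_mesh
from vaoflow.rheology import CassonParams
from vaoflow.solver import SolverConfig, run
from vaoflow.sweep import run_sweep
from vaoflow.waveforms import HarmonicSeries

# desk-scale study conditions used throughout: 0.4 mm mesh, dt = T/1600,
# two cardiac cycles with the second recorded
SWEEP_H = 0.4
SWEEP_CONFIG = SolverConfig(dt=0.8 / 1600, n_cycles=2, record_cycle=2)

# pulsatile channel benchmark: SCA-scale channel, one strong harmonic
CHANNEL_WIDTH = 8.4
CHANNEL_LENGTH = 25.2
CHANNEL_SERIES = HarmonicSeries(2.6483, (0.8, 0.0, 0.0, 0.0),
                                (0.5, 0.0, 0.0, 0.0), 0.8)


@pytest.fixture(scope="session")
def sweep_table():
    """Five-angle desk-scale sweep with retained results (minutes)."""
    return run_sweep(h=SWEEP_H, config=SWEEP_CONFIG, keep_results=True)


@pytest.fixture(scope="session")
def womersley_run():
    """Pulsatile Newtonian channel run at the 0.3 mm-equivalent mesh."""
    mesh = channel_mesh(CHANNEL_WIDTH, CHANNEL_LENGTH, 0.3)
    cfg = SolverConfig(dt=0.8 / 1600, n_cycles=2, record_cycle=2,
                       wss_cap=None)
    sec = ((CHANNEL_LENGTH / 2 * 1e-3, 0.2e-3),
           (CHANNEL_LENGTH / 2 * 1e-3, (CHANNEL_WIDTH - 0.2) * 1e-3))
    return run(mesh, CHANNEL_SERIES, None, CassonParams(newtonian=True),
               cfg, section=sec)
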