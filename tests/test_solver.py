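"""Flow solver oracles: rest state, Poiseuille, Womersley, conservation."""

import numpy as np
import pytest

from vaoflow import fem
from vaoflow.geometry import (BifurcationSpec, build_bifurcation, channel_mesh,
                              generate_mesh)
from vaoflow.rheology import CassonParams
from vaoflow.solver import (FlowSolver, FlowState, SolverConfig, SolverError,
                            _apply_cap, run, section_average_velocity,
                            solve_steady)
from vaoflow.waveforms import (HarmonicSeries, InletSpec, ProfileKind,
                               womersley_profile)

from conftest import CHANNEL_LENGTH, CHANNEL_SERIES, CHANNEL_WIDTH

NEWTONIAN = CassonParams(newtonian=True)


@pytest.fixture(scope="module")
def poiseuille():
    """Steady Newtonian channel flow at 4 cm/s mean."""
    mesh = channel_mesh(8.4, 33.6, 0.3)
    state, solver = solve_steady(mesh, 4.0, NEWTONIAN, SolverConfig())
    return mesh, state, solver


class TestAssemble:
    def test_operator_fingerprint_deterministic(self):
        mesh = channel_mesh(4.0, 12.0, 0.8)
        cfg = SolverConfig()
        f1 = FlowSolver(mesh, cfg, NEWTONIAN).fingerprint()
        f2 = FlowSolver(mesh, cfg, NEWTONIAN).fingerprint()
        assert f1 == f2

    def test_dofs_scale_linearly_with_nodes(self):
        sizes = []
        for h in (1.0, 0.5):
            mesh = channel_mesh(4.0, 12.0, h)
            s = FlowSolver(mesh, SolverConfig(), NEWTONIAN)
            sizes.append((s.space.n_p2, s.ndof))
        # P2 dofs ~ 4x when h halves (2D); total dofs track them
        assert sizes[1][0] / sizes[0][0] == pytest.approx(4.0, rel=0.3)
        assert sizes[1][1] / sizes[0][1] == pytest.approx(4.0, rel=0.3)

    def test_missing_inlet_tag_rejected(self):
        mesh = channel_mesh(4.0, 12.0, 0.8)
        mesh.edge_tags[mesh.edge_tags == "inlet"] = "wall_other"
        with pytest.raises(SolverError, match="inlet"):
            FlowSolver(mesh, SolverConfig(), NEWTONIAN)

    def test_dt_must_divide_period(self):
        with pytest.raises(ValueError):
            SolverConfig(dt=0.0003).steps_per_cycle(0.8)


class TestSteadyOracles:
    def test_rest_state_with_zero_inflow(self):
        mesh = channel_mesh(4.0, 12.0, 0.8)
        state, solver = solve_steady(mesh, 0.0, NEWTONIAN, SolverConfig())
        assert np.max(state.speed()) < 1e-12

    def test_poiseuille_centerline(self, poiseuille):
        mesh, state, solver = poiseuille
        samp = fem.FieldSampler(solver.space)
        u_c = samp.sample(state.ux, np.array([[16.8e-3, 4.2e-3]]))[0] * 100
        assert u_c == pytest.approx(6.0, rel=0.01)

    def test_poiseuille_wall_shear(self, poiseuille):
        mesh, state, solver = poiseuille
        tau = solver.wall_shear(state)
        mag = np.hypot(tau[:, 0], tau[:, 1])
        expect = 6 * 0.0035 * 0.04 / 8.4e-3
        assert np.median(mag) == pytest.approx(expect, rel=0.02)

    def test_poiseuille_mass_conservation(self, poiseuille):
        mesh, state, solver = poiseuille
        q_in, q_sca, q_va = solver.flux_balance(state)
        assert abs(q_in - q_sca - q_va) / q_in < 1e-9


class TestSectionAverage:
    def test_plug_field(self, poiseuille):
        mesh, state, solver = poiseuille
        plug = FlowState(ux=np.full(solver.space.n_p2, 0.03),
                         uy=np.zeros(solver.space.n_p2),
                         p=np.zeros(solver.space.n_vert), time=0.0)
        sec = ((16.8e-3, 0.5e-3), (16.8e-3, 7.9e-3))
        v = section_average_velocity(solver.space, plug, sec)
        assert v == pytest.approx(3.0, rel=1e-9)

    def test_poiseuille_section_mean(self, poiseuille):
        mesh, state, solver = poiseuille
        sec = ((16.8e-3, 0.0), (16.8e-3, 8.4e-3))
        v = section_average_velocity(solver.space, state, sec)
        # mean over the full width of the parabola is the bulk velocity
        assert v == pytest.approx(4.0, rel=5e-3)

    def test_refinement_insensitive_beyond_100_points(self, poiseuille):
        mesh, state, solver = poiseuille
        sec = ((16.8e-3, 0.2e-3), (16.8e-3, 8.2e-3))
        v100 = section_average_velocity(solver.space, state, sec, 101)
        v400 = section_average_velocity(solver.space, state, sec, 401)
        assert abs(v400 - v100) / v100 < 1e-3

    def test_outside_domain_rejected(self, poiseuille):
        mesh, state, solver = poiseuille
        sec = ((16.8e-3, -5e-3), (16.8e-3, -1e-3))
        with pytest.raises(ValueError):
            section_average_velocity(solver.space, state, sec)


class TestWSSCap:
    def test_capping_clips_magnitude(self):
        tau = np.zeros((1, 2, 2))
        tau[0, 0] = (8.0, 0.0)
        tau[0, 1] = (3.0, 4.0)
        capped, n_capped, raw = _apply_cap(tau, 5.0)
        assert n_capped == 1
        assert raw == pytest.approx(8.0)
        assert np.hypot(*capped[0, 0]) == pytest.approx(5.0)
        assert np.allclose(capped[0, 1], (3.0, 4.0))

    def test_no_cap_passthrough(self):
        tau = np.random.default_rng(0).normal(size=(3, 4, 2)) * 10
        capped, n, _ = _apply_cap(tau, None)
        assert n == 0 and np.array_equal(capped, tau)


class TestTransient:
    def test_womersley_profile_match(self, womersley_run):
        """Recorded cycle matches the analytic oscillatory channel solution."""
        res = womersley_run
        samp = fem.FieldSampler(res.space)
        spec = InletSpec(diameter=CHANNEL_WIDTH,
                         profile_kind=ProfileKind.WOMERSLEY)
        ys = np.linspace(0.2e-3, (CHANNEL_WIDTH - 0.2) * 1e-3, 41)
        yhat = 2 * ys / (CHANNEL_WIDTH * 1e-3) - 1
        num = den = 0.0
        for snap in res.snapshots:
            pts = np.column_stack([np.full_like(ys, CHANNEL_LENGTH / 2 * 1e-3),
                                   ys])
            u = samp.sample(snap.ux, pts) * 100
            ua = womersley_profile(spec, CHANNEL_SERIES, NEWTONIAN, yhat,
                                   snap.time)
            num += np.sum((u - ua) ** 2)
            den += np.sum(ua ** 2)
        assert np.sqrt(num / den) < 0.02

    def test_mass_conservation_every_recorded_step(self, womersley_run):
        assert womersley_run.flux_defect < 1e-6

    def test_cycle_periodicity(self, womersley_run):
        sv = womersley_run.section_velocity
        assert abs(sv[0] - sv[-1]) / sv.max() < 0.01

    def test_deterministic_rerun_bit_identical(self):
        mesh = channel_mesh(8.4, 16.8, 0.7)
        cfg = SolverConfig(dt=0.8 / 1600, n_cycles=1, record_cycle=1)
        r1 = run(mesh, CHANNEL_SERIES, None, NEWTONIAN, cfg)
        r2 = run(mesh, CHANNEL_SERIES, None, NEWTONIAN, cfg)
        assert np.array_equal(r1.history.tau, r2.history.tau)

    def test_casson_zero_coupling_matches_newtonian(self):
        """A vanishing hematocrit correction reproduces the Newtonian run."""
        mesh = channel_mesh(8.4, 16.8, 0.7)
        cfg = SolverConfig(dt=0.8 / 1600, n_cycles=1, record_cycle=1)
        nearly = CassonParams(mu_p=1e-20, mu_infty_override=0.0035)
        r1 = run(mesh, CHANNEL_SERIES, None, NEWTONIAN, cfg)
        r2 = run(mesh, CHANNEL_SERIES, None, nearly, cfg)
        assert np.allclose(r1.history.tau, r2.history.tau, rtol=1e-9,
                           atol=1e-12)

    def test_blowup_detection(self):
        mesh = channel_mesh(3.3, 9.9, 0.3)  # fast narrow channel: unstable
        cfg = SolverConfig(dt=0.8 / 200, n_cycles=1, record_cycle=1)
        strong = HarmonicSeries(20.0, (5.0, 0, 0, 0), (0, 0, 0, 0), 0.8)
        with pytest.raises(SolverError):
            run(mesh, strong, None, NEWTONIAN, cfg)
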