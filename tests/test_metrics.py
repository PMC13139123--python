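"""TAWSS/OSI formulas, region aggregation and vortex detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vaoflow.fixtures import synthetic_wall_history
from vaoflow.geometry import BifurcationSpec, build_bifurcation, generate_mesh
from vaoflow.metrics import (WallMetricField, locate_vortex, osi,
                             oscillation_zone_summary, region_summary,
                             streamfunction, tawss)
from vaoflow.solver import (FlowState, RunResult, SolverConfig, WallShearHistory,
                            FlowSolver)
from vaoflow import fem
from vaoflow.rheology import CassonParams


def history_from(tau, period=0.8, tags=None):
    nt, nf, _ = tau.shape
    times = np.linspace(0.0, period, nt)
    tags = tags if tags is not None else np.array(["wall_lateral"] * nf,
                                                  dtype=object)
    return WallShearHistory(times=times, tau=tau, tags=tags,
                            arclength=np.arange(nf, dtype=float),
                            lengths_mm=np.ones(nf), period=period, cap=None)


class TestTawss:
    def test_constant_vector(self):
        tau = np.zeros((11, 1, 2))
        tau[:, 0, 0] = 0.2
        assert tawss(history_from(tau))[0] == pytest.approx(2.0, abs=1e-12)

    def test_direction_blind_magnitude(self):
        # antisymmetric reversal of 0.3 Pa: magnitude integral unaffected
        t = np.linspace(0, 0.8, 401)
        tau = np.zeros((401, 1, 2))
        tau[:, 0, 0] = 0.3 * np.sign(np.sin(2 * np.pi * t / 0.8 + 1e-12))
        got = tawss(history_from(tau))[0]
        assert got == pytest.approx(3.0, rel=5e-3)

    def test_rectified_sinusoid(self):
        t = np.linspace(0, 0.8, 801)
        tau = np.zeros((801, 1, 2))
        tau[:, 0, 1] = 0.5 * np.sin(2 * np.pi * t / 0.8)
        assert tawss(history_from(tau))[0] == pytest.approx(
            (2 / np.pi) * 0.5 * 10, rel=1e-4)

    def test_gap_detection(self):
        tau = np.zeros((11, 1, 2))
        h = history_from(tau)
        h.times = np.concatenate([h.times[:4], h.times[7:]])
        h.tau = h.tau[:8]
        with pytest.raises(ValueError):
            tawss(h)

    @given(st.floats(0.1, 10.0))
    @settings(max_examples=20, deadline=None)
    def test_linearity_under_scaling(self, c):
        h = synthetic_wall_history()
        scaled = history_from(h.tau * c, tags=h.tags)
        assert np.allclose(tawss(scaled), c * tawss(h))


class TestOsi:
    def test_unidirectional_zero(self):
        h = synthetic_wall_history()
        assert osi(h)[0] == 0.0       # constant vector
        assert osi(h)[2] == pytest.approx(0.0, abs=1e-12)  # 1+0.5 sin, no flip

    def test_perfect_reversal_half(self):
        assert osi(synthetic_wall_history())[1] == pytest.approx(0.5,
                                                                 abs=1e-12)

    def test_zero_history_zero_by_convention(self):
        assert osi(synthetic_wall_history())[3] == 0.0

    def test_bounds_on_random_histories(self):
        rng = np.random.default_rng(42)
        tau = rng.normal(size=(31, 50, 2))
        vals = osi(history_from(tau))
        assert np.all(vals >= 0.0) and np.all(vals <= 0.5)

    @given(st.floats(0.1, 10.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_invariance(self, c):
        h = synthetic_wall_history()
        scaled = history_from(h.tau * c, tags=h.tags)
        assert np.allclose(osi(scaled), osi(h), atol=1e-12)


class TestRegionSummary:
    def make_field(self, osi_lat=0.3, taw=2.0):
        n = 10
        tags = np.array(["wall_lateral"] * n + ["wall_medial"] * n,
                        dtype=object)
        return WallMetricField(
            tawss=np.full(2 * n, taw), osi=np.where(
                np.arange(2 * n) < n, osi_lat, 0.0),
            arclength=np.tile(np.arange(n, dtype=float), 2),
            tags=tags, lengths_mm=np.ones(2 * n))

    def test_uniform_lateral_osi(self):
        rs = region_summary(self.make_field(osi_lat=0.3))
        assert rs.osi_lateral == pytest.approx(0.3)
        assert rs.high_osi_fraction_lateral == 1.0

    def test_uniform_tawss_both_walls(self):
        rs = region_summary(self.make_field(taw=2.0))
        assert rs.tawss_medial == rs.tawss_lateral == pytest.approx(2.0)

    def test_empty_region_rejected(self):
        f = self.make_field()
        f.tags[:] = "wall_other"
        with pytest.raises(ValueError):
            region_summary(f)

    def test_oscillation_zone_extractor(self):
        f = self.make_field(osi_lat=0.0)
        f.osi[3:7] = 0.31          # one connected hot arc on the lateral wall
        z = oscillation_zone_summary(f)
        assert z["n_facets"] == 4
        assert z["zone_mean_osi"] == pytest.approx(0.31)
        cold = oscillation_zone_summary(self.make_field(osi_lat=0.1))
        assert cold["n_facets"] == 0


class TestVortex:
    def _fake_result(self, mesh, ux, uy):
        space = fem.build_space(mesh)
        state = FlowState(ux=ux(space), uy=uy(space),
                          p=np.zeros(space.n_vert), time=0.0)
        return RunResult(history=None, section_times=None,
                         section_velocity=None, snapshot_times=np.array([0.0]),
                         snapshots=[state], flux_defect=0.0, mesh=mesh,
                         space=space, config=SolverConfig())

    def test_poiseuille_channel_has_no_vortex(self):
        spec = BifurcationSpec(theta=70.0)
        mesh = generate_mesh(build_bifurcation(spec), 0.8)

        def ux(space):
            y = space.coords[:, 1]
            H = spec.d_sca * 1e-3
            return 0.06 * np.maximum(4 * (y / H) * (1 - y / H), 0.0)

        res = self._fake_result(mesh, ux, lambda s: np.zeros(s.n_p2))
        assert not locate_vortex(res, spec).found

    def test_analytic_gaussian_vortex_recovered(self):
        """A rotational field built from a known streamfunction is located
        within one element diameter of its true centre."""
        spec = BifurcationSpec(theta=90.0)
        mesh = generate_mesh(build_bifurcation(spec), 0.8)
        centre_mm = spec.junction_center + 6.0 * spec.branch_dir
        sigma = 1.2e-3

        def psi(xy):
            r2 = np.sum((xy - centre_mm * 1e-3) ** 2, axis=1)
            return 1e-4 * np.exp(-r2 / (2 * sigma ** 2))

        def ux(space):
            xy = space.coords
            return (xy[:, 1] - centre_mm[1] * 1e-3) / sigma ** 2 * psi(xy)

        def uy(space):
            xy = space.coords
            return -(xy[:, 0] - centre_mm[0] * 1e-3) / sigma ** 2 * psi(xy)

        res = self._fake_result(mesh, ux, uy)
        vi = locate_vortex(res, spec)
        assert vi.found
        assert np.linalg.norm(vi.position_mm - centre_mm) < 1.6

    def test_sweep_runs_find_vortex_at_every_angle(self, sweep_table):
        assert all(s.vortex.found for s in sweep_table.summaries)


class TestStreamfunction:
    def test_uniform_flow_linear_psi(self):
        mesh = generate_mesh(build_bifurcation(BifurcationSpec(theta=70.0)),
                             0.8)
        space = fem.build_space(mesh)
        state = FlowState(ux=np.full(space.n_p2, 0.02),
                          uy=np.zeros(space.n_p2),
                          p=np.zeros(space.n_vert), time=0.0)
        psi = streamfunction(space, state)
        # for u=(c,0): psi = c*y + const
        y = space.verts[:, 1]
        fit = np.polyfit(y, psi, 1)
        resid = psi - np.polyval(fit, y)
        assert fit[0] == pytest.approx(0.02, rel=1e-6)
        assert np.max(np.abs(resid)) < 1e-9 * max(abs(psi.max()), 1e-12)


class TestQuadratureRefinement:
    def test_doubling_recorded_steps_changes_metrics_little(self, sweep_table):
        """Halving the time sampling of the recorded history changes
        TAWSS/OSI by < 0.5% (quadrature convergence on the real run)."""
        theta = 70.0
        res = sweep_table.results[theta]
        h = res.history
        coarse = WallShearHistory(times=h.times[::2], tau=h.tau[::2],
                                  tags=h.tags, arclength=h.arclength,
                                  lengths_mm=h.lengths_mm, period=h.period,
                                  cap=h.cap)
        t_f, t_c = tawss(h), tawss(coarse)
        sel = t_f > 1e-3 * t_f.max()
        assert np.max(np.abs(t_f[sel] - t_c[sel]) / t_f[sel]) < 0.005
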