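"""Harmonic waveform representation, inlet profiles and Reynolds number."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from vaoflow.rheology import CassonParams
from vaoflow.waveforms import (HarmonicSeries, InletSpec, ProfileKind,
                               cycle_mean, evaluate, inlet_velocity,
                               peak_reynolds, published_flow_series,
                               published_pressure_series, womersley_profile)

SCA_INLET = InletSpec(diameter=8.4)

coeffs = st.tuples(*[st.floats(-5, 5) for _ in range(4)])


@st.composite
def series_strategy(draw):
    return HarmonicSeries(draw(st.floats(-10, 10)), draw(coeffs),
                          draw(coeffs), draw(st.floats(0.1, 5.0)))


class TestEvaluate:
    def test_published_flow_series_at_zero(self):
        # mean + sum of cosine coefficients at t=0
        q = evaluate(published_flow_series(), 0.0)
        assert q == pytest.approx(2.6483 + 0.1007 - 0.0034 + 0.0294 + 0.0195,
                                  abs=1e-12)
        assert q == pytest.approx(2.7945, abs=1e-12)

    def test_constant_series_returns_mean(self):
        s = HarmonicSeries(3.2, (0,) * 4, (0,) * 4, 0.8)
        for t in (0.0, 0.3, 17.9):
            assert evaluate(s, t) == 3.2

    @given(series_strategy(), st.floats(-10, 10))
    @settings(max_examples=50, deadline=None)
    def test_periodicity(self, s, t):
        assert evaluate(s, t) == pytest.approx(evaluate(s, t + s.period),
                                               abs=1e-9)

    @given(series_strategy(), st.floats(0, 10))
    @settings(max_examples=30, deadline=None)
    def test_quarter_phase_maps_cos_to_minus_sin(self, s, t):
        # shifting every harmonic argument by pi/2 equals evaluating the
        # series with coefficients (a,b) -> per-harmonic rotation
        shifted = evaluate(s, t, math.pi / 2)
        w = s.omega
        expect = s.mean
        for n in range(1, 5):
            arg = n * w * (t % s.period)
            expect += -s.a[n - 1] * math.sin(arg) + s.b[n - 1] * math.cos(arg)
        assert shifted == pytest.approx(expect, rel=1e-9, abs=1e-9)

    def test_rejects_nonfinite_time_and_bad_period(self):
        s = published_flow_series()
        with pytest.raises(ValueError):
            evaluate(s, float("nan"))
        with pytest.raises(ValueError):
            HarmonicSeries(1.0, (0,) * 4, (0,) * 4, -0.8)

    def test_exactly_four_harmonics_enforced(self):
        with pytest.raises(ValueError):
            HarmonicSeries(1.0, (0.0,) * 3, (0.0,) * 4, 0.8)


class TestCycleMean:
    def test_published_means(self):
        assert cycle_mean(published_flow_series()) == 2.6483
        assert cycle_mean(published_pressure_series()) == 11328.663

    @pytest.mark.parametrize("series", [published_flow_series(),
                                        published_pressure_series()])
    def test_quadrature_cross_check(self, series):
        val, _ = quad(lambda t: evaluate(series, t), 0, series.period,
                      limit=200)
        assert val / series.period == pytest.approx(series.mean, rel=1e-9)

    def test_zero_mean_series(self):
        s = HarmonicSeries(0.0, (1, 2, 3, 4), (4, 3, 2, 1), 0.8)
        assert cycle_mean(s) == 0.0

    @given(series_strategy())
    @settings(max_examples=25, deadline=None)
    def test_demeaned_series_averages_to_zero(self, s):
        demeaned = HarmonicSeries(0.0, s.a, s.b, s.period)
        t = np.linspace(0, s.period, 4097)
        v = evaluate(demeaned, t)
        assert np.trapezoid(v, t) / s.period == pytest.approx(0.0, abs=1e-9)


class TestInletVelocity:
    def test_constant_flow_unit_area(self):
        spec = InletSpec(diameter=2.0 / math.sqrt(math.pi) * 10)  # A = 1 cm^2
        s = HarmonicSeries(2.0, (0,) * 4, (0,) * 4, 0.8)
        assert inlet_velocity(spec, s, 0.37) == pytest.approx(2.0, rel=1e-12)

    def test_sca_cycle_mean_velocity(self):
        # 2.6483 cm^3/s over the 8.4 mm SCA lumen (0.5542 cm^2)
        assert SCA_INLET.cross_section_area == pytest.approx(0.5542, abs=1e-4)
        u = cycle_mean(published_flow_series()) / SCA_INLET.cross_section_area
        assert u == pytest.approx(4.779, abs=2e-3)

    def test_doubling_area_halves_velocity(self):
        s = published_flow_series()
        d2 = InletSpec(diameter=8.4 * math.sqrt(2))
        for t in (0.0, 0.2, 0.55):
            assert inlet_velocity(d2, s, t) == pytest.approx(
                0.5 * inlet_velocity(SCA_INLET, s, t), rel=1e-12)


class TestWomersleyProfile:
    fluid = CassonParams(newtonian=True)

    def test_steady_limit_is_parabolic(self):
        s = HarmonicSeries(2.6483, (0,) * 4, (0,) * 4, 0.8)
        u_mean = s.mean / SCA_INLET.cross_section_area
        u0 = womersley_profile(SCA_INLET, s, self.fluid, 0.0, 0.123)
        assert u0 == pytest.approx(1.5 * u_mean, rel=1e-12)
        uw = womersley_profile(SCA_INLET, s, self.fluid,
                               np.array([-1.0, 1.0]), 0.5)
        assert np.allclose(uw, 0.0, atol=1e-12)

    @pytest.mark.parametrize("t", [0.0, 0.13, 0.41, 0.79])
    def test_no_slip_at_walls(self, t):
        u = womersley_profile(SCA_INLET, published_flow_series(), self.fluid,
                              np.array([-1.0, 1.0]), t)
        assert np.allclose(u, 0.0, atol=1e-10)

    @pytest.mark.parametrize("t", [0.0, 0.2, 0.33, 0.6])
    def test_cross_section_average_matches_flow(self, t):
        y = np.linspace(-1, 1, 20001)
        u = womersley_profile(SCA_INLET, published_flow_series(), self.fluid, y, t)
        avg = np.trapezoid(u, y) / 2.0
        target = inlet_velocity(SCA_INLET, published_flow_series(), t)
        assert avg == pytest.approx(target, rel=1e-3)


class TestPeakReynolds:
    def test_printed_constants(self):
        # Re = rho U D / mu with U = 16 cm/s, D = 8.4 mm
        u = HarmonicSeries(16.0 * SCA_INLET.cross_section_area,
                           (0,) * 4, (0,) * 4, 0.8)
        re = peak_reynolds(SCA_INLET, u, 1060.0, 0.0035)
        assert re == pytest.approx(1060 * 0.16 * 0.0084 / 0.0035, rel=1e-9)
        assert re == pytest.approx(407, abs=1)

    def test_laminar_bound_for_published_waveform(self):
        assert peak_reynolds(SCA_INLET, published_flow_series()) < 2300

    def test_zero_flow(self):
        z = HarmonicSeries(0.0, (0,) * 4, (0,) * 4, 0.8)
        assert peak_reynolds(SCA_INLET, z) == 0.0

    @given(st.floats(500, 2000), st.floats(1e-3, 1e-2))
    @settings(max_examples=20, deadline=None)
    def test_homogeneity_in_density_and_viscosity(self, rho, mu):
        s = published_flow_series()
        base = peak_reynolds(SCA_INLET, s, 1000.0, 0.001)
        assert peak_reynolds(SCA_INLET, s, rho, mu) == pytest.approx(
            base * (rho / 1000.0) * (0.001 / mu), rel=1e-9)
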