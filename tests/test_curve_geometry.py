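"""Unit and property tests for centerline geometry and the index formulas."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesseltort import curve_geometry as cg
from vesseltort import synthetic_data as sd
from vesseltort.errors import (
    CurveLengthError,
    DegenerateCurveError,
    DegenerateInputError,
    DomainError,
    ParameterError,
)

from conftest import digital_arc


def line_curve(n=31, slope=0.0):
    x = np.arange(n, dtype=float)
    return cg.VesselCurve(np.column_stack([x, slope * x]))


class TestVesselCurve:
    def test_rejects_short_curves(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10)])
        with pytest.raises(CurveLengthError):
            cg.VesselCurve(pts)

    def test_rejects_coincident_points(self):
        x = np.arange(30.0)
        x[5] = x[4]
        with pytest.raises(DegenerateInputError):
            cg.VesselCurve(np.column_stack([x, np.zeros(30)]))

    def test_rejects_large_steps(self):
        pts = np.column_stack([np.arange(0.0, 60.0, 2.0), np.zeros(30)])
        with pytest.raises(ParameterError):
            cg.VesselCurve(pts)


class TestSmoothCurve:
    def test_collinear_points_unchanged(self):
        curve = line_curve(31)
        out = cg.smooth_curve(curve, 3)
        np.testing.assert_allclose(out.points, curve.points, atol=1e-12)

    def test_window_one_is_identity(self):
        curve = digital_curve = cg.VesselCurve(
            np.column_stack([np.arange(25.0), np.sin(np.arange(25.0)) * 0.4])
        )
        out = cg.smooth_curve(curve, 1)
        np.testing.assert_array_equal(out.points, curve.points)

    def test_alternating_sequence_interior_averages(self):
        n = 31
        y = (np.arange(n) % 2).astype(float)
        curve = cg.VesselCurve(np.column_stack([np.arange(n, dtype=float), y]))
        out = cg.smooth_curve(curve, 3)
        interior = out.y[1:-1]
        odd = interior[np.arange(1, n - 1) % 2 == 1]
        even = interior[np.arange(1, n - 1) % 2 == 0]
        np.testing.assert_allclose(odd, 1.0 / 3.0)
        np.testing.assert_allclose(even, 2.0 / 3.0)

    @pytest.mark.parametrize("window", [0, 2, -3])
    def test_bad_window_rejected(self, window):
        with pytest.raises(ParameterError):
            cg.smooth_curve(line_curve(), window)


class TestEstimateDerivatives:
    def test_line_exact(self):
        curve = cg.VesselCurve(
            np.column_stack([np.arange(41, dtype=float), np.full(41, 7.0)])
        )
        d = cg.estimate_derivatives(curve)
        np.testing.assert_allclose(d.x1, 1.0, atol=1e-9)
        np.testing.assert_allclose(d.x2, 0.0, atol=1e-9)
        np.testing.assert_allclose(d.y1, 0.0, atol=1e-9)
        np.testing.assert_allclose(d.y2, 0.0, atol=1e-9)

    def test_parabola_exact_in_interior(self):
        m = np.arange(41, dtype=float)
        curve = cg.VesselCurve(np.column_stack([m, 0.01 * m**2]))
        d = cg.estimate_derivatives(curve)
        # quadratics are in the model space; moving-averaging a constant
        # (y2) changes nothing anywhere, a linear y1 only at the two ends
        np.testing.assert_allclose(d.y2, 0.02, atol=1e-9)
        np.testing.assert_allclose(d.y1[1:-1], 0.02 * m[1:-1], atol=1e-9)

    def test_unit_speed_circle_interior_speed(self):
        R = 100.0
        n = int(R * math.pi)
        t = np.arange(n) / R
        curve = cg.VesselCurve(
            np.column_stack([R * np.cos(t), R * np.sin(t)])
        )
        d = cg.estimate_derivatives(curve)
        speed = d.speed[20:-20]
        assert np.all(np.abs(speed - 1.0) < 0.01)

    def test_short_curve_raises(self):
        pts = np.column_stack([np.arange(21.0), np.zeros(21)])
        curve = cg.VesselCurve(pts)
        cg.estimate_derivatives(curve)  # N = 21 is the minimum, must work
        with pytest.raises(CurveLengthError):
            short = cg.VesselCurve.__new__(cg.VesselCurve)
            short.points = pts[:15]
            cg.estimate_derivatives(short)


class TestComputeCurvature:
    def test_straight_line_zero(self):
        d = cg.DerivativeSeries(
            x1=np.ones(5), x2=np.zeros(5), y1=np.zeros(5), y2=np.zeros(5)
        )
        np.testing.assert_array_equal(cg.compute_curvature(d).kappa, 0.0)

    def test_direct_formula_evaluation(self):
        d = cg.DerivativeSeries(
            x1=np.zeros(3), x2=np.full(3, -0.02), y1=np.ones(3), y2=np.zeros(3)
        )
        np.testing.assert_allclose(cg.compute_curvature(d).kappa, 0.02)

    def test_analytic_circle_oracle(self):
        # fine-sampled analytic circle: kappa = 1/R to 0.1%
        ac = sd.gen_analytic_curve(
            "circular_arc", {"radius": 50, "angle": math.pi, "center": (100, 100)}
        )
        deriv = cg.estimate_derivatives(ac.as_curve())
        kappa = cg.compute_curvature(deriv).kappa
        assert np.all(np.abs(np.abs(kappa[30:-30]) * 50 - 1) < 1e-3)

    def test_digital_circle_mean_curvature(self):
        # integer-pixel (skeleton-like) circle: the circle's curvature is
        # recovered in the mean over interior points
        pts = digital_arc(80, math.pi)
        curve = cg.smooth_curve(cg.VesselCurve(pts), 3)
        kappa = cg.compute_curvature(cg.estimate_derivatives(curve)).kappa
        mean_k = np.abs(kappa[20:-20]).mean()
        assert abs(mean_k * 80 - 1) < 0.02

    def test_degenerate_speed_raises(self):
        d = cg.DerivativeSeries(
            x1=np.zeros(3), x2=np.zeros(3), y1=np.zeros(3), y2=np.ones(3)
        )
        with pytest.raises(DegenerateCurveError):
            cg.compute_curvature(d)


class TestGeometricParameters:
    def test_straight_segment(self):
        curve = cg.VesselCurve(
            np.column_stack([np.arange(100, dtype=float), np.zeros(100)])
        )
        gp, _ = cg.analyze_curve(curve)
        assert gp.D == pytest.approx(99.0)
        assert gp.L == pytest.approx(99.0, abs=0.5)
        assert gp.TK == pytest.approx(0.0, abs=1e-3)
        assert gp.TSK == pytest.approx(0.0, abs=1e-5)

    def test_semicircle_closed_forms(self):
        ac = sd.gen_analytic_curve(
            "circular_arc", {"radius": 50, "angle": math.pi, "center": (0, 0)}
        )
        gp, _ = cg.analyze_curve(ac.as_curve())
        assert gp.D == pytest.approx(100.0, rel=1e-3)
        assert gp.L == pytest.approx(157.0796, rel=1e-3)
        assert gp.TK == pytest.approx(math.pi, rel=1e-3)
        assert gp.TSK == pytest.approx(math.pi / 50, rel=1e-3)

    def test_quarter_circle_turning_angle(self):
        ac = sd.gen_analytic_curve(
            "circular_arc", {"radius": 80, "angle": math.pi / 2, "center": (0, 0)}
        )
        gp, _ = cg.analyze_curve(ac.as_curve())
        assert gp.TK == pytest.approx(math.pi / 2, rel=0.01)

    def test_mismatched_lengths_rejected(self):
        curve = line_curve(31)
        deriv = cg.estimate_derivatives(curve)
        kappa = cg.CurvatureSeries(np.zeros(10))
        with pytest.raises(ParameterError):
            cg.geometric_parameters(curve, kappa, deriv)


class TestTortuosityIndices:
    def test_reference_vessel_values(self):
        # inputs from a strongly tortuous clinical vessel; expected values
        # are direct evaluations of the definitions
        gp = cg.GeometricParams(D=339.86, L=457.30, TK=12.57, TSK=1.007)
        p = cg.tortuosity_indices(gp)
        assert p.DF == pytest.approx(1.3455, rel=1e-4)
        assert p.T1 == pytest.approx(0.3455, rel=1e-3)
        assert p.T4 == pytest.approx(0.02749, rel=1e-3)
        assert p.T5 == pytest.approx(0.002202, rel=1e-3)
        assert p.T6 == pytest.approx(0.036986, rel=1e-3)
        assert p.T7 == pytest.approx(0.002963, rel=1e-3)

    def test_straight_vessel(self):
        p = cg.tortuosity_indices(cg.GeometricParams(100, 100, 0, 0))
        assert p.DF == 1.0 and p.T1 == 0.0
        assert p.T2 == p.T3 == p.T4 == p.T5 == p.T6 == p.T7 == 0.0

    def test_semicircle_closed_forms(self):
        p = cg.tortuosity_indices(
            cg.GeometricParams(100, 157.0796, 3.14159, 0.0628319)
        )
        assert p.DF == pytest.approx(1.570796, rel=1e-5)
        assert p.T4 == pytest.approx(0.02, rel=1e-4)
        assert p.T5 == pytest.approx(0.0004, rel=1e-4)
        assert p.T6 == pytest.approx(0.0314159, rel=1e-5)
        assert p.T7 == pytest.approx(0.000628, rel=1e-3)

    def test_domain_error(self):
        with pytest.raises(DomainError):
            cg.tortuosity_indices(cg.GeometricParams(0.0, 10.0, 1.0, 0.1))

    @given(
        d=st.floats(1e-3, 1e3),
        excess=st.floats(0.0, 10.0),
        tk=st.floats(0.0, 100.0),
        tsk=st.floats(0.0, 10.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_algebraic_identities(self, d, excess, tk, tsk):
        gp = cg.GeometricParams(D=d, L=d * (1 + excess), TK=tk, TSK=tsk)
        p = cg.tortuosity_indices(gp)
        assert p.T1 == p.DF - 1.0  # same arithmetic path
        assert p.DF >= 1.0
        assert p.T6 >= p.T4 and p.T7 >= p.T5


@pytest.fixture(scope="module")
def wiggly():
    return sd.gen_analytic_curve(
        "sinusoid", {"amplitude": 8.0, "wavelength": 90.0, "length": 260.0}
    )


class TestInvariances:
    """Rigid-motion / scaling / reversal behavior of the whole chain."""

    @staticmethod
    def profile(points):
        _, p = cg.analyze_curve(cg.VesselCurve(points))
        return np.array([getattr(p, n) for n in cg.INDEX_NAMES])

    def test_rigid_motion_invariance(self, wiggly):
        base = self.profile(wiggly.points)
        ang = 0.7
        rot = np.array([[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]])
        moved = wiggly.points @ rot.T + np.array([37.0, -12.0])
        np.testing.assert_allclose(self.profile(moved), base, rtol=1e-6, atol=1e-9)

    @pytest.mark.parametrize("s", [0.5, 2.0])
    def test_uniform_scaling_laws(self, wiggly, s):
        base = self.profile(wiggly.points)
        scaled = self.profile(wiggly.points * s)
        names = cg.INDEX_NAMES
        expect = dict(zip(names, base))
        got = dict(zip(names, scaled))
        for n in ("DF", "T1", "T2"):
            assert got[n] == pytest.approx(expect[n], rel=0.01)
        for n in ("T3", "T4", "T6"):
            assert got[n] == pytest.approx(expect[n] / s, rel=0.02)
        for n in ("T5", "T7"):
            assert got[n] == pytest.approx(expect[n] / s**2, rel=0.02)

    def test_reversal_invariance(self, wiggly):
        curve = cg.VesselCurve(wiggly.points)
        gp_f, _ = cg.analyze_curve(curve)
        gp_r, _ = cg.analyze_curve(curve.reversed())
        for name in ("D", "L", "TK", "TSK"):
            assert getattr(gp_r, name) == pytest.approx(getattr(gp_f, name), rel=1e-9)

    def test_reversal_flips_curvature_sign(self, wiggly):
        curve = cg.VesselCurve(wiggly.points)
        k_f = cg.compute_curvature(cg.estimate_derivatives(curve)).kappa
        k_r = cg.compute_curvature(cg.estimate_derivatives(curve.reversed())).kappa
        np.testing.assert_allclose(k_r, -k_f[::-1], atol=1e-9)


class TestArcOracleEquivalence:
    @pytest.mark.parametrize("radius", [30, 50, 100])
    @pytest.mark.parametrize("angle", [math.pi / 4, math.pi / 2, math.pi])
    def test_closed_form_match_on_analytic_samples(self, radius, angle):
        ac = sd.gen_analytic_curve(
            "circular_arc", {"radius": radius, "angle": angle, "center": (0, 0)}
        )
        gp, _ = cg.analyze_curve(ac.as_curve())
        assert gp.D == pytest.approx(2 * radius * math.sin(angle / 2), rel=1e-3)
        assert gp.L == pytest.approx(radius * angle, rel=1e-3)
        assert gp.TK == pytest.approx(angle, rel=1e-3)
        assert gp.TSK == pytest.approx(angle / radius, rel=1e-3)

    @pytest.mark.parametrize("radius", [50, 80])
    def test_rasterized_arc_within_two_percent(self, radius):
        pts = digital_arc(radius, math.pi / 2, phase=0.4)
        curve = cg.smooth_curve(cg.VesselCurve(pts), 3)
        gp, _ = cg.analyze_curve(curve)
        assert gp.D == pytest.approx(2 * radius * math.sin(math.pi / 4), rel=0.02)
        assert gp.L == pytest.approx(radius * math.pi / 2, rel=0.02)
        assert gp.TK == pytest.approx(math.pi / 2, rel=0.02)


def test_curve_csv_roundtrip(tmp_path):
    pts = np.column_stack([np.arange(25.0), np.sin(np.arange(25.0)) * 0.3])
    curve = cg.VesselCurve(pts)
    path = tmp_path / "curve.csv"
    cg.write_curve_csv(curve, path)
    back = cg.read_curve_csv(path)
    np.testing.assert_allclose(back.points, curve.points)
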