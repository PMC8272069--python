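import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from grapefit.geometry import (
    ConicCoefficients,
    Ellipse,
    EllipseFitError,
    conic_to_geometric,
    ellipse_arc_length,
    ellipse_area,
    ellipse_perimeter,
    ellipse_point,
    fit_ellipse_lsq,
    geometric_to_conic,
    long_axis,
    point_ellipse_distance,
    points_ellipse_distance,
    rasterize_ellipse_arc,
)

from .conftest import random_ellipse, sample_on_ellipse, theta_close


def conic_through_5_points(pts):
    """Independent oracle: unique conic through 5 points by nullspace."""
    rows = [[x * x, x * y, y * y, x, y, 1.0] for x, y in pts]
    _, _, vt = np.linalg.svd(np.asarray(rows))
    return ConicCoefficients(*vt[-1])


class TestEllipseType:
    def test_axis_ordering_normalized(self):
        e = Ellipse(0, 0, 2.0, 5.0, 0.0)  # b > a given: swapped, theta rotated
        assert e.a == 5.0 and e.b == 2.0
        assert theta_close(e.theta, math.pi / 2, 1e-12)

    def test_theta_wraps_to_half_open_interval(self):
        e = Ellipse(0, 0, 5, 3, 4.0)
        assert 0.0 <= e.theta < math.pi

    def test_circle_theta_zero(self):
        assert Ellipse(1, 1, 2.0, 2.0, 1.3).theta == 0.0

    @pytest.mark.parametrize("bad", [(0, 0, 0, 1, 0), (0, 0, 5, -1, 0), (0, 0, math.nan, 1, 0)])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            Ellipse(*bad)


class TestFitEllipseLsq:
    def test_exact_interpolation_of_5_points(self):
        pts = [(5, 0), (-5, 0), (0, 3), (0, -3), (4, 1.8)]
        # Oracle: the unique conic through these 5 points is x^2/25 + y^2/9 = 1.
        oracle = conic_to_geometric(conic_through_5_points(pts))
        assert oracle.a == pytest.approx(5.0, abs=1e-9)
        e = fit_ellipse_lsq(pts)
        assert e.cx == pytest.approx(0.0, abs=1e-9)
        assert e.cy == pytest.approx(0.0, abs=1e-9)
        assert e.a == pytest.approx(5.0, abs=1e-9)
        assert e.b == pytest.approx(3.0, abs=1e-9)
        assert theta_close(e.theta, 0.0, 1e-9)

    def test_circle_through_5_points(self):
        r2 = math.sqrt(2.0)
        e = fit_ellipse_lsq([(2, 0), (0, 2), (-2, 0), (0, -2), (r2, r2)])
        assert e.a == pytest.approx(2.0, abs=1e-9)
        assert e.b == pytest.approx(2.0, abs=1e-9)
        assert e.cx == pytest.approx(0.0, abs=1e-9)

    def test_collinear_points_fail(self):
        with pytest.raises(EllipseFitError):
            fit_ellipse_lsq([(i, i) for i in range(5)])

    def test_too_few_distinct_points_fail(self):
        with pytest.raises(EllipseFitError):
            fit_ellipse_lsq([(0, 0), (1, 0), (0, 1), (1, 1)])
        with pytest.raises(EllipseFitError):
            fit_ellipse_lsq([(0, 0), (1, 0), (0, 1), (1, 1), (1, 1)])

    def test_recovery_from_noiseless_samples(self, rng):
        for _ in range(20):
            e = random_ellipse(rng)
            pts = sample_on_ellipse(e, 50, rng)
            f = fit_ellipse_lsq(pts)
            assert f.cx == pytest.approx(e.cx, rel=1e-6, abs=1e-6)
            assert f.cy == pytest.approx(e.cy, rel=1e-6, abs=1e-6)
            assert f.a == pytest.approx(e.a, rel=1e-6)
            assert f.b == pytest.approx(e.b, rel=1e-6)
            if e.a / e.b > 1.001:
                assert theta_close(f.theta, e.theta, 1e-6)


class TestConicConversion:
    def test_canonical_axis_aligned(self):
        e = conic_to_geometric(ConicCoefficients(1 / 25, 0, 1 / 9, 0, 0, -1))
        assert (e.a, e.b) == pytest.approx((5.0, 3.0))
        assert e.theta == pytest.approx(0.0)

    def test_circle(self):
        e = conic_to_geometric(ConicCoefficients(1, 0, 1, 0, 0, -4))
        assert e.a == pytest.approx(2.0)
        assert e.b == pytest.approx(2.0)

    def test_hyperbola_rejected(self):
        with pytest.raises(EllipseFitError):
            conic_to_geometric(ConicCoefficients(1, 0, -1, 0, 0, -1))

    def test_imaginary_ellipse_rejected(self):
        with pytest.raises(EllipseFitError):
            conic_to_geometric(ConicCoefficients(1, 0, 1, 0, 0, 4))  # x^2+y^2 = -4

    def test_roundtrip_identity(self, rng):
        for _ in range(30):
            e = random_ellipse(rng)
            r = conic_to_geometric(geometric_to_conic(e))
            assert r.cx == pytest.approx(e.cx, abs=1e-9 * max(1, abs(e.cx)))
            assert r.cy == pytest.approx(e.cy, abs=1e-9 * max(1, abs(e.cy)))
            assert r.a == pytest.approx(e.a, rel=1e-9)
            assert r.b == pytest.approx(e.b, rel=1e-9)
            if e.a / e.b > 1.001:
                assert theta_close(r.theta, e.theta, 1e-9)


class TestPerimeter:
    def test_circle_exact(self):
        assert ellipse_perimeter(Ellipse(0, 0, 7, 7, 0)) == pytest.approx(2 * math.pi * 7, rel=1e-12)

    def test_against_quadrature_oracle(self, canonical_ellipse):
        oracle, _ = quad(lambda t: math.hypot(5 * math.sin(t), 3 * math.cos(t)), 0, 2 * math.pi, limit=200)
        assert ellipse_perimeter(canonical_ellipse) == pytest.approx(oracle, rel=1e-6)
        assert ellipse_perimeter(canonical_ellipse) == pytest.approx(25.52699886, rel=1e-8)

    def test_continuity_toward_circle(self):
        near = ellipse_perimeter(Ellipse(0, 0, 1.0, 1.0 - 1e-9, 0))
        assert near == pytest.approx(2 * math.pi, rel=1e-7)

    def test_monotone_in_major_axis(self):
        ps = [ellipse_perimeter(Ellipse(0, 0, a, 3.0, 0)) for a in np.linspace(3.0, 10.0, 15)]
        assert all(p2 > p1 for p1, p2 in zip(ps, ps[1:]))

    def test_symmetric_under_axis_exchange(self):
        # Ellipse normalizes (a, b) ordering, so exchanged axes give the same locus.
        assert ellipse_perimeter(Ellipse(0, 0, 5, 3, 0)) == pytest.approx(
            ellipse_perimeter(Ellipse(0, 0, 3, 5, 0)), rel=1e-12
        )


class TestPointDistance:
    def test_on_major_axis_outside(self, canonical_ellipse):
        assert point_ellipse_distance((10, 0), canonical_ellipse) == pytest.approx(5.0, abs=1e-9)

    def test_center_nearest_minor_vertex(self, canonical_ellipse):
        assert point_ellipse_distance((0, 0), canonical_ellipse) == pytest.approx(3.0, abs=1e-9)

    def test_against_dense_sampling_oracle(self, canonical_ellipse):
        t = np.linspace(0, 2 * np.pi, 10**6)
        boundary = ellipse_point(canonical_ellipse, t)
        for p in [(4.0, 2.0), (1.0, 0.0), (-2.0, -0.5), (6.0, 6.0), (0.0, 2.9)]:
            oracle = float(np.min(np.hypot(boundary[:, 0] - p[0], boundary[:, 1] - p[1])))
            assert point_ellipse_distance(p, canonical_ellipse) == pytest.approx(oracle, abs=1e-6)

    def test_zero_on_boundary(self, rng):
        for _ in range(10):
            e = random_ellipse(rng)
            pts = sample_on_ellipse(e, 100, rng)
            assert np.max(points_ellipse_distance(pts, e)) <= 1e-9

    def test_circle_case(self):
        e = Ellipse(1, 1, 4, 4, 0)
        assert point_ellipse_distance((1, 7), e) == pytest.approx(2.0, abs=1e-12)

    def test_evolute_interior_on_axis(self):
        # Inside the evolute cusp the foot point is off-axis; verify vs sampling.
        e = Ellipse(0, 0, 5, 3, 0)
        t = np.linspace(0, 2 * np.pi, 10**6)
        boundary = ellipse_point(e, t)
        oracle = float(np.min(np.hypot(boundary[:, 0] - 1.0, boundary[:, 1])))
        assert point_ellipse_distance((1.0, 0.0), e) == pytest.approx(oracle, abs=1e-6)


class TestAreaAndAxis:
    def test_area_closed_form(self, canonical_ellipse):
        assert ellipse_area(canonical_ellipse) == pytest.approx(15 * math.pi)
        assert ellipse_area(Ellipse(0, 0, 1, 1, 0)) == pytest.approx(math.pi)

    def test_area_quadratic_scaling(self, rng):
        e = random_ellipse(rng)
        k = 3.0
        scaled = Ellipse(e.cx, e.cy, k * e.a, k * e.b, e.theta)
        assert ellipse_area(scaled) == pytest.approx(k * k * ellipse_area(e), rel=1e-12)

    def test_long_axis(self, canonical_ellipse):
        assert long_axis(canonical_ellipse) == 10.0
        assert long_axis(Ellipse(0, 0, 4, 4, 0)) == 8.0
        assert long_axis(canonical_ellipse) >= 2 * canonical_ellipse.b


class TestRasterize:
    def test_circle_pixel_count_bounds(self):
        e = Ellipse(100, 100, 50, 50, 0)
        pix = rasterize_ellipse_arc(e, (0, 2 * math.pi), (256, 256))
        assert 2 * math.pi * 50 <= len(pix) <= 1.5 * 2 * math.pi * 50

    def test_degenerate_arc(self):
        e = Ellipse(10, 10, 5, 3, 0)
        pix = rasterize_ellipse_arc(e, (1.0, 1.0), (64, 64))
        assert len(pix) <= 1

    def test_pixels_near_boundary(self, rng):
        e = random_ellipse(rng, aspect_max=2.0)
        e = Ellipse(128, 128, e.a, e.b, e.theta)
        pix = rasterize_ellipse_arc(e, (0, 2 * math.pi), (256, 256)).astype(float)
        assert np.max(points_ellipse_distance(pix, e)) <= 1.0

    def test_eight_connectivity(self):
        e = Ellipse(60, 60, 40, 25, 0.7)
        pix = rasterize_ellipse_arc(e, (0.3, 2.5), (128, 128))
        steps = np.abs(np.diff(pix, axis=0))
        assert np.all(steps.max(axis=1) <= 1)

    def test_outside_image_empty(self):
        e = Ellipse(1000, 1000, 5, 3, 0)
        assert len(rasterize_ellipse_arc(e, (0, 2 * math.pi), (64, 64))) == 0

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            rasterize_ellipse_arc(Ellipse(0, 0, 5, 3, 0), (1.0, 0.5), (64, 64))


@settings(max_examples=25, deadline=None)
@given(
    a=st.floats(2.0, 50.0),
    ratio=st.floats(1.0, 5.0),
    theta=st.floats(0.0, math.pi - 1e-9),
    seed=st.integers(0, 2**16),
)
def test_fit_recovers_random_ellipses(a, ratio, theta, seed):
    e = Ellipse(10.0, -5.0, a, a / ratio, theta)
    pts = sample_on_ellipse(e, 60, np.random.default_rng(seed))
    f = fit_ellipse_lsq(pts)
    assert f.a == pytest.approx(e.a, rel=1e-6)
    assert f.b == pytest.approx(e.b, rel=1e-6)


def test_arc_length_full_equals_perimeter(canonical_ellipse):
    full = ellipse_arc_length(canonical_ellipse, 0.0, 2 * math.pi, n=4096)
    assert full == pytest.approx(ellipse_perimeter(canonical_ellipse), rel=1e-6)
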