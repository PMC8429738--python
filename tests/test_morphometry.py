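"""Geometry core: contours, calibration, axes, chords, measurements."""

import math

import numpy as np
import pytest
from skimage import draw as skdraw

from craniometry import morphometry as mm


def ellipse_contour(a, b, n=2000, rotate_deg=0.0, center=(0.0, 0.0)):
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    x, y = a * np.cos(t), b * np.sin(t)
    th = math.radians(rotate_deg)
    xr = x * math.cos(th) - y * math.sin(th) + center[0]
    yr = x * math.sin(th) + y * math.cos(th) + center[1]
    return mm.ensure_closed(np.column_stack([xr, yr]))


class TestPolygonPrimitives:
    def test_shoelace_area_of_unit_square(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]], dtype=float)
        assert mm.polygon_area(sq) == pytest.approx(1.0)
        assert mm.polygon_area(sq[::-1]) == pytest.approx(-1.0)

    def test_centroid_and_moments_of_offset_ellipse(self):
        c = ellipse_contour(5.0, 3.0, center=(2.0, -1.0))
        assert mm.polygon_centroid(c) == pytest.approx([2.0, -1.0], abs=1e-9)
        mu20, mu02, mu11 = mm.polygon_second_moments(c)
        area = abs(mm.polygon_area(c))
        # ellipse: mu20 = A a^2 / 4
        assert mu20 == pytest.approx(area * 25.0 / 4.0, rel=1e-4)
        assert mu02 == pytest.approx(area * 9.0 / 4.0, rel=1e-4)
        assert mu11 == pytest.approx(0.0, abs=1e-6)

    def test_self_intersection_detection(self):
        bowtie = np.array([[0, 0], [2, 2], [2, 0], [0, 2], [0, 0]], dtype=float)
        assert not mm.is_simple_polygon(bowtie)
        assert mm.is_simple_polygon(ellipse_contour(3, 2, n=64))


class TestExtractContour:
    def test_single_pixel_region_yields_small_closed_contour(self):
        mask = np.zeros((7, 7), dtype=np.uint8)
        mask[3, 3] = mm.HEAD
        contour = mm.extract_contour(mask, mm.HEAD)
        assert np.allclose(contour[0], contour[-1])
        area = mm.polygon_area(contour)
        assert 0.25 <= area <= 1.25  # marching squares: about one pixel

    def test_disc_area_matches_analytic(self):
        mask = np.zeros((160, 160), dtype=np.uint8)
        rr, cc = skdraw.disk((80, 80), 50)
        mask[rr, cc] = mm.HEAD
        contour = mm.extract_contour(mask, mm.HEAD)
        assert mm.polygon_area(contour) == pytest.approx(math.pi * 50**2, rel=0.01)
        assert np.allclose(contour[0], contour[-1])
        assert mm.polygon_area(contour) > 0  # counterclockwise

    def test_soft_field_contoured_directly(self):
        yy, xx = np.mgrid[0:64, 0:64]
        field = np.clip(1.5 - np.hypot(yy - 32, xx - 32) / 20.0, 0, 1)
        contour = mm.extract_contour(field)
        # 0.5 level sits at radius 20
        assert mm.polygon_area(contour) == pytest.approx(math.pi * 400, rel=0.01)

    def test_empty_and_multicomponent_errors(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        with pytest.raises(mm.MorphometryError, match="no pixels"):
            mm.extract_contour(mask, mm.HEAD)
        mask[1, 1] = mask[8, 8] = mm.HEAD
        with pytest.raises(mm.MorphometryError, match="one connected component"):
            mm.extract_contour(mask, mm.HEAD)


class TestCalibration:
    def test_equivalent_area_diameter(self):
        mask = np.zeros((200, 200), dtype=np.uint8)
        area = int(round(math.pi * 48.5**2))
        rows = np.repeat(np.arange(200), 200)[:area]
        cols = np.tile(np.arange(200), 200)[:area]
        mask[rows, cols] = mm.COIN
        cal = mm.calibrate_scale(mask)
        assert cal.coin_diameter_px == pytest.approx(97.0, abs=0.01)
        assert cal.mm_per_px == pytest.approx(0.25, rel=1e-3)

    def test_missing_and_tiny_coin(self):
        mask = np.zeros((50, 50), dtype=np.uint8)
        with pytest.raises(mm.MorphometryError, match="no coin"):
            mm.calibrate_scale(mask)
        mask[0, :10] = mm.COIN
        with pytest.raises(mm.MorphometryError, match="too small"):
            mm.calibrate_scale(mask)

    def test_scale_invariant_inconsistency_rejected(self):
        with pytest.raises(mm.MorphometryError):
            mm.ScaleCalibration(mm_per_px=1.0, coin_diameter_px=97.0, coin_center=(0, 0))


class TestPrincipalAxis:
    @pytest.mark.parametrize("angle", [-60.0, -10.0, 0.0, 30.0, 85.0])
    def test_rotated_ellipse(self, angle):
        c = ellipse_contour(8.5, 6.0, rotate_deg=angle)
        assert mm.principal_axis(c) == pytest.approx(angle, abs=0.5)

    def test_circle_tie_break_is_zero(self):
        assert mm.principal_axis(ellipse_contour(7.0, 7.0)) == 0.0

    def test_axis_invariant_under_180_rotation(self):
        c = ellipse_contour(8.0, 5.0, rotate_deg=40.0)
        flipped = mm.ensure_closed(-c[:-1])
        assert mm.principal_axis(c) == pytest.approx(mm.principal_axis(flipped), abs=1e-6)


class TestChordLength:
    def test_circle_chord_through_center(self):
        c = ellipse_contour(7.0, 7.0)
        for ang in (0.0, 33.0, 90.0):
            assert mm.chord_length(c, (0, 0), ang) == pytest.approx(14.0, rel=1e-4)

    def test_ellipse_40_degree_chord_closed_form(self):
        c = ellipse_contour(8.5, 6.0)
        th = math.radians(40.0)
        expected = 2 * 8.5 * 6.0 / math.sqrt(
            (6.0 * math.cos(th)) ** 2 + (8.5 * math.sin(th)) ** 2
        )
        assert mm.chord_length(c, (0, 0), 40.0) == pytest.approx(expected, rel=1e-4)
        assert expected == pytest.approx(14.286, abs=0.001)

    def test_chord_symmetric_under_half_turn(self):
        c = ellipse_contour(8.0, 5.0, rotate_deg=17.0)
        a = mm.chord_length(c, (0.5, -0.3), 25.0)
        b = mm.chord_length(c, (0.5, -0.3), 205.0)
        assert a == pytest.approx(b, rel=1e-12)

    def test_outside_point_rejected(self):
        c = ellipse_contour(3.0, 2.0)
        with pytest.raises(mm.MorphometryError, match="outside"):
            mm.chord_length(c, (10.0, 0.0), 0.0)


class TestMeasureHead:
    def test_circle_degenerate_case(self):
        scale = mm.ScaleCalibration(0.25, 97.0, (0, 0))
        # circle of diameter 14 cm at 0.25 mm/px -> radius 280 px
        c = ellipse_contour(280.0, 280.0)
        meas = mm.measure_head(c, scale, smooth=False)
        assert meas.ci_pct == pytest.approx(100.0, abs=0.01)
        assert meas.length_cm == pytest.approx(14.0, rel=1e-3)
        assert meas.width_cm == pytest.approx(14.0, rel=1e-3)
        assert meas.cvai_pct == pytest.approx(0.0, abs=0.01)
        assert meas.perimeter_cm == pytest.approx(math.pi * 14.0, rel=1e-3)

    def test_measurements_invariants(self):
        scale = mm.ScaleCalibration(0.25, 97.0, (0, 0))
        c = ellipse_contour(340.0, 240.0, rotate_deg=25.0)
        meas = mm.measure_head(c, scale)
        assert meas.width_cm <= meas.length_cm
        assert meas.diag_a_cm <= meas.perimeter_cm / 2
        assert meas.diag_b_cm <= meas.perimeter_cm / 2
        assert 0.0 <= meas.cvai_pct <= 100.0
        assert meas.ci_pct == pytest.approx(
            100 * meas.width_cm / meas.length_cm, rel=1e-9
        )

    def test_cvai_denominator_variants(self):
        scale = mm.ScaleCalibration(1.0, 24.25, (0, 0))
        c = ellipse_contour(100.0, 80.0, rotate_deg=10.0)
        longer = mm.measure_head(c, scale, cvai_denominator="longer")
        shorter = mm.measure_head(c, scale, cvai_denominator="shorter")
        assert longer.cvai_pct <= shorter.cvai_pct + 1e-12
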