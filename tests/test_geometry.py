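import math

import numpy as np
import pytest

from lcshift import geometry
from lcshift.types import LandmarkRecord

from conftest import make_record, random_simple_polygon, regular_polygon


# ---------------------------------------------------------------------------
# orientation normalization

class TestRightEyeOrientation:
    def test_right_eye_is_identity(self):
        rec = make_record()
        assert geometry.to_right_eye_orientation(rec) is rec

    def test_left_eye_mirrors_nasal_temporal_and_keeps_superior(self):
        # left eye, trunk 100 um temporal (toward fovea) and 50 um superior
        rec = make_record(laterality="left", fovea=(3000.0, 0.0), trunk=(100.0, 50.0))
        out = geometry.to_right_eye_orientation(rec)
        assert out.laterality == "right"
        # centroid at origin: temporal axis flips in raw x, superior unchanged
        assert out.trunk == pytest.approx((-100.0, 50.0))
        assert out.fovea == pytest.approx((-3000.0, 0.0))

    def test_mirroring_twice_restores_coordinates(self):
        rec = make_record(laterality="left", fovea=(3000.0, -250.0), trunk=(120.0, -80.0))
        once = geometry.to_right_eye_orientation(rec)
        # mirror by hand a second time and compare with the original
        cx, _ = geometry.bmo_centroid(once.bmo_margin)
        twice = tuple((2 * cx - x, y) for x, y in once.bmo_margin)
        assert np.allclose(sorted(twice), sorted(rec.bmo_margin), atol=1e-9)

    def test_unknown_laterality_rejected(self):
        with pytest.raises(ValueError, match="laterality"):
            make_record(laterality="both")


# ---------------------------------------------------------------------------
# centroid and axis

def shoelace_centroid(pts):
    pts = np.asarray(pts, float)
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = cross.sum() / 2.0
    cx = ((x + xn) * cross).sum() / (6 * a)
    cy = ((y + yn) * cross).sum() / (6 * a)
    return cx, cy


class TestBmoCentroid:
    def test_unit_square(self):
        sq = [(0, 0), (1, 0), (1, 1), (0, 1)]
        assert geometry.bmo_centroid(sq) == pytest.approx((0.5, 0.5))

    def test_regular_24gon_off_origin(self):
        poly = regular_polygon(24, r=750.0, center=(10.0, -3.0))
        assert geometry.bmo_centroid(poly) == pytest.approx((10.0, -3.0), abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_shoelace_oracle(self, seed):
        poly = random_simple_polygon(np.random.default_rng(seed))
        got = geometry.bmo_centroid(poly)
        want = shoelace_centroid(poly)
        assert got == pytest.approx(want, abs=1e-9)

    def test_cyclic_reordering_invariance(self):
        poly = random_simple_polygon(np.random.default_rng(3))
        rolled = poly[7:] + poly[:7]
        assert geometry.bmo_centroid(rolled) == pytest.approx(geometry.bmo_centroid(poly), abs=1e-9)

    def test_self_intersecting_rejected(self):
        bowtie = [(0, 0), (1, 1), (1, 0), (0, 1)]
        with pytest.raises(ValueError, match="self-intersecting"):
            geometry.bmo_centroid(bowtie)


class TestFobmoAxis:
    def test_horizontal(self):
        ax = geometry.fobmo_axis((0, 0), (-3000, 0))
        assert ax == pytest.approx([-1.0, 0.0])

    def test_tilted_is_normalized(self):
        ax = geometry.fobmo_axis((0, 0), (-3000, -300))
        want = math.atan2(-300, -3000)
        assert math.atan2(ax[1], ax[0]) == pytest.approx(want)
        assert np.hypot(*ax) == pytest.approx(1.0)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            c = rng.normal(size=2)
            f = c + rng.normal(size=2) * 100
            th = rng.uniform(-math.pi, math.pi)
            R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
            ax0 = geometry.fobmo_axis(tuple(c), tuple(f))
            ax1 = geometry.fobmo_axis(tuple(R @ c), tuple(R @ f))
            assert np.allclose(R @ ax0, ax1, atol=1e-12)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError, match="coincides"):
            geometry.fobmo_axis((1, 2), (1, 2))


# ---------------------------------------------------------------------------
# angles

NASAL = np.array([1.0, 0.0])  # fovea at -x => nasal ray +x


class TestAngularDeviation:
    @pytest.mark.parametrize(
        "trunk,expected",
        [
            ((200.0, 0.0), 0.0),       # exactly nasal
            ((0.0, 200.0), 90.0),      # exactly superior
            ((200.0, -200.0), -45.0),  # equal nasal and inferior offsets
        ],
    )
    def test_reference_directions(self, trunk, expected):
        assert geometry.angular_deviation((0, 0), trunk, NASAL) == pytest.approx(expected)

    def test_absent_trunk_is_missing(self):
        assert geometry.angular_deviation((0, 0), None, NASAL) is None

    def test_trunk_at_center_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="coincides"):
            assert geometry.angular_deviation((0, 0), (0, 0), NASAL) == 0.0

    def test_superior_sign_with_tilted_axis(self):
        # axis tilted: a point above the reference line is positive regardless
        temporal = geometry.fobmo_axis((0, 0), (-3000, -300))
        nasal = -temporal
        above = (200.0, 100.0)
        assert geometry.angular_deviation((0, 0), above, nasal) > 0


class TestPpaAngle:
    def test_temporal_zero(self):
        assert geometry.ppa_angular_location((0, 0), (-500.0, 0.0), np.array([-1.0, 0.0])) == pytest.approx(0.0)

    def test_inferior_minus_90(self):
        assert geometry.ppa_angular_location((0, 0), (0.0, -500.0), np.array([-1.0, 0.0])) == pytest.approx(-90.0)

    def test_missing_point(self):
        assert geometry.ppa_angular_location((0, 0), None, np.array([-1.0, 0.0])) is None


class TestObliqueness:
    @pytest.mark.parametrize("alpha,expected", [(90.0, 90.0), (0.0, 0.0), (-135.0, 45.0)])
    def test_examples(self, alpha, expected):
        assert geometry.obliqueness(alpha) == pytest.approx(expected)

    def test_symmetries(self):
        for a in np.linspace(-179.0, 180.0, 73):
            v = geometry.obliqueness(a)
            assert 0.0 <= v <= 90.0
            assert geometry.obliqueness(-a if a != 180.0 else 180.0) == pytest.approx(v) or a == 180.0
            mirrored = 180.0 - a
            if -180.0 < mirrored <= 180.0:
                assert geometry.obliqueness(mirrored) == pytest.approx(v)

    def test_missing(self):
        assert geometry.obliqueness(None) is None


# ---------------------------------------------------------------------------
# shift index

class TestShiftIndex:
    def test_trunk_at_center(self):
        assert geometry.shift_index((0, 0), (0, 0), regular_polygon()) == 0.0

    def test_circle_analytic(self):
        # circular margin radius 750, trunk 300 from centre -> 0.4
        poly = regular_polygon(n=720, r=750.0)
        si = geometry.shift_index((0, 0), (300.0, 0.0), poly)
        assert si == pytest.approx(0.4, abs=1e-6)

    def test_absent_trunk_convention(self):
        assert geometry.shift_index((0, 0), None, regular_polygon()) == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_circle_closed_form_any_direction(self, seed):
        rng = np.random.default_rng(seed)
        r = rng.uniform(500, 1200)
        poly = regular_polygon(n=2000, r=r)
        th = rng.uniform(0, 2 * math.pi)
        a = rng.uniform(0, r * 0.95)
        trunk = (a * math.cos(th), a * math.sin(th))
        assert geometry.shift_index((0, 0), trunk, poly) == pytest.approx(a / r, abs=1e-5)

    def test_in_unit_interval_for_random_polygons(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            poly = random_simple_polygon(rng)
            cx, cy = geometry.bmo_centroid(poly)
            # a trunk near the centroid is inside any star-shaped margin
            trunk = (cx + rng.normal(0, 50), cy + rng.normal(0, 50))
            si = geometry.shift_index((cx, cy), trunk, poly)
            assert 0.0 <= si <= 1.0


# ---------------------------------------------------------------------------
# grouping and depth

class TestShiftGroupAndLcd:
    @pytest.mark.parametrize("si,grp", [(0.25, "A"), (0.68, "B"), (1.0, "C"), (0.0, "A"), (0.5, "B")])
    def test_groups(self, si, grp):
        assert geometry.classify_shift_group(si) == grp

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            geometry.classify_shift_group(1.2)

    @pytest.mark.parametrize("plane,trunk,want", [(0, 546, 546), (100, 100, 0), (50, 581, 531)])
    def test_lcd_examples(self, plane, trunk, want):
        assert geometry.lcd(plane, trunk) == pytest.approx(want)

    def test_lcd_missing_and_floor(self):
        assert geometry.lcd(None, 500) is None
        with pytest.warns(UserWarning, match="floored"):
            assert geometry.lcd(200, 100) == 0.0


# ---------------------------------------------------------------------------
# whole-record invariants

def rigid_motion(rec: LandmarkRecord, theta: float, shift) -> LandmarkRecord:
    R = np.array([[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]])

    def mv(p):
        return None if p is None else tuple(R @ np.asarray(p) + shift)

    return LandmarkRecord(
        eye_id=rec.eye_id, laterality=rec.laterality,
        bmo_margin=tuple(mv(p) for p in rec.bmo_margin),
        fovea=mv(rec.fovea), trunk=mv(rec.trunk),
        trunk_depth_um=rec.trunk_depth_um, bmo_plane_depth_um=rec.bmo_plane_depth_um,
        ppa_max_point=mv(rec.ppa_max_point),
    )


class TestSummaryInvariants:
    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(5)
        rec = make_record(trunk=(250.0, 180.0), fovea=(-2900.0, -350.0),
                          ppa_max_point=(-800.0, -100.0),
                          trunk_depth_um=540.0, bmo_plane_depth_um=100.0)
        base = geometry.summarize_geometry(rec)
        for _ in range(10):
            moved = rigid_motion(rec, rng.uniform(-math.pi, math.pi), rng.normal(0, 500, 2))
            got = geometry.summarize_geometry(moved)
            assert got.alpha_deg == pytest.approx(base.alpha_deg, abs=1e-9)
            assert got.shift_index == pytest.approx(base.shift_index, abs=1e-9)
            assert got.beta_deg == pytest.approx(base.beta_deg, abs=1e-9)
            assert got.obliqueness_deg == pytest.approx(base.obliqueness_deg, abs=1e-9)

    def test_left_right_mirror_consistency(self):
        right = make_record(trunk=(250.0, 180.0), fovea=(-2900.0, -350.0),
                            ppa_max_point=(-800.0, -100.0))
        # hand-constructed left-eye mirror of the same anatomy (about x = 0)
        left = LandmarkRecord(
            eye_id=right.eye_id, laterality="left",
            bmo_margin=tuple((-x, y) for x, y in reversed(right.bmo_margin)),
            fovea=(-right.fovea[0], right.fovea[1]),
            trunk=(-right.trunk[0], right.trunk[1]),
            ppa_max_point=(-right.ppa_max_point[0], right.ppa_max_point[1]),
        )
        a, b = geometry.summarize_geometry(right), geometry.summarize_geometry(left)
        assert a.alpha_deg == pytest.approx(b.alpha_deg, abs=1e-9)
        assert a.shift_index == pytest.approx(b.shift_index, abs=1e-9)
        assert a.beta_deg == pytest.approx(b.beta_deg, abs=1e-9)
        assert a.bmo_area_mm2 == pytest.approx(b.bmo_area_mm2, abs=1e-12)

    def test_severe_shift_summary_consistency(self):
        rec = make_record(trunk=None)
        s = geometry.summarize_geometry(rec)
        assert s.shift_index == 1.0
        assert s.shift_group == "C"
        assert s.alpha_deg is None and s.obliqueness_deg is None

    def test_bmo_area_matches_polygon_area(self):
        rec = make_record()
        s = geometry.summarize_geometry(rec)
        # regular 24-gon of circumradius 750 um
        want = 0.5 * 24 * 750.0**2 * math.sin(2 * math.pi / 24) / 1e6
        assert s.bmo_area_mm2 == pytest.approx(want, rel=1e-12)
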