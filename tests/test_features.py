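"""Geometry of the four posture angles and three vertical distances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fhpdetect.errors import DegenerateGeometryError, InvalidTriangleError
from fhpdetect.features import (
    AnatomicalPoints, FEATURE_COLUMNS, compute_features, ena_angle,
    feature_frame, horizontal_angle, law_of_cosines_angle, vertical_distance,
)
from fhpdetect.landmark_io import SubjectMeta

coord = st.floats(min_value=-500, max_value=500, allow_nan=False)


def _atan2_horizontal(vertex, p):
    return math.degrees(math.atan2(abs(p[1] - vertex[1]), abs(p[0] - vertex[0])))


def _vector_angle(v, a, b):
    """Independent oracle: angle at v between v->a and v->b via dot product."""
    ua = np.array(a) - np.array(v)
    ub = np.array(b) - np.array(v)
    cos = np.dot(ua, ub) / (np.linalg.norm(ua) * np.linalg.norm(ub))
    return math.degrees(math.acos(np.clip(cos, -1, 1)))


class TestLawOfCosines:
    @pytest.mark.parametrize("a,b,c,expected", [
        (5, 3, 4, 90.0),          # Pythagorean triple
        (1, 1, 1, 60.0),          # equilateral
        (2, 1, 1, 180.0),         # collinear, clamped cosine
    ])
    def test_known_triangles(self, a, b, c, expected):
        assert law_of_cosines_angle(a, b, c) == pytest.approx(expected, abs=1e-9)

    def test_zero_side_is_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            law_of_cosines_angle(1.0, 0.0, 1.0)

    def test_triangle_inequality_enforced(self):
        with pytest.raises(InvalidTriangleError):
            law_of_cosines_angle(10.0, 1.0, 2.0)

    @given(vx=coord, vy=coord, ax=coord, ay=coord, bx=coord, by=coord)
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_reconstruction_oracle(self, vx, vy, ax, ay, bx, by):
        """Given the three side lengths, rebuild coordinates (vertex at the
        origin, side c on the x-axis) and compare with atan2 of the rebuilt
        point.  Ill-conditioned needle triangles, where the rounded sides
        themselves no longer pin the angle down to the tolerance, are
        filtered out."""
        v, a, b = (vx, vy), (ax, ay), (bx, by)
        sb, sc = math.dist(v, a), math.dist(v, b)
        if min(sb, sc) < 1e-2 or min(sb, sc) / max(sb, sc) < 0.02:
            return
        sa = math.dist(a, b)
        got = law_of_cosines_angle(sa, sb, sc)
        if not 0.5 < got < 179.5:
            return
        px = (sb * sb + sc * sc - sa * sa) / (2 * sc)
        py = math.sqrt(max(0.0, sb * sb - px * px))
        assert got == pytest.approx(math.degrees(math.atan2(py, px)), abs=1e-9)


class TestHorizontalAngle:
    @pytest.mark.parametrize("vertex,p,expected", [
        ((0, 0), (5, 0), 0.0),
        ((0, 0), (0, 5), 90.0),
        ((0, 0), (3, 4), 53.13010235415598),
        ((0, 0), (-3, 4), 53.13010235415598),   # mirror in x
        ((0, 0), (3, -4), 53.13010235415598),   # above vs below the row
    ])
    def test_examples(self, vertex, p, expected):
        assert horizontal_angle(vertex, p) == pytest.approx(expected, abs=1e-9)

    def test_coincident_point_raises(self):
        with pytest.raises(DegenerateGeometryError):
            horizontal_angle((1, 1), (1, 1))

    @given(vx=coord, vy=coord, px=coord, py=coord)
    @settings(max_examples=200, deadline=None)
    def test_matches_atan2_oracle_and_range(self, vx, vy, px, py):
        if math.dist((vx, vy), (px, py)) < 1e-3:
            return
        got = horizontal_angle((vx, vy), (px, py))
        assert 0.0 <= got <= 90.0
        assert got == pytest.approx(_atan2_horizontal((vx, vy), (px, py)), abs=1e-9)


class TestEnaAngle:
    @pytest.mark.parametrize("np_,reamp,expected", [
        ((10, 0), (0, 10), 90.0),
        ((2, 0), (1, 1), 45.0),
    ])
    def test_examples(self, np_, reamp, expected):
        pts = AnatomicalPoints(RAP=(0, 0), NP=np_, RPCP=(5, 5), REAMP=reamp)
        assert ena_angle(pts) == pytest.approx(expected, abs=1e-9)

    @given(nx=coord, ny=coord, ex=coord, ey=coord)
    @settings(max_examples=200, deadline=None)
    def test_matches_dot_product_oracle(self, nx, ny, ex, ey):
        if math.hypot(nx, ny) < 1e-3 or math.hypot(ex, ey) < 1e-3:
            return
        pts = AnatomicalPoints(RAP=(0.0, 0.0), NP=(nx, ny), RPCP=(1.0, 1.0), REAMP=(ex, ey))
        got = ena_angle(pts)
        assert 0.0 <= got <= 180.0
        if got < 5e-3 or got > 179.9:  # acos in the oracle is ill-conditioned at 0/180
            return
        assert got == pytest.approx(_vector_angle((0, 0), (nx, ny), (ex, ey)), abs=1e-9)


@pytest.mark.parametrize("vertex,p,expected", [
    ((0, 0), (3, 4), 4.0),
    ((0, 7), (9, 7), 0.0),
    ((0, -2), (1, 5), 7.0),
])
def test_vertical_distance(vertex, p, expected):
    assert vertical_distance(vertex, p) == expected


class TestComputeFeatures:
    def test_collinear_vertical_pose(self):
        pts = AnatomicalPoints(RAP=(0, 0), NP=(0, 10), RPCP=(0, 11), REAMP=(0, 12))
        fv = compute_features(pts)
        assert (fv.NAH, fv.PAH, fv.EAH) == (90.0, 90.0, 90.0)
        assert fv.ENA == pytest.approx(0.0, abs=1e-9)
        assert (fv.d1, fv.d2, fv.d3) == (10.0, 11.0, 12.0)

    def test_hand_placed_pose_against_independent_calculator(self):
        # all seven geometric features recomputed with raw numpy here
        rap, np_, rpcp, reamp = (100.0, 400.0), (220.0, 270.0), (190.0, 245.0), (175.0, 260.0)
        fv = compute_features(AnatomicalPoints(rap, np_, rpcp, reamp))
        assert fv.NAH == pytest.approx(_atan2_horizontal(rap, np_), abs=1e-9)
        assert fv.PAH == pytest.approx(_atan2_horizontal(rap, rpcp), abs=1e-9)
        assert fv.EAH == pytest.approx(_atan2_horizontal(rap, reamp), abs=1e-9)
        assert fv.ENA == pytest.approx(_vector_angle(rap, np_, reamp), abs=1e-9)
        assert fv.d1 == abs(np_[1] - rap[1])
        assert fv.d2 == abs(rpcp[1] - rap[1])
        assert fv.d3 == abs(reamp[1] - rap[1])

    def test_degenerate_point_names_offending_feature(self):
        pts = AnatomicalPoints(RAP=(0, 0), NP=(0.0, 0.0), RPCP=(1, 1), REAMP=(2, 2))
        with pytest.raises(DegenerateGeometryError, match="NAH"):
            compute_features(pts)

    def test_bmi_recomputed_and_gender_encoded(self):
        pts = AnatomicalPoints(RAP=(0, 0), NP=(5, 10), RPCP=(4, 11), REAMP=(3, 12))
        meta = SubjectMeta(gender="male", age=12, height=160.0, weight=51.2, label="FHP")
        fv = compute_features(pts, meta)
        assert fv.gender == 1
        assert fv.bmi == pytest.approx(51.2 / 1.6 ** 2)
        assert fv.label == 1

    @given(dx=coord, dy=coord, s=st.floats(min_value=0.1, max_value=50))
    @settings(max_examples=100, deadline=None)
    def test_translation_and_scale_invariance(self, dx, dy, s):
        base = AnatomicalPoints(RAP=(10, 40), NP=(60, 5), RPCP=(55, 0), REAMP=(45, 8))
        f0 = compute_features(base)
        moved = AnatomicalPoints(
            *[(s * (p[0] + dx), s * (p[1] + dy))
              for p in (base.RAP, base.NP, base.RPCP, base.REAMP)])
        f1 = compute_features(moved)
        for ang in ("NAH", "ENA", "PAH", "EAH"):
            assert getattr(f1, ang) == pytest.approx(getattr(f0, ang), abs=1e-6)
        for d in ("d1", "d2", "d3"):
            assert getattr(f1, d) == pytest.approx(s * getattr(f0, d), rel=1e-9)

    def test_mirror_invariance_in_x(self):
        base = AnatomicalPoints(RAP=(10, 40), NP=(60, 5), RPCP=(55, 0), REAMP=(45, 8))
        mirrored = AnatomicalPoints(
            *[(200.0 - p[0], p[1]) for p in (base.RAP, base.NP, base.RPCP, base.REAMP)])
        f0, f1 = compute_features(base), compute_features(mirrored)
        for name in ("NAH", "ENA", "PAH", "EAH", "d1", "d2", "d3"):
            assert getattr(f1, name) == pytest.approx(getattr(f0, name), abs=1e-9)


def test_feature_frame_column_order():
    pts = AnatomicalPoints(RAP=(0, 0), NP=(5, 10), RPCP=(4, 11), REAMP=(3, 12))
    df = feature_frame([compute_features(pts, subject_id="a")])
    assert list(df.columns) == ["subject_id"] + FEATURE_COLUMNS + ["label"]
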