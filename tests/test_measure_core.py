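"""Geometry: arc lengths, calibration, fragment joining, centromere placement."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from karyodraw.measure_core import (
    ChromosomeMeasurement,
    Landmark,
    MeasurementError,
    Polyline,
    calibrate,
    join_fragments,
    landmark_relative,
    place_centromere,
    polyline_length,
)


def brute_force_length(vertices):
    return sum(
        math.hypot(x2 - x1, y2 - y1)
        for (x1, y1), (x2, y2) in zip(vertices, vertices[1:])
    )


class TestPolylineLength:
    @pytest.mark.parametrize(
        "verts,expected",
        [
            ([(0, 0), (3, 4)], 5.0),           # 3-4-5 segment
            ([(7, 7)], 0.0),                   # degenerate single point
            ([(0, 0), (1, 0), (1, 1)], 2.0),   # L-shape
        ],
    )
    def test_examples(self, verts, expected):
        assert polyline_length(Polyline(verts)) == pytest.approx(expected)

    def test_matches_per_segment_summation_oracle(self, rng):
        for _ in range(25):
            verts = [tuple(p) for p in rng.uniform(-100, 100, size=(10, 2))]
            assert polyline_length(Polyline(verts)) == pytest.approx(
                brute_force_length(verts), rel=1e-12)

    @given(
        st.lists(
            st.tuples(st.floats(-1e3, 1e3), st.floats(-1e3, 1e3)),
            min_size=2, max_size=12,
        ),
        st.floats(0, 2 * math.pi),
        st.tuples(st.floats(-1e3, 1e3), st.floats(-1e3, 1e3)),
    )
    @settings(max_examples=60, deadline=None)
    def test_rigid_motion_invariance(self, verts, angle, shift):
        """Rotating and translating every vertex leaves arc length unchanged."""
        p = Polyline(verts)
        c, s = math.cos(angle), math.sin(angle)
        dx, dy = shift
        moved = Polyline(
            [(c * x - s * y + dx, s * x + c * y + dy) for x, y in verts])
        assert polyline_length(moved) == pytest.approx(
            polyline_length(p), rel=1e-9, abs=1e-9)

    def test_rejects_non_finite(self):
        with pytest.raises(MeasurementError):
            Polyline([(0, 0), (float("nan"), 1)])
        with pytest.raises(MeasurementError):
            Polyline([])


class TestCalibrate:
    def test_horizontal_and_vertical_bars(self):
        assert calibrate(Polyline([(0, 0), (100, 0)]), 10).pixels_per_micron == 10
        assert calibrate(Polyline([(0, 0), (0, 50)]), 10).pixels_per_micron == 5

    def test_bent_bar_equals_straight_bar_of_same_arc_length(self):
        bent = Polyline([(0, 0), (30, 40), (60, 0), (90, 40)])
        straight = Polyline([(0, 0), (polyline_length(bent), 0)])
        assert calibrate(bent, 12.5).pixels_per_micron == pytest.approx(
            calibrate(straight, 12.5).pixels_per_micron)

    def test_invalid_inputs(self):
        with pytest.raises(MeasurementError):
            calibrate(Polyline([(1, 1), (1, 1)]), 10)
        with pytest.raises(MeasurementError):
            calibrate(Polyline([(0, 0), (5, 0)]), 0)


class TestJoinFragments:
    def test_gap_contributes_zero_length(self):
        f1 = Polyline([(0, 0), (12, 0)])
        f2 = Polyline([(500, 500), (500, 508)])  # far away: gap not counted
        joined, total = join_fragments([f1, f2])
        assert total == pytest.approx(20.0)
        # local arc 3 on fragment 2 -> global arc 15
        assert 12.0 + 3.0 == pytest.approx(15.0)

    def test_single_fragment_identity(self):
        f = Polyline([(0, 0), (3, 4), (10, 4)])
        joined, total = join_fragments([f])
        assert total == pytest.approx(polyline_length(f))
        assert joined.vertices == f.vertices

    def test_total_is_sum_of_fragment_lengths(self, rng):
        frags = [
            Polyline([tuple(p) for p in rng.uniform(0, 50, size=(5, 2))])
            for _ in range(3)
        ]
        _, total = join_fragments(frags)
        assert total == pytest.approx(sum(polyline_length(f) for f in frags))

    def test_empty_list_rejected(self):
        with pytest.raises(MeasurementError):
            join_fragments([])


def _chromosome(L=10.0, landmarks=()):
    return ChromosomeMeasurement(
        name="c", fragments=[Polyline([(0.0, 0.0), (L, 0.0)])],
        landmarks=list(landmarks))


class TestPlaceCentromere:
    def test_short_arm_already_first(self):
        m = place_centromere(_chromosome(10), 2)
        assert m.short_arm == pytest.approx(2)
        assert m.long_arm == pytest.approx(8)

    def test_flip_reflects_centromere_and_landmarks(self):
        lm = Landmark("s", "signal_point", "#fff", 9.0, 9.0)
        m = place_centromere(_chromosome(10, [lm]), 8)
        assert m.short_arm == pytest.approx(2)
        assert m.landmarks[0].arc_start == pytest.approx(1.0)

    def test_exact_metacentric_not_flipped(self):
        m = place_centromere(_chromosome(10), 5)
        assert m.short_arm == pytest.approx(5)
        assert m.fragments[0].vertices[0] == (0.0, 0.0)

    def test_idempotent_normalizer(self, rng):
        for _ in range(20):
            L = float(rng.uniform(5, 40))
            arc = float(rng.uniform(0.1, 0.9)) * L
            once = place_centromere(_chromosome(L), arc)
            twice = place_centromere(once, once.centromere_arc)
            assert twice.centromere_arc == pytest.approx(once.centromere_arc)
            assert once.short_arm <= once.long_arm + 1e-12

    def test_arc_outside_open_interval_rejected(self):
        for bad in (0.0, 10.0, -1.0, 11.0):
            with pytest.raises(MeasurementError):
                place_centromere(_chromosome(10), bad)


class TestLandmarkRelative:
    @pytest.mark.parametrize(
        "a,b,expected_arm,expected_fracs",
        [
            (1.0, 1.0, "p", (0.1, 0.1)),        # point on short arm
            (4.0, 6.0, "q", (0.4, 0.6)),        # band on long arm
            (1.0, 3.0, "spanning", (0.1, 0.3)), # straddles the centromere
            (2.0, 2.0, "p", (0.2, 0.2)),        # point at centromere -> p
            (2.0, 5.0, "q", (0.2, 0.5)),        # starts at centromere -> q
        ],
    )
    def test_arm_assignment(self, a, b, expected_arm, expected_fracs):
        m = place_centromere(_chromosome(10), 2)
        kind = "signal_point" if a == b else "band"
        rel = landmark_relative(m, Landmark("x", kind, "#000", a, b))
        assert rel.arm == expected_arm
        assert (rel.frac_start, rel.frac_end) == pytest.approx(expected_fracs)

    def test_size_calibration(self):
        from karyodraw.measure_core import ScaleCalibration

        m = place_centromere(_chromosome(10), 2)
        lm = Landmark("b", "band", "#000", 4.0, 6.0)
        assert landmark_relative(m, lm).size == pytest.approx(2.0)  # px
        cal = ScaleCalibration(bar_pixels=20, bar_physical=10)  # 2 px/µm
        rel = landmark_relative(m, lm, cal)
        assert rel.size == pytest.approx(1.0) and rel.unit == "um"

    @given(st.floats(0.01, 100.0))
    @settings(max_examples=40, deadline=None)
    def test_fractions_invariant_under_uniform_scaling(self, k):
        m1 = place_centromere(_chromosome(10), 3)
        m2 = place_centromere(_chromosome(10 * k), 3 * k)
        lm1 = Landmark("x", "band", "#000", 4.0, 7.0)
        lm2 = Landmark("x", "band", "#000", 4.0 * k, 7.0 * k)
        r1, r2 = landmark_relative(m1, lm1), landmark_relative(m2, lm2)
        assert r2.frac_start == pytest.approx(r1.frac_start, rel=1e-9)
        assert r2.frac_end == pytest.approx(r1.frac_end, rel=1e-9)

    def test_landmark_beyond_path_rejected(self):
        m = place_centromere(_chromosome(10), 2)
        with pytest.raises(MeasurementError):
            landmark_relative(m, Landmark("x", "band", "#000", 8.0, 12.0))
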