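"""Metric primitives against independent brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gallerytrack.datamodel import Gallery, Point
from gallerytrack.errors import CalibrationError, DegeneratePolylineError
from gallerytrack.geometry import (point_to_polyline_distance, polyline_length,
                                   scale_factor, snap_endpoints,
                                   translate_to_ref)


def _pts(coords):
    return [Point(float(x), float(y)) for x, y in coords]


class TestPolylineLength:
    @pytest.mark.parametrize("coords,expected", [
        ([(0, 0), (3, 4)], 5.0),                   # 3-4-5 triangle
        ([(0, 0), (1, 0), (1, 1)], 2.0),           # unit steps
        ([(0, 0), (0, -7)], 7.0),
    ])
    def test_known_lengths(self, coords, expected):
        assert polyline_length(_pts(coords)) == pytest.approx(expected)

    def test_matches_per_segment_hand_sum(self, rng):
        pts = rng.uniform(0, 500, size=(10, 2))
        hand = sum(math.hypot(pts[i + 1][0] - pts[i][0], pts[i + 1][1] - pts[i][1])
                   for i in range(len(pts) - 1))
        assert polyline_length(_pts(pts)) == pytest.approx(hand, rel=1e-12)

    def test_degenerate_rejected(self):
        with pytest.raises(DegeneratePolylineError):
            polyline_length(_pts([(0, 0)]))

    def test_additive_under_concatenation(self, rng):
        pts = _pts(rng.uniform(0, 100, size=(8, 2)))
        whole = polyline_length(pts)
        parts = polyline_length(pts[:4]) + polyline_length(pts[3:])
        assert whole == pytest.approx(parts, rel=1e-12)

    @given(st.floats(-300, 300), st.floats(-300, 300),
           st.floats(0.1, math.tau))
    def test_invariant_under_translation_and_rotation(self, dx, dy, theta):
        pts = np.array([[0, 0], [13, 7], [20, -5], [31, 2]], dtype=float)
        rot = np.array([[math.cos(theta), -math.sin(theta)],
                        [math.sin(theta), math.cos(theta)]])
        moved = pts @ rot.T + [dx, dy]
        assert polyline_length(_pts(moved)) == pytest.approx(
            polyline_length(_pts(pts)), rel=1e-9)

    @given(st.floats(0.01, 50))
    def test_scales_linearly(self, k):
        pts = np.array([[0, 0], [3, 4], [10, -1]], dtype=float)
        assert polyline_length(_pts(pts * k)) == pytest.approx(
            k * polyline_length(_pts(pts)), rel=1e-9)


class TestScaleFactor:
    @pytest.mark.parametrize("line,mm,expected", [
        (((0, 0), (100, 0)), 10.0, 0.1),
        (((0, 0), (0, 50)), 50.0, 1.0),
        (((0, 0), (30, 40)), 25.0, 0.5),   # diagonal: 3-4-5 gives 50 px
    ])
    def test_known_calibrations(self, line, mm, expected):
        a, b = line
        assert scale_factor((Point(*a), Point(*b)), mm) == pytest.approx(expected)

    def test_zero_length_line_rejected(self):
        with pytest.raises(CalibrationError):
            scale_factor((Point(5, 5), Point(5, 5)), 10.0)
        with pytest.raises(CalibrationError):
            scale_factor((Point(0, 0), Point(1, 0)), -3.0)


class TestTranslateToRef:
    def test_moves_ref_to_origin(self):
        assert translate_to_ref([Point(5, 5)], Point(5, 5)) == [Point(0, 0)]

    def test_absent_ref_is_identity(self):
        pts = _pts([(3, 4), (8, 1)])
        assert translate_to_ref(pts, None) == pts

    @given(st.floats(-100, 100), st.floats(-100, 100),
           st.floats(-100, 100), st.floats(-100, 100))
    def test_composition(self, x1, y1, x2, y2):
        pts = _pts([(7, 11), (0, -2)])
        r1, r2 = Point(x1, y1), Point(x2, y2)
        once = translate_to_ref(translate_to_ref(pts, r1), r2)
        both = translate_to_ref(pts, Point(x1 + x2, y1 + y2))
        for a, b in zip(once, both):
            assert a.distance_to(b) < 1e-9


def _dense_sampling_oracle(p, coords, n=None):
    """Brute force: min distance over points sampled evenly by arc length.

    The sample spacing is kept at 1e-3 px of arc (unless ``n`` is forced),
    so the oracle's own discretization error stays below the comparison
    tolerance of the tests that use it.
    """
    pts = np.asarray(coords, dtype=float)
    seg = np.diff(pts, axis=0)
    lens = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(lens)])
    if n is None:
        n = max(10_000, int(cum[-1] / 1e-3) + 1)
    s = np.linspace(0, cum[-1], n)
    idx = np.clip(np.searchsorted(cum[1:], s), 0, len(lens) - 1)
    t = (s - cum[idx]) / np.where(lens[idx] == 0, 1, lens[idx])
    samples = pts[idx] + t[:, None] * seg[idx]
    d = np.hypot(samples[:, 0] - p[0], samples[:, 1] - p[1])
    k = int(d.argmin())
    return float(d[k]), float(s[k])


class TestPointToPolylineDistance:
    def test_perpendicular_foot(self):
        d, s = point_to_polyline_distance(Point(1, 1), _pts([(0, 0), (2, 0)]))
        assert d == pytest.approx(1.0)
        assert s == pytest.approx(1.0)

    def test_point_on_vertex(self):
        d, _ = point_to_polyline_distance(Point(2, 0), _pts([(0, 0), (2, 0), (2, 5)]))
        assert d == 0.0

    def test_projection_beats_vertex_only(self):
        # nearest point is mid-segment, far from every clicked vertex
        d, s = point_to_polyline_distance(Point(50, 3), _pts([(0, 0), (100, 0)]))
        assert d == pytest.approx(3.0)
        assert s == pytest.approx(50.0)

    def test_against_dense_sampling_oracle(self, rng):
        for _ in range(20):
            coords = rng.uniform(0, 200, size=(20, 2))
            p = rng.uniform(0, 200, size=2)
            d, s = point_to_polyline_distance(Point(*p), _pts(coords))
            d_o, s_o = _dense_sampling_oracle(p, coords)
            assert abs(d - d_o) < 1e-3
            # arc-length may differ when two stretches are near-equidistant;
            # the distances at both positions must then agree closely
            assert d <= d_o + 1e-3


def _union_find_oracle(coords, threshold):
    """Hand union-find over all O(n^2) pairs with strict <."""
    n = len(coords)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if math.dist(coords[i], coords[j]) < threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


class TestSnapEndpoints:
    def test_two_close_points_merge(self):
        clusters = snap_endpoints(_pts([(0, 0), (3, 0)]), 5.0)
        assert len(clusters) == 1
        assert clusters[0].representative == Point(1.5, 0.0)

    def test_far_points_stay_apart(self):
        assert len(snap_endpoints(_pts([(0, 0), (100, 0)]), 5.0)) == 2

    def test_single_linkage_chaining(self):
        # 0-4-8: consecutive gaps below threshold chain into one cluster,
        # although the extremes are 8 > 5 apart
        clusters = snap_endpoints(_pts([(0, 0), (4, 0), (8, 0)]), 5.0)
        assert len(clusters) == 1

    def test_threshold_is_strict(self):
        assert len(snap_endpoints(_pts([(0, 0), (5, 0)]), 5.0)) == 2
        assert len(snap_endpoints(_pts([(0, 0), (4.999, 0)]), 5.0)) == 1

    def test_against_pairwise_union_find_oracle(self, rng):
        for _ in range(30):
            coords = rng.uniform(0, 60, size=(rng.integers(1, 40), 2))
            threshold = float(rng.uniform(2, 15))
            clusters = snap_endpoints(_pts(coords), threshold)
            got = {frozenset(c.member_indices) for c in clusters}
            assert got == _union_find_oracle(coords.tolist(), threshold)

    def test_partition_and_order_independence(self, rng):
        coords = rng.uniform(0, 50, size=(25, 2))
        clusters = snap_endpoints(_pts(coords), 6.0)
        all_indices = sorted(i for c in clusters for i in c.member_indices)
        assert all_indices == list(range(25))  # disjoint and covering
        perm = rng.permutation(25)
        permuted = snap_endpoints(_pts(coords[perm]), 6.0)
        orig_sets = {frozenset(map(tuple, np.asarray(
            [p.as_tuple() for p in c.member_points]))) for c in clusters}
        perm_sets = {frozenset(map(tuple, np.asarray(
            [p.as_tuple() for p in c.member_points]))) for c in permuted}
        assert orig_sets == perm_sets

    def test_empty_input(self):
        assert snap_endpoints([], 5.0) == []
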