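"""Temporal logic: copy-forward, append consistency, growth series."""

import pytest

from gallerytrack.datamodel import (Gallery, ImageAnnotation, Point,
                                    ProjectState, Status)
from gallerytrack.errors import UnresolvableSkipError
from gallerytrack.sequence import (analyze_group, check_append_consistency,
                                   compute_series, materialize_series)
from gallerytrack.synthgen import GrowthParams, generate


def _ann(group, serial, status=Status.ANALYZED, galleries=(), ref=None,
         append=True):
    return ImageAnnotation(group_id=group, serial=serial, status=status,
                           ref_point=ref, append_mode=append,
                           galleries=list(galleries))


def _g(gid, coords):
    return Gallery(gid, [Point(float(x), float(y)) for x, y in coords])


def _project(anns, threshold=5.0):
    state = ProjectState(threshold_px=threshold)
    for a in anns:
        state.add(a)
    return state


class TestMaterialize:
    def test_skip_copies_previous_galleries(self):
        g0 = [_g("a", [(0, 0), (10, 0)]), _g("b", [(5, 1), (5, 9)])]
        state = _project([
            _ann("x", 0, galleries=g0),
            _ann("x", 1, status=Status.SKIPPED),
            _ann("x", 2, galleries=[_g("a", [(0, 0), (10, 0), (20, 0)])]),
        ])
        resolved = materialize_series(state, "x")
        assert [g.gallery_id for g in resolved[1].galleries] == ["a", "b"]
        assert resolved[1].galleries[0].points == g0[0].points
        # deep copy: mutating the resolved copy leaves the source untouched
        resolved[1].galleries[0].points.append(Point(99, 99))
        assert len(state.annotations[("x", 0)].galleries[0].points) == 2

    def test_transitive_copy(self):
        state = _project([
            _ann("x", 0, galleries=[_g("a", [(0, 0), (8, 0)])]),
            _ann("x", 1, status=Status.SKIPPED),
            _ann("x", 2, status=Status.SKIPPED),
        ])
        resolved = materialize_series(state, "x")
        for ann in resolved[1:]:
            assert [g.gallery_id for g in ann.galleries] == ["a"]

    def test_empty_images_resolve_to_zero_galleries(self):
        state = _project([_ann("x", 0, status=Status.EMPTY),
                          _ann("x", 1, status=Status.EMPTY)])
        resolved = materialize_series(state, "x")
        assert all(a.galleries == [] for a in resolved)

    def test_skip_on_first_serial_errors(self):
        state = _project([_ann("x", 0, status=Status.SKIPPED)])
        with pytest.raises(UnresolvableSkipError):
            materialize_series(state, "x")

    def test_idempotent(self):
        state = _project([
            _ann("x", 0, galleries=[_g("a", [(0, 0), (8, 0)])]),
            _ann("x", 1, status=Status.SKIPPED),
        ])
        once = materialize_series(state, "x")
        rebuilt = _project([a.copy() for a in once])
        twice = materialize_series(rebuilt, "x")
        assert [(a.serial, [g.points for g in a.galleries]) for a in once] == \
               [(a.serial, [g.points for g in a.galleries]) for a in twice]


class TestAppendConsistency:
    def test_pure_extension_passes(self):
        prev = _ann("x", 0, galleries=[_g("a", [(0, 0), (5, 0)])])
        curr = _ann("x", 1, galleries=[_g("a", [(0, 0), (5, 0), (9, 0)])])
        assert check_append_consistency(prev, curr, tol_px=1.0) == []

    def test_shortening_is_one_violation(self):
        prev = _ann("x", 0, galleries=[_g("a", [(0, 0), (5, 0), (9, 0)])])
        curr = _ann("x", 1, galleries=[_g("a", [(0, 0), (3, 0)])])
        violations = check_append_consistency(prev, curr, tol_px=1.0)
        assert len(violations) == 1
        assert violations[0].kind == "shortened"
        assert violations[0].gallery_id == "a"

    def test_not_appending_permits_anything(self):
        prev = _ann("x", 0, galleries=[_g("a", [(0, 0), (5, 0), (9, 0)])])
        curr = _ann("x", 1, append=False, galleries=[_g("a", [(0, 0), (3, 0)])])
        assert check_append_consistency(prev, curr, tol_px=1.0) == []

    def test_disappeared_gallery_flagged(self):
        prev = _ann("x", 0, galleries=[_g("a", [(0, 0), (5, 0)])])
        curr = _ann("x", 1, galleries=[])
        violations = check_append_consistency(prev, curr, tol_px=1.0)
        assert [v.kind for v in violations] == ["missing"]

    def test_ref_correction_absorbs_camera_shift(self):
        # identical structure, camera moved 50 px: no violation
        prev = _ann("x", 0, ref=Point(10, 10),
                    galleries=[_g("a", [(10, 10), (60, 10)])])
        curr = _ann("x", 1, ref=Point(60, 60),
                    galleries=[_g("a", [(60, 60), (110, 60), (140, 60)])])
        assert check_append_consistency(prev, curr, tol_px=0.5) == []

    def test_jitter_within_tolerance_ok(self):
        prev = _ann("x", 0, galleries=[_g("a", [(0, 0), (5, 0)])])
        curr = _ann("x", 1, galleries=[_g("a", [(0.4, 0.3), (5.2, 0.1), (9, 0)])])
        assert check_append_consistency(prev, curr, tol_px=1.0) == []
        assert len(check_append_consistency(prev, curr, tol_px=0.1)) == 1


class TestComputeSeries:
    def test_all_empty_series_yields_zero_records(self):
        state = _project([_ann("x", s, status=Status.EMPTY) for s in range(3)])
        records = compute_series(state, "x")
        assert len(records) == 3
        for r in records:
            assert r.total_mm == 0 and r.n_galleries == 0 and r.growth_mm == 0

    def test_skipped_image_duplicates_predecessor_with_zero_growth(self):
        state = _project([
            _ann("x", 0, galleries=[_g("a", [(0, 0), (10, 0)])]),
            _ann("x", 1, status=Status.SKIPPED),
        ])
        state.entrance_points["x"] = [Point(0, 0)]
        r0, r1 = compute_series(state, "x")
        assert r1.total_mm == r0.total_mm
        assert r1.n_nodes == r0.n_nodes
        assert r1.growth_mm == 0.0

    def test_first_increment_equals_total(self):
        state = _project([_ann("x", 0, galleries=[_g("a", [(0, 0), (10, 0)])])])
        state.entrance_points["x"] = [Point(0, 0)]
        (rec,) = compute_series(state, "x")
        assert rec.growth_mm == rec.total_mm == pytest.approx(10.0)

    def test_records_one_per_serial_in_order(self, grown_structure):
        state, _ = grown_structure
        records = compute_series(state, "synth")
        serials = [r.serial for r in records]
        assert serials == sorted({a.serial for a in state.group_annotations("synth")})

    def test_monotone_totals_under_append_mode(self, grown_structure):
        state, _ = grown_structure
        records = compute_series(state, "synth")
        totals = [r.total_mm for r in records]
        assert all(b >= a for a, b in zip(totals, totals[1:]))
        assert all(r.growth_mm >= 0 for r in records)

    def test_totals_match_generator_bookkeeping(self):
        state, truth = generate(GrowthParams(seed=9, n_steps=15, skip_prob=0.2))
        records = compute_series(state, "synth")
        by_serial = {r.serial: r for r in records}
        for st in truth.steps:
            assert by_serial[st.serial].total_mm == pytest.approx(
                st.total_mm, abs=1e-6)
            assert by_serial[st.serial].n_galleries == st.n_galleries

    def test_violations_surface_in_group_result(self):
        state = _project([
            _ann("x", 0, galleries=[_g("a", [(0, 0), (10, 0), (20, 0)])]),
            _ann("x", 1, galleries=[_g("a", [(0, 0), (10, 0)])]),
        ], threshold=2.0)
        res = analyze_group(state, "x")
        assert len(res.violations) == 1
        assert res.violations[0].serial == 1
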