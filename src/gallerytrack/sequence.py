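"""Temporal logic across an image series.

A gallery system is photographed repeatedly (e.g. every hour). This module
resolves the per-image annotations into a consistent time series:

* **copy-forward** — an image the user skipped (no development visible)
  inherits a deep copy of the nearest preceding analyzed/empty image's
  galleries, reference point and scale line;
* **zero records** — an image marked empty yields all-zero metrics;
* **append consistency** — under the default assumption that galleries only
  grow, every previous polyline must be a prefix of its successor
  (after reference alignment, within a pixel tolerance); backfilling is
  declared by the user with ``append_mode=False``, which permits free
  replacement;
* **growth increments** — per-step change of the total length in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .classification import ClassifiedGallery, assign_identities, rank_bin
from .datamodel import ImageAnnotation, ProjectState, Status
from .errors import ClassificationError, UnresolvableSkipError
from .geometry import polyline_length, scale_factor, translate_gallery, translate_to_ref
from .network import GalleryNetwork, build_network, network_summary

__all__ = [
    "TimeSeriesRecord", "AppendViolation", "GroupResult",
    "materialize_series", "check_append_consistency",
    "analyze_group", "compute_series",
]


@dataclass(frozen=True)
class TimeSeriesRecord:
    """Per-image summary row: per-rank and total lengths in mm, counts, growth."""

    group_id: str
    serial: int
    total_mm: float
    len1_mm: float
    len2_mm: float
    len3_mm: float
    len4plus_mm: float
    n_galleries: int
    n_nodes: int
    n_edges: int
    growth_mm: float


@dataclass(frozen=True)
class AppendViolation:
    """One gallery that broke the galleries-only-grow assumption."""

    group_id: str
    serial: int
    gallery_id: str
    kind: str      # "missing" | "shortened" | "moved"
    detail: str


@dataclass
class GroupResult:
    """Everything computed for one group, keyed by serial where per-image."""

    group_id: str
    records: list[TimeSeriesRecord]
    classified: dict[int, list[ClassifiedGallery]]
    networks: dict[int, GalleryNetwork]
    violations: list[AppendViolation] = field(default_factory=list)


def materialize_series(state: ProjectState, group_id: str) -> list[ImageAnnotation]:
    """Resolve a group's annotations: skipped images carry copied galleries.

    Skipped images receive a deep copy of the nearest preceding
    analyzed/empty image's galleries (transitively), and inherit its
    reference point and scale line; analyzed/empty images missing a scale
    line inherit the most recent one (one scale line per sequence is
    enough). The first image of a group may not be skipped. Materializing
    an already-materialized series is the identity (idempotence).
    """
    anns = state.group_annotations(group_id)
    if not anns:
        raise KeyError(f"no annotations for group {group_id!r}")
    resolved: list[ImageAnnotation] = []
    last_scale = None
    for i, ann in enumerate(anns):
        cur = ann.copy()
        if cur.status is Status.SKIPPED:
            if not resolved:
                raise UnresolvableSkipError(
                    f"{group_id}_{cur.serial}: first image of a group cannot be skipped")
            prev = resolved[-1]
            cur.galleries = [g.copy() for g in prev.galleries]
            cur.ref_point = prev.ref_point
            cur.scale_line = prev.scale_line
        if cur.scale_line is None:
            cur.scale_line = last_scale
        else:
            last_scale = cur.scale_line
        resolved.append(cur)
    return resolved


def check_append_consistency(prev: ImageAnnotation,
                             curr: ImageAnnotation,
                             tol_px: float) -> list[AppendViolation]:
    """Violations of the galleries-only-grow assumption between two images.

    With ``curr.append_mode`` true, every gallery of ``prev`` must exist in
    ``curr`` and its reference-corrected points must be a prefix of
    ``curr``'s (each within ``tol_px`` — re-clicked inherited points may
    jitter). With ``append_mode`` false (the user declared backfilling /
    "not appending"), free replacement is permitted and no violations are
    reported.
    """
    if not curr.append_mode:
        return []
    out: list[AppendViolation] = []
    curr_by_id = {g.gallery_id: g for g in curr.galleries}
    for g_prev in prev.galleries:
        g_curr = curr_by_id.get(g_prev.gallery_id)
        if g_curr is None:
            out.append(AppendViolation(
                curr.group_id, curr.serial, g_prev.gallery_id, "missing",
                "gallery present in previous image has disappeared"))
            continue
        p_pts = translate_to_ref(g_prev.points, prev.ref_point)
        c_pts = translate_to_ref(g_curr.points, curr.ref_point)
        if len(c_pts) < len(p_pts):
            out.append(AppendViolation(
                curr.group_id, curr.serial, g_prev.gallery_id, "shortened",
                f"{len(p_pts)} points shrank to {len(c_pts)}"))
            continue
        for k, (a, b) in enumerate(zip(p_pts, c_pts)):
            if a.distance_to(b) > tol_px:
                out.append(AppendViolation(
                    curr.group_id, curr.serial, g_prev.gallery_id, "moved",
                    f"point {k} moved {a.distance_to(b):.2f} px (> {tol_px} px)"))
                break
    return out


def _mm_per_px(ann: ImageAnnotation, scale_mm: float | None) -> float:
    """Calibration for one image; 1.0 (mm == px) without a scale line or length."""
    if ann.scale_line is None or scale_mm is None:
        return 1.0
    return scale_factor(ann.scale_line, scale_mm)


def analyze_group(state: ProjectState,
                  group_id: str,
                  tol_px: float | None = None) -> GroupResult:
    """Materialize, align, classify and reduce one group's full series.

    ``tol_px`` is the append-consistency prefix tolerance and defaults to
    the project's snapping threshold. Raises :class:`ClassificationError`
    (carrying the image identity) when galleries remain unclassified.
    """
    tol = state.threshold_px if tol_px is None else tol_px
    resolved = materialize_series(state, group_id)
    entrances = state.entrance_points.get(group_id)
    scale_mm = state.group_scale_mm(group_id)

    records: list[TimeSeriesRecord] = []
    classified_by_serial: dict[int, list[ClassifiedGallery]] = {}
    networks: dict[int, GalleryNetwork] = {}
    violations: list[AppendViolation] = []
    prev_total = 0.0

    for i, ann in enumerate(resolved):
        if i > 0:
            violations.extend(check_append_consistency(resolved[i - 1], ann, tol))
        corrected = [translate_gallery(g, ann.ref_point) for g in ann.galleries]
        classified = assign_identities(corrected, entrances, state.threshold_px)
        bad = [c.gallery_id for c in classified if c.unclassified]
        if bad:
            raise ClassificationError(
                f"{group_id}_{ann.serial}: unclassified galleries {bad}",
                group_id=group_id, serial=ann.serial, gallery_ids=tuple(bad))
        mmpx = _mm_per_px(ann, scale_mm)
        net = build_network(classified, entrances, state.threshold_px, mmpx)
        summary = network_summary(net)

        per_bin = {"1": 0.0, "2": 0.0, "3": 0.0, "4+": 0.0}
        total = 0.0
        for c in classified:
            length_mm = polyline_length(c.gallery.points) * mmpx
            per_bin[rank_bin(c.rank)] += length_mm
            total += length_mm
        records.append(TimeSeriesRecord(
            group_id=group_id,
            serial=ann.serial,
            total_mm=total,
            len1_mm=per_bin["1"],
            len2_mm=per_bin["2"],
            len3_mm=per_bin["3"],
            len4plus_mm=per_bin["4+"],
            n_galleries=len(classified),
            n_nodes=int(summary["n_nodes"]),
            n_edges=int(summary["n_edges"]),
            growth_mm=total - prev_total if i > 0 else total,
        ))
        prev_total = total
        classified_by_serial[ann.serial] = classified
        networks[ann.serial] = net

    return GroupResult(group_id=group_id, records=records,
                       classified=classified_by_serial, networks=networks,
                       violations=violations)


def compute_series(state: ProjectState,
                   group_id: str,
                   tol_px: float | None = None) -> list[TimeSeriesRecord]:
    """Per-image time-series records for one group (see :func:`analyze_group`)."""
    return analyze_group(state, group_id, tol_px=tol_px).records
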