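"""Metric computation: polyline length, alignment, calibration, snapping.

Everything downstream (identity classification, network extraction, the
exported tables) is built on the five primitives here:

* :func:`polyline_length` — Euclidean length of a traced polyline, px.
* :func:`scale_factor` — mm per pixel from the user's scale line and the
  known real-world length of the scale object.
* :func:`translate_to_ref` — align coordinates to the clicked reference
  landmark; with no reference the top-left image corner (0, 0) is used,
  which makes the operation the identity.
* :func:`point_to_polyline_distance` — minimum distance from a point to a
  polyline with projection onto segments (not just vertices), plus the
  arc-length position of the nearest point.
* :func:`snap_endpoints` — single-linkage clustering of candidate node
  points under a strict ``< threshold_px`` contact relation; clusters of
  clicked endpoints become the nodes of the gallery network.

Threshold semantics are strict ``<``: two points exactly at the threshold
distance do NOT merge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import LineString
from shapely.geometry import Point as _ShapelyPoint

from .datamodel import Gallery, Point
from .errors import CalibrationError, DegeneratePolylineError

__all__ = [
    "NodeCluster",
    "polyline_length",
    "scale_factor",
    "translate_to_ref",
    "point_to_polyline_distance",
    "snap_endpoints",
    "as_array",
]


def as_array(points: Sequence[Point] | np.ndarray) -> np.ndarray:
    """(n, 2) float array view of a point sequence."""
    if isinstance(points, np.ndarray):
        return np.asarray(points, dtype=float)
    return np.array([(p.x, p.y) for p in points], dtype=float)


def polyline_length(points: Sequence[Point] | np.ndarray) -> float:
    """Total Euclidean length in pixels of an ordered polyline.

    Additive under concatenation at a shared point; >= 0.
    """
    arr = as_array(points)
    if arr.shape[0] < 2:
        raise DegeneratePolylineError(
            f"polyline needs >= 2 points, got {arr.shape[0]}")
    return float(np.hypot(*np.diff(arr, axis=0).T).sum())


def scale_factor(scale_line: tuple[Point, Point], scale_mm: float) -> float:
    """mm per pixel implied by a drawn scale line of known real length."""
    a, b = scale_line
    px = a.distance_to(b)
    if px <= 0.0:
        raise CalibrationError("scale line has zero pixel length")
    if scale_mm <= 0.0:
        raise CalibrationError(f"scale_mm must be > 0, got {scale_mm}")
    return scale_mm / px


def translate_to_ref(points: Iterable[Point], ref_point: Point | None) -> list[Point]:
    """Shift coordinates so the reference landmark becomes the origin.

    With ``ref_point`` absent the reference is the top-left image corner
    (0, 0) and the points are returned unchanged.
    """
    pts = list(points)
    if ref_point is None:
        return pts
    return [p - ref_point for p in pts]


def translate_gallery(g: Gallery, ref_point: Point | None) -> Gallery:
    """Reference-corrected copy of a gallery (identity when ref is absent)."""
    if ref_point is None:
        return g.copy()
    return Gallery(g.gallery_id, translate_to_ref(g.points, ref_point))


def point_to_polyline_distance(p: Point,
                               polyline: Gallery | Sequence[Point],
                               ) -> tuple[float, float]:
    """Minimum distance from ``p`` to a polyline, with the foot's arc-length.

    The candidate nearest point is the orthogonal projection onto each
    segment (clamped to the segment), not merely the clicked vertices.
    Returns ``(distance_px, arclength_px)`` where ``arclength_px`` is the
    position along the polyline, from its start, of the nearest point.
    """
    pts = polyline.points if isinstance(polyline, Gallery) else polyline
    line = LineString(as_array(pts))
    sp = _ShapelyPoint(p.x, p.y)
    return float(line.distance(sp)), float(line.project(sp))


@dataclass
class NodeCluster:
    """A group of candidate node points merged by the snapping threshold."""

    member_indices: list[int]
    member_points: list[Point]

    @property
    def representative(self) -> Point:
        """Centroid of the member points; used as the node coordinate."""
        arr = as_array(self.member_points)
        cx, cy = arr.mean(axis=0)
        return Point(float(cx), float(cy))


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # anchor to the smaller root for deterministic output
            if ra < rb:
                self.parent[rb] = ra
            else:
                self.parent[ra] = rb


def snap_endpoints(points: Sequence[Point],
                   threshold_px: float) -> list[NodeCluster]:
    """Partition points into single-linkage clusters under ``dist < threshold``.

    Points connected by a chain of pairwise distances strictly below the
    threshold are regarded as the same node (chaining can merge points more
    than a threshold apart — deliberate single-linkage semantics). The
    result is a partition: disjoint clusters covering every input point,
    ordered by each cluster's smallest input index, and independent of the
    input order at set level.
    """
    if threshold_px <= 0:
        raise ValueError(f"threshold_px must be > 0, got {threshold_px}")
    pts = list(points)
    n = len(pts)
    if n == 0:
        return []
    arr = as_array(pts)
    uf = _UnionFind(n)
    tree = cKDTree(arr)
    for i, j in tree.query_pairs(threshold_px):
        # query_pairs uses <=; contact requires strictly < threshold
        if np.hypot(*(arr[i] - arr[j])) < threshold_px:
            uf.union(i, j)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(uf.find(i), []).append(i)
    ordered = sorted(clusters.values(), key=lambda idx: min(idx))
    return [NodeCluster(member_indices=idx,
                        member_points=[pts[i] for i in idx])
            for idx in ordered]
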