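"""Gallery identity assignment: primary, secondary, tertiary, ...

A gallery system is a branching hierarchy. The identity (rank) of each
traced gallery follows four rules used widely in the tunneling literature:

i.   galleries originating from the start point (entrance) are primary;
ii.  galleries emerging from the side of a pre-existing gallery are
     descendants: their rank is the parent's rank + 1;
iii. when one tunnel splits in two, the branch deviating least from the
     incoming direction keeps the parent's identity (a drawing convention
     the user follows while tracing — validated here, never re-segmented);
iv.  where a gallery merges into a pre-existing gallery, its polyline ends
     (reported as ``merged_end``).

Attachment is tested from the child's START point only: the direction of
drawing is semantic. A gallery drawn "backwards" (start in open space, end
on a parent) is reported as merged_end, not re-parented.

Ranks are resolved by iterating parent links to a fixed point; circular
parentage (possible when two galleries each start on the other) is flagged
``unclassified`` rather than silently ranked.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

from .datamodel import Gallery, Point
from .geometry import point_to_polyline_distance

log = logging.getLogger(__name__)

__all__ = ["ClassifiedGallery", "find_parent", "assign_identities",
           "split_inheritance_check", "rank_bin"]


@dataclass
class ClassifiedGallery:
    """A gallery plus its position in the branching hierarchy.

    ``rank`` is 1 for primary galleries, parent rank + 1 otherwise, and
    ``None`` while unclassified. ``attach_arclength_px`` locates the
    attachment along the parent polyline (from the parent's start).
    """

    gallery: Gallery
    rank: int | None
    parent_id: str | None
    attach_arclength_px: float | None
    merged_end: bool
    unclassified: bool = False

    @property
    def gallery_id(self) -> str:
        return self.gallery.gallery_id


def find_parent(g: Gallery,
                others: Sequence[Gallery],
                threshold_px: float) -> tuple[str, float] | None:
    """Nearest pre-existing gallery that ``g``'s start point contacts.

    Returns ``(parent_id, attach_arclength_px)`` for the gallery whose
    polyline is nearest to ``g``'s start, if that distance is strictly
    below the threshold; otherwise ``None``. Ties are broken by smallest
    distance, then lexicographically earliest gallery id.
    """
    best: tuple[float, str, float] | None = None
    for other in others:
        if other.gallery_id == g.gallery_id:
            continue
        dist, arc = point_to_polyline_distance(g.start, other)
        if dist < threshold_px:
            key = (dist, other.gallery_id)
            if best is None or key < (best[0], best[1]):
                best = (dist, other.gallery_id, arc)
    if best is None:
        return None
    return best[1], best[2]


def _near_entrance(p: Point, entrances: Sequence[Point], threshold_px: float) -> bool:
    return any(p.distance_to(e) < threshold_px for e in entrances)


def assign_identities(galleries: Sequence[Gallery],
                      entrance_points: Sequence[Point] | None,
                      threshold_px: float) -> list[ClassifiedGallery]:
    """Assign a rank to every gallery from the four identity rules.

    With ``entrance_points`` given, galleries starting within the threshold
    of an entrance are primary; without them, galleries with no parent
    found are primary. Every other gallery receives parent rank + 1,
    resolved by iteration to a fixed point. Galleries left unresolved
    (circular parentage, or orphans when entrances are declared) keep
    ``rank=None`` with ``unclassified=True`` and a logged warning naming
    the offending ids. The result order matches the input order; the
    assignment itself is independent of it.
    """
    ids = [g.gallery_id for g in galleries]
    if len(ids) != len(set(ids)):
        raise ValueError(f"gallery ids must be unique, got {sorted(ids)}")

    out: list[ClassifiedGallery] = []
    for g in galleries:
        parent = None
        if entrance_points is not None and _near_entrance(g.start, entrance_points, threshold_px):
            pass  # primary regardless of nearby galleries
        else:
            parent = find_parent(g, galleries, threshold_px)
        merged = False
        for other in galleries:
            if other.gallery_id == g.gallery_id:
                continue
            dist, _ = point_to_polyline_distance(g.end, other)
            if dist < threshold_px:
                merged = True
                break
        out.append(ClassifiedGallery(
            gallery=g,
            rank=None,
            parent_id=parent[0] if parent else None,
            attach_arclength_px=parent[1] if parent else None,
            merged_end=merged,
        ))

    # roots: primaries per rule i
    by_id = {c.gallery_id: c for c in out}
    for c in out:
        if c.parent_id is None:
            if entrance_points is None or _near_entrance(
                    c.gallery.start, entrance_points, threshold_px):
                c.rank = 1
            # else: orphan while entrances are declared -> stays unresolved

    # propagate rank = parent rank + 1 to a fixed point
    changed = True
    while changed:
        changed = False
        for c in out:
            if c.rank is None and c.parent_id is not None:
                parent = by_id[c.parent_id]
                if parent.rank is not None:
                    c.rank = parent.rank + 1
                    changed = True

    unresolved = [c for c in out if c.rank is None]
    for c in unresolved:
        c.unclassified = True
    if unresolved:
        log.warning(
            "unclassified galleries (circular or orphaned parentage): %s",
            ", ".join(f"{c.gallery_id}->{c.parent_id}" for c in unresolved))
    return out


def rank_bin(rank: int) -> str:
    """Reporting bin for a rank: '1', '2', '3' or '4+' (quaternary+ pooled)."""
    return str(rank) if rank < 4 else "4+"


def split_inheritance_check(parent_dir_in: tuple[float, float],
                            child_dirs: Sequence[tuple[float, float]],
                            ) -> int:
    """Index of the branch that keeps the parent's identity at a split.

    At a split, the branch with the shallower angle — smaller absolute
    angular deviation from the incoming direction — retains the identity
    (rule iii). This is an advisory validator for the drawing convention
    (and the ground truth of the synthetic generator); it never re-segments
    a user's polylines. Ties return the first index with a warning.
    """
    ux, uy = parent_dir_in
    nu = math.hypot(ux, uy)
    if nu == 0:
        raise ValueError("parent direction must be nonzero")

    def deviation(v: tuple[float, float]) -> float:
        vx, vy = v
        nv = math.hypot(vx, vy)
        if nv == 0:
            raise ValueError("child direction must be nonzero")
        c = (ux * vx + uy * vy) / (nu * nv)
        return math.acos(max(-1.0, min(1.0, c)))

    devs = [deviation(v) for v in child_dirs]
    best = min(range(len(devs)), key=lambda i: devs[i])
    ties = [i for i, d in enumerate(devs) if math.isclose(d, devs[best], abs_tol=1e-12)]
    if len(ties) > 1:
        warnings.warn(
            f"split-angle tie between branches {ties}; first retains identity",
            stacklevel=2)
        return ties[0]
    return best
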