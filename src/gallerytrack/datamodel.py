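"""Core annotation types, the image-naming convention, and project persistence.

The objects here mirror what a user produces while tracing gallery systems
(tunnels, burrows, shelter tubes) on sequential photographs:

* :class:`Point` — one clicked pixel coordinate (image convention: origin at
  the top-left corner, y increasing downward).
* :class:`Gallery` — one traced tunnel as an ordered polyline; the first
  point is where the gallery originates, the last is its current tip.
* :class:`ImageAnnotation` — everything recorded for one image: a reference
  landmark, a scale line, the traced galleries, and flags for skipped/empty
  images and for the append assumption (galleries only grow over time).
* :class:`ProjectState` — an ordered collection of annotations for one or
  more experiment groups, plus the global parameters (snapping threshold in
  pixels, real-world scale length in mm, optional entrance points).

Coordinates are stored RAW, exactly as clicked. Reference-point alignment is
applied at analysis time (see :mod:`gallerytrack.geometry`), never
destructively, so a project file always reflects the user's clicks.

Persistence is a versioned JSON file, one per project, with round-trip
identity on every field (floats serialize via Python's shortest round-trip
repr, so coordinates survive bit-exactly).
"""

from __future__ import annotations

import json
import math
import os
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator

from .errors import MalformedNameError, ProjectFormatError, ProjectVersionError

FORMAT_VERSION = 1

#: Default endpoint-snapping threshold in pixels ("users can decide"; a
#: default is needed for batch runs).
DEFAULT_THRESHOLD_PX = 10.0


@dataclass(frozen=True)
class Point:
    """A pixel coordinate. Origin top-left, y increases downward."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"Point coordinates must be finite, got ({self.x}, {self.y})")

    def __sub__(self, other: "Point") -> "Point":
        return Point(self.x - other.x, self.y - other.y)

    def __add__(self, other: "Point") -> "Point":
        return Point(self.x + other.x, self.y + other.y)

    def as_tuple(self) -> tuple[float, float]:
        return (self.x, self.y)

    def distance_to(self, other: "Point") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


class Status(str, Enum):
    """What the user decided for an image during measurement."""

    ANALYZED = "analyzed"   #: galleries were (re)drawn on this image
    SKIPPED = "skipped"     #: no development seen; inherit the previous image
    EMPTY = "empty"         #: no gallery present; all metrics are zero


@dataclass
class Gallery:
    """One traced tunnel: an ordered polyline of >= 2 clicked points.

    The FIRST point is the gallery's start (where it originates, on its
    parent or at an entrance), the LAST its end (the excavation tip, or the
    point where it merged into a pre-existing gallery).
    """

    gallery_id: str
    points: list[Point]

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError(
                f"Gallery {self.gallery_id!r} needs >= 2 points, got {len(self.points)}")
        for a, b in zip(self.points, self.points[1:]):
            if a == b:
                raise ValueError(
                    f"Gallery {self.gallery_id!r} has consecutive duplicate point {a.as_tuple()}")

    @property
    def start(self) -> Point:
        return self.points[0]

    @property
    def end(self) -> Point:
        return self.points[-1]

    def copy(self) -> "Gallery":
        return Gallery(self.gallery_id, list(self.points))


@dataclass
class ImageAnnotation:
    """Full annotation state for one image of a sequence."""

    group_id: str
    serial: int
    status: Status = Status.ANALYZED
    ref_point: Point | None = None
    scale_line: tuple[Point, Point] | None = None
    append_mode: bool = True
    galleries: list[Gallery] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.serial < 0:
            raise ValueError(f"serial must be >= 0, got {self.serial}")
        if self.status is Status.EMPTY and self.galleries:
            raise ValueError(
                f"{self.group_id}_{self.serial}: empty image cannot carry galleries")
        ids = [g.gallery_id for g in self.galleries]
        if len(ids) != len(set(ids)):
            raise ValueError(
                f"{self.group_id}_{self.serial}: duplicate gallery ids {sorted(ids)}")

    def copy(self) -> "ImageAnnotation":
        return ImageAnnotation(
            group_id=self.group_id,
            serial=self.serial,
            status=self.status,
            ref_point=self.ref_point,
            scale_line=self.scale_line,
            append_mode=self.append_mode,
            galleries=[g.copy() for g in self.galleries],
        )


@dataclass
class ProjectState:
    """Ordered collection of annotations plus global analysis parameters.

    ``entrance_points`` are expressed in the reference-corrected (aligned)
    frame so they stay comparable across repositioned photographs.
    ``scale_mm`` is the real-world length of the scale object; a per-group
    override may be given in ``scale_mm_overrides``.
    """

    threshold_px: float = DEFAULT_THRESHOLD_PX
    scale_mm: float | None = None
    annotations: dict[tuple[str, int], ImageAnnotation] = field(default_factory=dict)
    entrance_points: dict[str, list[Point]] = field(default_factory=dict)
    scale_mm_overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.threshold_px <= 0:
            raise ValueError(f"threshold_px must be > 0, got {self.threshold_px}")
        if self.scale_mm is not None and self.scale_mm <= 0:
            raise ValueError(f"scale_mm must be > 0, got {self.scale_mm}")

    # -- collection helpers -------------------------------------------------

    def add(self, ann: ImageAnnotation) -> None:
        key = (ann.group_id, ann.serial)
        if key in self.annotations:
            raise ValueError(f"duplicate annotation for {ann.group_id}_{ann.serial}")
        self.annotations[key] = ann

    def groups(self) -> list[str]:
        return sorted({g for g, _ in self.annotations})

    def group_annotations(self, group_id: str) -> list[ImageAnnotation]:
        """Annotations of one group in strictly increasing serial order."""
        anns = sorted(
            (a for (g, _), a in self.annotations.items() if g == group_id),
            key=lambda a: a.serial)
        return anns

    def group_scale_mm(self, group_id: str) -> float | None:
        return self.scale_mm_overrides.get(group_id, self.scale_mm)

    def sorted_annotations(self) -> Iterator[ImageAnnotation]:
        for key in sorted(self.annotations):
            yield self.annotations[key]


# ---------------------------------------------------------------------------
# Filename convention
# ---------------------------------------------------------------------------

_NAME_RE = re.compile(r"^(?P<group>.+)_(?P<serial>\d+)$")


def parse_image_name(filename: str) -> tuple[str, int]:
    """Parse ``<groupid>_<serial>.<ext>`` into ``(group_id, serial)``.

    The group id is everything before the LAST underscore (so ids may
    themselves contain underscores, e.g. ``colony_1_12.jpg`` ->
    ``("colony_1", 12)``); the serial is the trailing all-digit token,
    leading zeros allowed.
    """
    base = os.path.basename(filename)
    stem, dot, _ext = base.rpartition(".")
    if not dot:
        stem = base
    m = _NAME_RE.match(stem)
    if m is None:
        raise MalformedNameError(
            f"image name {filename!r} does not match '<groupid>_<serial>.<ext>' "
            "(need an underscore followed by a numeric serial)")
    return m.group("group"), int(m.group("serial"))


# ---------------------------------------------------------------------------
# Serialization (versioned JSON; replaces an undocumented binary dialect)
# ---------------------------------------------------------------------------


def _point_to_json(p: Point) -> list[float]:
    return [p.x, p.y]


def _point_from_json(v: object, where: str) -> Point:
    if not (isinstance(v, list) and len(v) == 2):
        raise ProjectFormatError(f"{where}: expected [x, y], got {v!r}")
    return Point(float(v[0]), float(v[1]))


def project_to_dict(state: ProjectState) -> dict:
    """Plain-dict form of a project, ready for ``json.dump``."""
    groups: dict[str, dict] = {}
    for ann in state.sorted_annotations():
        grec = groups.setdefault(ann.group_id, {"images": []})
        rec = {
            "serial": ann.serial,
            "status": ann.status.value,
            "ref_point": _point_to_json(ann.ref_point) if ann.ref_point else None,
            "scale_line": ([_point_to_json(ann.scale_line[0]),
                            _point_to_json(ann.scale_line[1])]
                           if ann.scale_line else None),
            "append_mode": ann.append_mode,
            # skipped images store no gallery copy; copy-forward is
            # materialized at analysis time, keeping the file minimal
            "galleries": ([] if ann.status is Status.SKIPPED else
                          [{"id": g.gallery_id,
                            "points": [_point_to_json(p) for p in g.points]}
                           for g in ann.galleries]),
        }
        grec["images"].append(rec)
    for gid, pts in state.entrance_points.items():
        groups.setdefault(gid, {"images": []})["entrance_points"] = [
            _point_to_json(p) for p in pts]
    for gid, mm in state.scale_mm_overrides.items():
        groups.setdefault(gid, {"images": []})["scale_mm"] = mm
    return {
        "format_version": FORMAT_VERSION,
        "threshold_px": state.threshold_px,
        "scale_mm": state.scale_mm,
        "groups": groups,
    }


def save_project(state: ProjectState, path: str | os.PathLike) -> None:
    """Write ``state`` to ``path`` as versioned JSON (atomic rename)."""
    data = project_to_dict(state)
    tmp = f"{path}.tmp"
    with open(tmp, "w", encoding="utf-8") as fh:
        json.dump(data, fh, indent=1)
        fh.write("\n")
    os.replace(tmp, path)


def project_from_dict(data: dict) -> ProjectState:
    if not isinstance(data, dict) or "format_version" not in data:
        raise ProjectFormatError("not a gallerytrack project file (no format_version)")
    version = data["format_version"]
    if version != FORMAT_VERSION:
        raise ProjectVersionError(
            f"project format_version {version!r} is not supported (expected {FORMAT_VERSION})")
    try:
        state = ProjectState(
            threshold_px=float(data["threshold_px"]),
            scale_mm=(None if data.get("scale_mm") is None else float(data["scale_mm"])),
        )
        for gid, grec in data.get("groups", {}).items():
            if "entrance_points" in grec:
                state.entrance_points[gid] = [
                    _point_from_json(v, f"group {gid} entrance") for v in grec["entrance_points"]]
            if "scale_mm" in grec:
                state.scale_mm_overrides[gid] = float(grec["scale_mm"])
            for rec in grec.get("images", []):
                where = f"{gid}_{rec.get('serial')}"
                scale_line = None
                if rec.get("scale_line") is not None:
                    a, b = rec["scale_line"]
                    scale_line = (_point_from_json(a, where), _point_from_json(b, where))
                ann = ImageAnnotation(
                    group_id=gid,
                    serial=int(rec["serial"]),
                    status=Status(rec["status"]),
                    ref_point=(None if rec.get("ref_point") is None
                               else _point_from_json(rec["ref_point"], where)),
                    scale_line=scale_line,
                    append_mode=bool(rec.get("append_mode", True)),
                    galleries=[Gallery(g["id"],
                                       [_point_from_json(p, where) for p in g["points"]])
                               for g in rec.get("galleries", [])],
                )
                state.add(ann)
    except ProjectFormatError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise ProjectFormatError(f"corrupt project file: {exc}") from exc
    return state


def load_project(path: str | os.PathLike) -> ProjectState:
    """Read a project file written by :func:`save_project`."""
    try:
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise ProjectFormatError(f"cannot read project file {path}: {exc}") from exc
    return project_from_dict(data)


def inventory_images(directory: str | os.PathLike,
                     extensions: Iterable[str] | None = None,
                     ) -> tuple[dict[str, list[tuple[int, str]]], list[str]]:
    """Scan a directory for images named per the ``id_serial`` convention.

    Returns ``(groups, unparseable)`` where ``groups`` maps group_id to a
    serial-sorted list of ``(serial, filename)`` and ``unparseable`` lists
    files whose names do not follow the convention. Images themselves are
    never opened here — they are only a canvas for the annotations.
    """
    exts = {e.lower().lstrip(".") for e in extensions} if extensions else None
    groups: dict[str, list[tuple[int, str]]] = {}
    bad: list[str] = []
    for name in sorted(os.listdir(directory)):
        stem, dot, ext = name.rpartition(".")
        if not dot or (exts is not None and ext.lower() not in exts):
            continue
        try:
            gid, serial = parse_image_name(name)
        except MalformedNameError:
            bad.append(name)
            continue
        groups.setdefault(gid, []).append((serial, name))
    for entries in groups.values():
        entries.sort()
    return groups, bad
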