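"""Seeded generator of branching gallery growth sequences with ground truth.

This is the package's test fixture standing in for real annotated
photographs: it emulates a gallery system growing from an entrance in a
two-dimensional arena — primaries radiating from the start point,
descendants branching from their sides, optional merges closing loops —
and emits both a :class:`~gallerytrack.datamodel.ProjectState` (what a user
would have traced) and a :class:`GroundTruth` carrying every gallery's true
rank, parent and attachment, per-step cumulative lengths in mm, and true
node/edge counts per step.

The generator deliberately keeps the geometry unambiguous for recovery
tests (a design choice, documented in the methods note):

* branch attachment points are placed at least ``separation_factor`` (2.5 by
  default) snapping thresholds away from every existing node and from every
  unrelated gallery, so endpoint snapping cannot confuse clusters;
* growth segments are capped at two thresholds, so a segment whose
  endpoints respect the clearance cannot pass within one threshold of an
  unrelated gallery;
* headings drift within a bounded cone, so galleries grow outward and never
  curl back onto themselves;
* a child leaves its parent at 50–70 degrees with a first segment of about
  two thresholds, placing its tip clear of the parent immediately — and
  keeping the continuation/branch angle convention satisfied (the parent's
  continuation always deviates less than the branch).

``hard_mode`` relaxes the separation factor to probe tie-breaking.

Same seed, same parameters -> byte-identical output.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from PIL import Image, ImageDraw

from .datamodel import (Gallery, ImageAnnotation, Point, ProjectState, Status)

__all__ = ["GrowthParams", "StepTruth", "GroundTruth", "generate",
           "generate_project", "render_synthetic_images"]


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of the synthetic growth model (pixel units, degrees)."""

    seed: int = 0
    n_steps: int = 20                    #: number of images in the series
    n_primaries: int = 2                 #: galleries radiating from the entrance
    elongation_px_per_step: tuple[float, float] = (15.0, 4.0)  #: (mean, sd)
    branch_prob_per_step: float = 0.12   #: per gallery per step
    max_rank: int = 5
    max_galleries: int = 40
    arena_px: tuple[float, float] = (1000.0, 1000.0)
    threshold_px: float = 10.0           #: snapping threshold the project will use
    ref_jitter_px: float = 3.0           #: camera-repositioning jitter, sd
    ref_base_px: tuple[float, float] = (20.0, 15.0)
    scale_len_px: float = 100.0          #: drawn scale-line length
    scale_mm: float = 20.0               #: real-world length of the scale object
    branch_angle_deg: tuple[float, float] = (58.0, 6.0)  #: branch deviation (mean, sd)
    heading_wobble_deg: float = 4.0      #: per-step continuation deviation, sd
    max_drift_deg: float = 35.0          #: cone around a gallery's initial heading
    skip_prob: float = 0.0               #: chance a step is "skipped" (no development)
    start_empty: bool = True             #: serial 0 is an empty arena
    n_merges: int = 0                    #: loops closed at the final step
    hard_mode: bool = False              #: shrink separations to probe tie-breaking

    @property
    def separation_factor(self) -> float:
        return 1.3 if self.hard_mode else 2.5

    @property
    def mm_per_px(self) -> float:
        return self.scale_mm / self.scale_len_px


@dataclass(frozen=True)
class StepTruth:
    """Ground truth after one step (one image) of the series."""

    serial: int
    status: str
    total_mm: float
    per_bin_mm: dict[str, float]     # keys "1", "2", "3", "4+"
    n_galleries: int
    n_nodes: int
    n_edges: int
    n_cycles: int


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    group_id: str
    mm_per_px: float
    entrance: Point
    ranks: dict[str, int] = field(default_factory=dict)
    parents: dict[str, str | None] = field(default_factory=dict)
    attach_arclength_px: dict[str, float | None] = field(default_factory=dict)
    merged: dict[str, bool] = field(default_factory=dict)
    steps: list[StepTruth] = field(default_factory=list)


class _SimGallery:
    __slots__ = ("gid", "pts", "rank", "parent", "attach_arc", "heading",
                 "init_heading", "active", "merged", "length_px", "birth_step")

    def __init__(self, gid: str, start: np.ndarray, heading: float, rank: int,
                 parent: str | None, attach_arc: float | None, birth_step: int):
        self.gid = gid
        self.pts: list[np.ndarray] = [start]
        self.rank = rank
        self.parent = parent
        self.attach_arc = attach_arc
        self.heading = heading
        self.init_heading = heading
        self.active = True
        self.merged = False
        self.length_px = 0.0
        self.birth_step = birth_step

    def append(self, p: np.ndarray) -> None:
        self.length_px += float(math.hypot(*(p - self.pts[-1])))
        self.pts.append(p)

    def array(self) -> np.ndarray:
        return np.asarray(self.pts, dtype=float)


def _point_polyline_dist(p: np.ndarray, pts: np.ndarray) -> float:
    """Min distance from p to a polyline given as an (n, 2) array."""
    if pts.shape[0] == 1:
        return float(math.hypot(*(p - pts[0])))
    a, b = pts[:-1], pts[1:]
    ab = b - a
    denom = (ab * ab).sum(axis=1)
    denom[denom == 0] = 1.0
    t = np.clip(((p - a) * ab).sum(axis=1) / denom, 0.0, 1.0)
    foot = a + t[:, None] * ab
    return float(np.sqrt(((p - foot) ** 2).sum(axis=1).min()))


class _Simulator:
    def __init__(self, params: GrowthParams, group_id: str):
        self.p = params
        self.group_id = group_id
        self.rng = np.random.default_rng(params.seed)
        w, h = params.arena_px
        self.entrance = np.array([w / 2.0, h / 2.0])
        self.galleries: list[_SimGallery] = []
        self.node_points: list[np.ndarray] = [self.entrance]
        self.n_interior = 0
        self.n_merged = 0
        self.sep = params.separation_factor * params.threshold_px
        self.margin = 3.0 * params.threshold_px

    # -- geometric guards ---------------------------------------------------

    def _in_arena(self, p: np.ndarray) -> bool:
        w, h = self.p.arena_px
        m = self.margin
        return m <= p[0] <= w - m and m <= p[1] <= h - m

    def _clear_of_others(self, p: np.ndarray, g: _SimGallery) -> bool:
        """Clearance of a proposed tip from every unrelated polyline."""
        thr = self.p.threshold_px
        near_origin = math.hypot(*(p - g.pts[0])) <= 3.5 * thr
        for h in self.galleries:
            if h.gid == g.gid:
                continue
            d = _point_polyline_dist(p, h.array())
            exempt = near_origin and (
                h.gid == g.parent or
                (g.rank == 1 and math.hypot(*(p - self.entrance)) <= 3.5 * thr))
            if exempt:
                if d <= 1.35 * thr:
                    return False
            elif d < self.sep:
                return False
        return True

    def _clear_of_nodes(self, p: np.ndarray) -> bool:
        return all(math.hypot(*(p - q)) >= self.sep for q in self.node_points)

    # -- growth -------------------------------------------------------------

    def _spawn_primaries(self, step: int) -> None:
        base = self.rng.uniform(0.0, 2.0 * math.pi)
        for k in range(self.p.n_primaries):
            heading = base + 2.0 * math.pi * k / self.p.n_primaries
            gid = f"g{len(self.galleries):02d}"
            g = _SimGallery(gid, self.entrance.copy(), heading, 1, None, None, step)
            self.galleries.append(g)
            self._elongate(g, first=True)
            if len(g.pts) < 2:  # could not place even the first segment
                self.galleries.pop()

    def _segment_length(self, first: bool = False) -> float:
        mean, sd = self.p.elongation_px_per_step
        thr = self.p.threshold_px
        lo, hi = (1.9 * thr, 2.0 * thr) if first else (0.8 * thr, 2.0 * thr)
        return float(np.clip(self.rng.normal(mean, sd), lo, hi))

    def _elongate(self, g: _SimGallery, first: bool = False) -> None:
        drift = math.radians(self.p.max_drift_deg)
        for _ in range(12):
            wobble = self.rng.normal(0.0, math.radians(self.p.heading_wobble_deg))
            heading = g.heading + wobble
            # continuation stays within a cone of the initial heading
            lo, hi = g.init_heading - drift, g.init_heading + drift
            heading = min(max(heading, lo), hi)
            length = self._segment_length(first=first)
            tip = g.pts[-1] + length * np.array([math.cos(heading), math.sin(heading)])
            if self._in_arena(tip) and self._clear_of_others(tip, g):
                g.heading = heading
                g.append(tip)
                return
        g.active = False

    def _try_branch(self, parent: _SimGallery, step: int) -> None:
        pts = parent.array()
        total = parent.length_px
        if total < 2.0 * self.sep + 2.0:
            return
        thr = self.p.threshold_px
        for _ in range(15):
            s = float(self.rng.uniform(self.sep, total - self.sep))
            seg = np.diff(pts, axis=0)
            lens = np.hypot(seg[:, 0], seg[:, 1])
            cum = np.concatenate([[0.0], np.cumsum(lens)])
            i = int(np.searchsorted(cum[1:], s))
            t = (s - cum[i]) / lens[i]
            q = pts[i] + t * seg[i]
            if not self._clear_of_nodes(q):
                continue
            ok = True
            for h in self.galleries:
                if h.gid == parent.gid:
                    continue
                if _point_polyline_dist(q, h.array()) < self.sep:
                    ok = False
                    break
            if not ok:
                continue
            direction = math.atan2(*seg[i][::-1])
            ang = float(np.clip(self.rng.normal(*self.p.branch_angle_deg), 50.0, 70.0))
            sign = 1.0 if self.rng.random() < 0.5 else -1.0
            heading = direction + sign * math.radians(ang)
            gid = f"g{len(self.galleries):02d}"
            child = _SimGallery(gid, q, heading, parent.rank + 1,
                                parent.gid, s, step)
            # place the first segment; must clear everything except its parent
            first_len = float(np.clip(self.rng.normal(
                self.p.elongation_px_per_step[0], 1.0), 1.9 * thr, 2.0 * thr))
            tip = q + first_len * np.array([math.cos(heading), math.sin(heading)])
            self.galleries.append(child)
            if self._in_arena(tip) and self._clear_of_others(tip, child):
                child.append(tip)
                self.node_points.append(q)
                self.n_interior += 1
                return
            self.galleries.pop()  # placement failed; retry elsewhere
        return

    def _try_merge(self) -> bool:
        """Steer one active gallery's tip onto another gallery (closes a loop)."""
        thr = self.p.threshold_px
        order = [g for g in self.galleries if g.active and not g.merged]
        for g in order:
            tip = g.pts[-1]
            for h in self.galleries:
                if h.gid == g.gid:
                    continue
                pts = h.array()
                seg = np.diff(pts, axis=0)
                lens = np.hypot(seg[:, 0], seg[:, 1])
                cum = np.concatenate([[0.0], np.cumsum(lens)])
                if cum[-1] < 2.0 * self.sep + 2.0:
                    continue
                for _ in range(10):
                    s = float(self.rng.uniform(self.sep, cum[-1] - self.sep))
                    i = int(np.searchsorted(cum[1:], s))
                    t = (s - cum[i]) / lens[i]
                    target = pts[i] + t * seg[i]
                    if not self._clear_of_nodes(target):
                        continue
                    d_jump = math.hypot(*(target - tip))
                    if not (2.0 * thr <= d_jump <= 12.0 * thr):
                        continue
                    # connecting segment and landing point must stay clear of
                    # third galleries so the merge target is unambiguous
                    samples = tip + np.linspace(0.05, 1.0, 20)[:, None] * (target - tip)
                    ok = True
                    for other in self.galleries:
                        if other.gid in (g.gid, h.gid):
                            continue
                        arr = other.array()
                        if any(_point_polyline_dist(p, arr) < 1.5 * thr
                               for p in samples):
                            ok = False
                            break
                    if ok and _point_polyline_dist(
                            np.asarray(h.pts[-1]), np.vstack([tip, target])) < self.sep:
                        ok = False
                    if not ok:
                        continue
                    g.append(target)
                    g.active = False
                    g.merged = True
                    self.n_merged += 1
                    self.n_interior += 1
                    self.node_points.append(target)
                    return True
        return False

    # -- bookkeeping --------------------------------------------------------

    def truth_counts(self) -> tuple[int, int, int]:
        n_gal = len(self.galleries)
        if n_gal == 0:
            return 0, 0, 0
        free_tips = n_gal - self.n_merged
        n_nodes = 1 + self.n_interior + free_tips
        n_edges = n_gal + self.n_interior
        return n_nodes, n_edges, self.n_merged

    def per_bin_mm(self) -> tuple[dict[str, float], float]:
        bins = {"1": 0.0, "2": 0.0, "3": 0.0, "4+": 0.0}
        total = 0.0
        for g in self.galleries:
            mm = g.length_px * self.p.mm_per_px
            key = str(g.rank) if g.rank < 4 else "4+"
            bins[key] += mm
            total += mm
        return bins, total


def generate(params: GrowthParams,
             group_id: str = "synth") -> tuple[ProjectState, GroundTruth]:
    """Grow one gallery system and package it as an annotated image series.

    Returns the project (raw, camera-jittered coordinates, per-image
    reference point and scale line) plus the ground truth in the aligned
    frame. Same parameters -> identical output.
    """
    p = params
    sim = _Simulator(p, group_id)
    truth = GroundTruth(group_id=group_id, mm_per_px=p.mm_per_px,
                        entrance=Point(*sim.entrance))
    state = ProjectState(threshold_px=p.threshold_px, scale_mm=p.scale_mm)
    state.entrance_points[group_id] = [Point(*sim.entrance)]

    scale_line_raw = (Point(10.0, 10.0), Point(10.0 + p.scale_len_px, 10.0))
    rng_cam = np.random.default_rng(p.seed + 7)  # camera jitter stream

    for serial in range(p.n_steps):
        grown_this_step = False
        if serial == 0:
            if not p.start_empty:
                sim._spawn_primaries(serial)
                grown_this_step = True
            status = Status.EMPTY if p.start_empty else Status.ANALYZED
        else:
            if not sim.galleries:
                sim._spawn_primaries(serial)
                status = Status.ANALYZED
                grown_this_step = True
            elif p.skip_prob > 0 and sim.rng.random() < p.skip_prob:
                status = Status.SKIPPED
            else:
                status = Status.ANALYZED
                for g in list(sim.galleries):
                    if g.active:
                        sim._elongate(g)
                for g in list(sim.galleries):
                    if (g.rank < p.max_rank
                            and len(sim.galleries) < p.max_galleries
                            and sim.rng.random() < p.branch_prob_per_step):
                        sim._try_branch(g, serial)
                grown_this_step = True
        if serial == p.n_steps - 1 and status is not Status.SKIPPED:
            for _ in range(p.n_merges):
                sim._try_merge()

        off = np.asarray(p.ref_base_px) + rng_cam.normal(0.0, p.ref_jitter_px, 2)
        ref = Point(float(off[0]), float(off[1]))
        if status is Status.SKIPPED:
            ann = ImageAnnotation(group_id=group_id, serial=serial,
                                  status=Status.SKIPPED, append_mode=True)
        else:
            galleries = [
                Gallery(g.gid, [Point(float(x + off[0]), float(y + off[1]))
                                for x, y in g.pts])
                for g in sim.galleries]
            ann = ImageAnnotation(
                group_id=group_id, serial=serial, status=status,
                ref_point=ref, scale_line=scale_line_raw,
                append_mode=True, galleries=galleries)
        state.add(ann)

        bins, total = sim.per_bin_mm()
        n_nodes, n_edges, n_cycles = sim.truth_counts()
        truth.steps.append(StepTruth(
            serial=serial, status=status.value, total_mm=total,
            per_bin_mm=bins, n_galleries=len(sim.galleries),
            n_nodes=n_nodes, n_edges=n_edges, n_cycles=n_cycles))

    for g in sim.galleries:
        truth.ranks[g.gid] = g.rank
        truth.parents[g.gid] = g.parent
        truth.attach_arclength_px[g.gid] = g.attach_arc
        truth.merged[g.gid] = g.merged
    return state, truth


def generate_project(n_groups: int,
                     params: GrowthParams,
                     seed: int | None = None,
                     group_prefix: str = "colony",
                     ) -> tuple[ProjectState, dict[str, GroundTruth]]:
    """Multi-group project: one independent growth sequence per group."""
    base_seed = params.seed if seed is None else seed
    merged = ProjectState(threshold_px=params.threshold_px,
                          scale_mm=params.scale_mm)
    truths: dict[str, GroundTruth] = {}
    for i in range(n_groups):
        gid = f"{group_prefix}{i:02d}"
        sub_params = replace(params, seed=(base_seed * 1009 + i) % (2 ** 31))
        sub, truth = generate(sub_params, group_id=gid)
        for ann in sub.sorted_annotations():
            merged.add(ann)
        merged.entrance_points[gid] = sub.entrance_points[gid]
        truths[gid] = truth
    return merged, truths


def render_synthetic_images(state: ProjectState,
                            outdir: str | os.PathLike,
                            size: tuple[int, int] = (1060, 1040),
                            line_width: int = 3) -> list[str]:
    """Rasterize each annotation as dark strokes on a light background.

    Files are named per the ``<groupid>_<serial>.png`` convention so they
    round-trip through :func:`gallerytrack.datamodel.parse_image_name`,
    enabling end-to-end smoke tests without real photographs.
    """
    os.makedirs(outdir, exist_ok=True)
    paths: list[str] = []
    for ann in state.sorted_annotations():
        img = Image.new("RGB", size, (245, 242, 235))
        draw = ImageDraw.Draw(img)
        for g in ann.galleries:
            draw.line([p.as_tuple() for p in g.points],
                      fill=(40, 30, 20), width=line_width)
        path = os.path.join(outdir, f"{ann.group_id}_{ann.serial:02d}.png")
        img.save(path)
        paths.append(path)
    return paths
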