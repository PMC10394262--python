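"""Reduce classified galleries to a graph of typed nodes and measured edges.

Candidate nodes are every gallery's start and end point plus every
attachment point (a child's start and any merged end, projected onto the
gallery it touches). Candidates within the snapping threshold collapse into
one node (single-linkage, strict ``<``). Each gallery polyline is then split
at every interior node lying on it, by arc-length position, so the graph is
embedded on the drawn skeleton and edge lengths are measured along the
original polyline. Consequently the sum of edge lengths equals the sum of
gallery lengths exactly (the split positions telescope).

Node types follow the convention used for termite foraging networks:
``entrance`` when the cluster contains a declared entrance point, otherwise
``end`` for degree-1 nodes (blind tips) and ``intersection`` for the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
from shapely.geometry import LineString
from shapely.geometry import Point as _ShapelyPoint

from .classification import ClassifiedGallery
from .datamodel import Point
from .errors import NetworkError
from .geometry import as_array, snap_endpoints

__all__ = ["Node", "Edge", "GalleryNetwork", "build_network", "network_summary"]

#: split positions closer than this along a polyline are treated as one node
_ARC_EPS = 1e-9

NODE_ENTRANCE = "entrance"
NODE_INTERSECTION = "intersection"
NODE_END = "end"


@dataclass(frozen=True)
class Node:
    node_id: int
    coord: Point
    type: str


@dataclass(frozen=True)
class Edge:
    node_a: int
    node_b: int
    length_px: float
    length_mm: float
    gallery_id: str


@dataclass
class GalleryNetwork:
    """Typed nodes and measured edges of one image's gallery system."""

    nodes: list[Node] = field(default_factory=list)
    edges: list[Edge] = field(default_factory=list)

    def graph(self) -> nx.MultiGraph:
        """networkx view (MultiGraph: parallel edges and loops possible)."""
        g = nx.MultiGraph()
        for n in self.nodes:
            g.add_node(n.node_id, coord=n.coord.as_tuple(), type=n.type)
        for e in self.edges:
            g.add_edge(e.node_a, e.node_b, length_px=e.length_px,
                       length_mm=e.length_mm, gallery_id=e.gallery_id)
        return g


def build_network(classified: Sequence[ClassifiedGallery],
                  entrance_points: Sequence[Point] | None,
                  threshold_px: float,
                  mm_per_px: float = 1.0) -> GalleryNetwork:
    """Reconstruct the node/edge network from classified galleries.

    Coordinates are expected reference-corrected. Refuses to run when any
    gallery is still unclassified (see the classification warnings for the
    offending ids).
    """
    bad = [c.gallery_id for c in classified if c.unclassified]
    if bad:
        raise NetworkError(
            f"cannot build network with unclassified galleries {bad}; "
            "see classification warnings")

    lines: dict[str, LineString] = {
        c.gallery_id: LineString(as_array(c.gallery.points)) for c in classified}
    # split positions (arc-lengths) per gallery: its own ends, children
    # attaching on it, merged ends landing on it
    splits: dict[str, set[float]] = {
        gid: {0.0, line.length} for gid, line in lines.items()}

    for c in classified:
        if c.parent_id is not None and c.attach_arclength_px is not None:
            splits[c.parent_id].add(float(c.attach_arclength_px))
        if c.merged_end:
            # find which gallery the end merges into (nearest polyline)
            tip = _ShapelyPoint(c.gallery.end.x, c.gallery.end.y)
            best: tuple[float, str] | None = None
            for other in classified:
                if other.gallery_id == c.gallery_id:
                    continue
                d = lines[other.gallery_id].distance(tip)
                if d < threshold_px and (best is None or (d, other.gallery_id) < best):
                    best = (d, other.gallery_id)
            if best is not None:
                target = best[1]
                splits[target].add(float(lines[target].project(tip)))

    # candidate node points with provenance (gallery id + arc position)
    candidates: list[Point] = []
    owners: list[tuple[str, float] | None] = []  # None marks an entrance point
    for gid in sorted(splits):
        line = lines[gid]
        for s in sorted(_dedupe_arcs(splits[gid], line.length)):
            pt = line.interpolate(s)
            candidates.append(Point(float(pt.x), float(pt.y)))
            owners.append((gid, s))
    n_structural = len(candidates)
    for e in entrance_points or []:
        candidates.append(e)
        owners.append(None)

    clusters = snap_endpoints(candidates, threshold_px) if candidates else []
    cluster_of = {}
    entrance_cluster = set()
    structural_cluster = set()
    for node_id, cl in enumerate(clusters):
        for i in cl.member_indices:
            cluster_of[i] = node_id
            if owners[i] is None:
                entrance_cluster.add(node_id)
            else:
                structural_cluster.add(node_id)

    # edges: consecutive split positions along each gallery
    edges: list[Edge] = []
    idx_by_owner = {owners[i]: i for i in range(n_structural)}
    for gid in sorted(splits):
        arcs = sorted(_dedupe_arcs(splits[gid], lines[gid].length))
        for s0, s1 in zip(arcs, arcs[1:]):
            length = s1 - s0
            if length <= _ARC_EPS:
                continue
            a = cluster_of[idx_by_owner[(gid, s0)]]
            b = cluster_of[idx_by_owner[(gid, s1)]]
            edges.append(Edge(node_a=a, node_b=b, length_px=length,
                              length_mm=length * mm_per_px, gallery_id=gid))

    degree: dict[int, int] = {}
    for e in edges:
        degree[e.node_a] = degree.get(e.node_a, 0) + 1
        degree[e.node_b] = degree.get(e.node_b, 0) + 1

    nodes: list[Node] = []
    for node_id, cl in enumerate(clusters):
        if node_id not in structural_cluster:
            continue  # a declared entrance with no gallery near it: no node
        if node_id in entrance_cluster:
            ntype = NODE_ENTRANCE
        elif degree.get(node_id, 0) == 1:
            ntype = NODE_END
        else:
            ntype = NODE_INTERSECTION
        nodes.append(Node(node_id=node_id, coord=cl.representative, type=ntype))
    return GalleryNetwork(nodes=nodes, edges=edges)


def _dedupe_arcs(arcs: set[float], total: float) -> list[float]:
    """Collapse split positions closer than _ARC_EPS; clamp into [0, total]."""
    out: list[float] = []
    for s in sorted(min(max(a, 0.0), total) for a in arcs):
        if not out or s - out[-1] > _ARC_EPS:
            out.append(s)
        # a position within eps of the previous collapses onto it
    return out


def network_summary(net: GalleryNetwork) -> dict[str, float]:
    """Counts and total length of a network, consistent with its lists."""
    by_type = {NODE_ENTRANCE: 0, NODE_INTERSECTION: 0, NODE_END: 0}
    for n in net.nodes:
        by_type[n.type] += 1
    return {
        "n_nodes": len(net.nodes),
        "n_edges": len(net.edges),
        "n_entrance": by_type[NODE_ENTRANCE],
        "n_intersection": by_type[NODE_INTERSECTION],
        "n_end": by_type[NODE_END],
        "total_length_mm": float(sum(e.length_mm for e in net.edges)),
    }
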