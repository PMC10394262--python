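"""Tidy CSV outputs and overlay renderings — the user-facing surface.

Four tables are written per project, with fixed headers and deterministic
row order (group, serial, then gallery/node id):

* ``per_image.csv``  — one row per image:
  ``group,serial,total_mm,len1_mm,len2_mm,len3_mm,len4plus_mm,n_galleries,n_nodes,n_edges,growth_mm``
* ``per_gallery.csv`` — one row per gallery per image:
  ``group,serial,gallery_id,rank,parent_id,length_mm,merged_end``
* ``nodes.csv`` — ``group,serial,node_id,x_mm,y_mm,type``
* ``edges.csv`` — ``group,serial,node_a,node_b,gallery_id,length_mm``

The "4+" pooling (quaternary and later galleries summed into one column)
applies only to the per-image summary; the per-gallery table keeps true
ranks. All lengths are in mm; node coordinates are reference-corrected and
mm-scaled. Overlays, in contrast, are drawn in raw pixel coordinates so
they register with the photograph — the two frames are intentionally
different.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import pandas as pd
from PIL import Image, ImageDraw

from .classification import ClassifiedGallery
from .datamodel import ImageAnnotation, Point
from .geometry import polyline_length
from .network import GalleryNetwork
from .sequence import GroupResult, TimeSeriesRecord

__all__ = ["PER_IMAGE_COLUMNS", "PER_GALLERY_COLUMNS", "NODE_COLUMNS",
           "EDGE_COLUMNS", "RANK_PALETTE", "NODE_COLORS",
           "write_tables", "render_overlay", "export_group_results"]

PER_IMAGE_COLUMNS = ["group", "serial", "total_mm", "len1_mm", "len2_mm",
                     "len3_mm", "len4plus_mm", "n_galleries", "n_nodes",
                     "n_edges", "growth_mm"]
PER_GALLERY_COLUMNS = ["group", "serial", "gallery_id", "rank", "parent_id",
                       "length_mm", "merged_end"]
NODE_COLUMNS = ["group", "serial", "node_id", "x_mm", "y_mm", "type"]
EDGE_COLUMNS = ["group", "serial", "node_a", "node_b", "gallery_id", "length_mm"]

#: stroke colors by identity rank (1-based; ranks past the palette cycle)
RANK_PALETTE: list[tuple[int, int, int]] = [
    (31, 119, 180),    # primary: blue
    (214, 39, 40),     # secondary: red
    (44, 160, 44),     # tertiary: green
    (255, 127, 14),    # quaternary+: orange
]
#: node colors by type: entrances purple, intersections green, ends yellow
NODE_COLORS: dict[str, tuple[int, int, int]] = {
    "entrance": (128, 0, 128),
    "intersection": (0, 170, 0),
    "end": (255, 215, 0),
}
UNCLASSIFIED_COLOR = (120, 120, 120)


def rank_color(rank: int | None) -> tuple[int, int, int]:
    if rank is None:
        return UNCLASSIFIED_COLOR
    return RANK_PALETTE[(rank - 1) % len(RANK_PALETTE)]


def write_tables(records: Sequence[TimeSeriesRecord],
                 classified: Mapping[tuple[str, int], Sequence[ClassifiedGallery]],
                 networks: Mapping[tuple[str, int], GalleryNetwork],
                 outdir: str | os.PathLike,
                 mm_per_px: Mapping[tuple[str, int], float] | None = None,
                 ) -> dict[str, str]:
    """Write the four CSVs; returns ``{table name: path}``.

    ``classified`` and ``networks`` are keyed by ``(group, serial)``.
    ``mm_per_px`` supplies the per-image calibration used for the
    per-gallery lengths and node coordinates (default 1.0: mm == px).
    """
    os.makedirs(outdir, exist_ok=True)
    mmpx = mm_per_px or {}

    per_image = pd.DataFrame(
        [[r.group_id, r.serial, r.total_mm, r.len1_mm, r.len2_mm, r.len3_mm,
          r.len4plus_mm, r.n_galleries, r.n_nodes, r.n_edges, r.growth_mm]
         for r in records],
        columns=PER_IMAGE_COLUMNS,
    ).sort_values(["group", "serial"], kind="stable")

    gal_rows, node_rows, edge_rows = [], [], []
    for (group, serial) in sorted(classified):
        f = mmpx.get((group, serial), 1.0)
        for c in sorted(classified[(group, serial)], key=lambda c: c.gallery_id):
            gal_rows.append([group, serial, c.gallery_id,
                             c.rank if c.rank is not None else "",
                             c.parent_id if c.parent_id is not None else "",
                             polyline_length(c.gallery.points) * f,
                             c.merged_end])
    for (group, serial) in sorted(networks):
        f = mmpx.get((group, serial), 1.0)
        net = networks[(group, serial)]
        for n in sorted(net.nodes, key=lambda n: n.node_id):
            node_rows.append([group, serial, n.node_id,
                              n.coord.x * f, n.coord.y * f, n.type])
        for e in net.edges:
            edge_rows.append([group, serial, e.node_a, e.node_b,
                              e.gallery_id, e.length_mm])

    per_gallery = pd.DataFrame(gal_rows, columns=PER_GALLERY_COLUMNS)
    nodes = pd.DataFrame(node_rows, columns=NODE_COLUMNS)
    edges = pd.DataFrame(edge_rows, columns=EDGE_COLUMNS)

    paths = {}
    for name, df in [("per_image", per_image), ("per_gallery", per_gallery),
                     ("nodes", nodes), ("edges", edges)]:
        path = os.path.join(outdir, f"{name}.csv")
        df.to_csv(path, index=False)  # str(float) = full round-trip precision
        paths[name] = path
    return paths


def export_group_results(results: Sequence[GroupResult],
                         state,
                         outdir: str | os.PathLike) -> dict[str, str]:
    """Write the four tables for a list of per-group analysis results."""
    from .sequence import _mm_per_px, materialize_series

    records: list[TimeSeriesRecord] = []
    classified, networks, mmpx = {}, {}, {}
    for res in results:
        records.extend(res.records)
        scale_mm = state.group_scale_mm(res.group_id)
        resolved = {a.serial: a for a in materialize_series(state, res.group_id)}
        for serial, cl in res.classified.items():
            key = (res.group_id, serial)
            classified[key] = cl
            networks[key] = res.networks[serial]
            mmpx[key] = _mm_per_px(resolved[serial], scale_mm)
    return write_tables(records, classified, networks, outdir, mm_per_px=mmpx)


def render_overlay(annotation: ImageAnnotation,
                   classified: Sequence[ClassifiedGallery] | None = None,
                   network: GalleryNetwork | None = None,
                   image: Image.Image | None = None,
                   margin: int = 20,
                   line_width: int = 3,
                   node_radius: int = 4) -> Image.Image:
    """Draw the traced galleries (colored by rank) over the source image.

    Galleries are stroked in raw pixel coordinates so the overlay registers
    with the photograph; an optional node layer (purple entrances, green
    intersections, yellow ends) is shifted back into the raw frame using
    the image's reference point. Without a source image, a white canvas of
    the annotations' bounding box plus ``margin`` is used.
    """
    ranks = {c.gallery_id: c.rank for c in (classified or [])}
    if image is None:
        xs = [p.x for g in annotation.galleries for p in g.points] or [0.0]
        ys = [p.y for g in annotation.galleries for p in g.points] or [0.0]
        w = int(max(xs)) + margin + 1
        h = int(max(ys)) + margin + 1
        canvas = Image.new("RGB", (max(w, 2 * margin), max(h, 2 * margin)),
                           (255, 255, 255))
    else:
        canvas = image.convert("RGB").copy()
    draw = ImageDraw.Draw(canvas)

    for g in annotation.galleries:
        color = rank_color(ranks.get(g.gallery_id))
        draw.line([p.as_tuple() for p in g.points], fill=color, width=line_width)

    if network is not None:
        ref = annotation.ref_point or Point(0.0, 0.0)
        for n in network.nodes:
            x, y = n.coord.x + ref.x, n.coord.y + ref.y
            draw.ellipse([x - node_radius, y - node_radius,
                          x + node_radius, y + node_radius],
                         fill=NODE_COLORS[n.type])
    return canvas
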