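"""Optional interactive annotator (matplotlib window).

Shows the images of each group sequentially with the previous image's
galleries as an editable overlay, following the measurement workflow:
Check (analyze / skip / empty), Ref point, Measure (freeform polylines),
Scale. The project JSON is saved after every image, so an interruption
loses at most the current image.

Keybindings
-----------
=============  ===================================================
left click     add a point to the current polyline
``g``          close the current gallery polyline
``r``          next click sets the reference point
``c``          next two clicks set the scale line
``s``          skip this image (inherit the previous one)
``e``          mark the image empty (no galleries)
``t``          toggle append mode ("not appending" = backfilling)
``u``          undo the last point
``n``          save this image and move to the next
``q``          save and quit
=============  ===================================================

This module is intentionally thin over :mod:`gallerytrack.datamodel`; the
headless ``measure --from-annotations`` path exercises the same model
without a display.
"""

from __future__ import annotations

import logging
import os

from .datamodel import (DEFAULT_THRESHOLD_PX, Gallery, ImageAnnotation, Point,
                        ProjectState, Status, save_project)

log = logging.getLogger(__name__)


class _ImageSession:
    """Mutable annotation state for the image currently on screen."""

    def __init__(self, group_id: str, serial: int,
                 inherited: ImageAnnotation | None):
        self.group_id = group_id
        self.serial = serial
        self.status = Status.ANALYZED
        self.append_mode = True
        self.ref_point: Point | None = None
        self.scale_line: list[Point] = []
        self.galleries: list[Gallery] = (
            [g.copy() for g in inherited.galleries] if inherited else [])
        if inherited:
            self.ref_point = inherited.ref_point
            self.scale_line = list(inherited.scale_line or [])
        self.current: list[Point] = []
        self.mode = "draw"  # draw | ref | scale

    def next_gallery_id(self) -> str:
        return f"g{len(self.galleries):02d}"

    def finish(self) -> ImageAnnotation:
        if self.current and len(self.current) >= 2:
            self.galleries.append(Gallery(self.next_gallery_id(), self.current))
            self.current = []
        return ImageAnnotation(
            group_id=self.group_id,
            serial=self.serial,
            status=self.status,
            ref_point=self.ref_point,
            scale_line=(tuple(self.scale_line[:2])
                        if len(self.scale_line) >= 2 else None),
            append_mode=self.append_mode,
            galleries=[] if self.status is not Status.ANALYZED else self.galleries,
        )


def run_annotator(image_dir: str,
                  groups: dict[str, list[tuple[int, str]]],
                  project_path: str,
                  threshold_px: float = DEFAULT_THRESHOLD_PX,
                  scale_mm: float | None = None) -> ProjectState:
    """Walk every image of every group in (group, serial) order."""
    import matplotlib.pyplot as plt
    from PIL import Image

    state = ProjectState(threshold_px=threshold_px, scale_mm=scale_mm)
    stop = False
    for group_id in sorted(groups):
        prev: ImageAnnotation | None = None
        for serial, filename in groups[group_id]:
            if stop:
                break
            session = _ImageSession(group_id, serial, prev)
            img = Image.open(os.path.join(image_dir, filename))

            fig, ax = plt.subplots(figsize=(9, 7))
            ax.imshow(img)
            ax.set_title(f"{group_id} #{serial} — g:close gallery  r:ref  "
                         "c:scale  s:skip  e:empty  t:append  u:undo  n:next  q:quit")
            artists: list = []

            def redraw() -> None:
                for a in artists:
                    a.remove()
                artists.clear()
                for g in session.galleries:
                    xs = [p.x for p in g.points]
                    ys = [p.y for p in g.points]
                    artists.extend(ax.plot(xs, ys, "-o", color="tab:blue", ms=3))
                if session.current:
                    xs = [p.x for p in session.current]
                    ys = [p.y for p in session.current]
                    artists.extend(ax.plot(xs, ys, "-o", color="tab:red", ms=3))
                if session.ref_point:
                    artists.extend(ax.plot([session.ref_point.x],
                                           [session.ref_point.y], "+",
                                           color="magenta", ms=12))
                if session.scale_line:
                    xs = [p.x for p in session.scale_line]
                    ys = [p.y for p in session.scale_line]
                    artists.extend(ax.plot(xs, ys, "-s", color="green", ms=4))
                fig.canvas.draw_idle()

            def on_click(event) -> None:
                if event.inaxes is not ax or event.xdata is None:
                    return
                p = Point(float(event.xdata), float(event.ydata))
                if session.mode == "ref":
                    session.ref_point = p
                    session.mode = "draw"
                elif session.mode == "scale":
                    session.scale_line.append(p)
                    if len(session.scale_line) >= 2:
                        session.scale_line = session.scale_line[-2:]
                        session.mode = "draw"
                else:
                    session.current.append(p)
                redraw()

            def on_key(event) -> None:
                nonlocal stop
                if event.key == "g":
                    if len(session.current) >= 2:
                        session.galleries.append(
                            Gallery(session.next_gallery_id(), session.current))
                    session.current = []
                elif event.key == "r":
                    session.mode = "ref"
                elif event.key == "c":
                    session.mode = "scale"
                    session.scale_line = []
                elif event.key == "s":
                    session.status = Status.SKIPPED
                    plt.close(fig)
                    return
                elif event.key == "e":
                    session.status = Status.EMPTY
                    session.galleries = []
                    session.current = []
                elif event.key == "t":
                    session.append_mode = not session.append_mode
                    log.info("append_mode -> %s", session.append_mode)
                elif event.key == "u":
                    if session.current:
                        session.current.pop()
                    elif session.galleries:
                        last = session.galleries.pop()
                        session.current = list(last.points)
                elif event.key == "n":
                    plt.close(fig)
                    return
                elif event.key == "q":
                    stop = True
                    plt.close(fig)
                    return
                redraw()

            fig.canvas.mpl_connect("button_press_event", on_click)
            fig.canvas.mpl_connect("key_press_event", on_key)
            redraw()
            plt.show(block=True)

            ann = session.finish()
            state.add(ann)
            prev = ann if ann.status is not Status.SKIPPED else prev
            save_project(state, project_path)  # incremental: lose <= 1 image
        if stop:
            break
    return state
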