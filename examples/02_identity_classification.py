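"""Classify galleries into primary / secondary / tertiary identities.

Identity follows the branching hierarchy: galleries from the entrance are
primary, galleries emerging from a primary's side are secondary, and so
on. A gallery whose tip meets another gallery is reported as merged.
"""

from gallerytrack import Gallery, Point, assign_identities

galleries = [
    Gallery("A", [Point(0, 0), Point(120, 0)]),          # from the entrance
    Gallery("B", [Point(60, 1), Point(60, 80)]),         # branches off A
    Gallery("C", [Point(61, 40), Point(120, 40)]),       # branches off B
    Gallery("D", [Point(90, 2), Point(90, 39)]),         # off A, merges into C
]
entrance = [Point(0, 0)]

for c in assign_identities(galleries, entrance, threshold_px=5.0):
    label = {1: "primary", 2: "secondary", 3: "tertiary"}.get(c.rank, f"rank {c.rank}")
    merge = " (tip merges into another gallery)" if c.merged_end else ""
    parent = f", parent {c.parent_id}" if c.parent_id else ""
    print(f"{c.gallery_id}: {label}{parent}{merge}")
# A is primary; B (off A) secondary; C (off B) tertiary; D is secondary
# (it emerges from A's side) and its endpoint lies on C, so it is merged.
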