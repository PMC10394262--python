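"""Measure a traced polyline and calibrate pixels to millimetres.

The basic measurement loop: a user clicks a tunnel as a freeform polyline,
clicks the two ends of a scale object of known real length, and every
length in the analysis comes out in mm.
"""

from gallerytrack import Point, polyline_length, scale_factor, snap_endpoints

# a tunnel traced with four clicks (pixel coordinates, origin top-left)
tunnel = [Point(100, 200), Point(160, 180), Point(230, 190), Point(300, 150)]
length_px = polyline_length(tunnel)
print(f"traced length: {length_px:.2f} px")

# the scale object: a 20 mm ruler segment spanning 100 px in the photo
mm_per_px = scale_factor((Point(50, 400), Point(150, 400)), scale_mm=20.0)
print(f"calibration:   {mm_per_px:.3f} mm/px")
print(f"tunnel length: {length_px * mm_per_px:.2f} mm")

# endpoint snapping: clicks within the threshold collapse into one node
clicks = [Point(100, 200), Point(103, 201), Point(300, 150)]
clusters = snap_endpoints(clicks, threshold_px=10.0)
print(f"{len(clicks)} clicked endpoints -> {len(clusters)} distinct nodes")
# The first two clicks are 3.2 px apart (< 10 px threshold), so they are
# the same physical junction; the third is a separate tunnel tip.
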