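# gallerytrack

Measure the temporal length development of gallery systems built by
animals — termite foraging tunnels, ant nest excavations, mouse burrows,
shelter tubes — from sequences of annotated images.

Many subterranean and wood-boring animals build branching gallery systems,
and the dynamics of their building behavior are captured by photographing
the structure repeatedly and measuring how much, and where, it grew.
Automated binarization needs high-quality standardized imagery; manual
tracing works on any photograph a human can read, but bookkeeping the
traced polylines — aligning repositioned photographs, converting pixels to
millimetres, deciding which tunnel is primary and which is a branch,
extracting the node/edge network, keeping a tidy spreadsheet — is where
the time and the errors go. gallerytrack takes over all of that: the user
(or a synthetic generator) supplies traced polylines per image, and the
library produces analysis-ready tables.

## What it computes

For each image *t* of a group (one experiment/colony, images named
`<groupid>_<serial>.<ext>`, e.g. `TunnelA_00.jpg`):

- **Alignment** — all clicked coordinates are shifted so the clicked
  reference landmark is the origin: `p ↦ p − r_t`. Without a landmark the
  top-left corner is used.
- **Calibration** — a scale line of drawn pixel length `ℓ_px` over an
  object of known length `L_mm` gives `mm/px = L_mm / ℓ_px`; every output
  is in mm.
- **Identity classification** — each traced gallery *g* (an ordered
  polyline; first point = origin, last = tip) gets a rank:
  rank 1 (primary) if its start lies within the contact threshold θ of an
  entrance point; otherwise rank = rank(parent) + 1, where the parent is
  the nearest pre-existing gallery whose polyline lies within θ of *g*'s
  start. A tip that lands within θ of another gallery is a **merge**
  (the gallery ends there). At a split, the branch with the shallower
  angle keeps the parent's identity — a drawing convention the library
  validates (`split_inheritance_check`) but never enforces by re-cutting
  the user's polylines.
- **Network extraction** — gallery start/end points and attachment points
  are snapped into nodes (single-linkage clustering under strict
  `dist < θ`); polylines are split at interior nodes; nodes are typed
  entrance / intersection / end. Σ edge lengths = Σ gallery lengths
  exactly.
- **Temporal logic** — skipped images (no development) inherit the
  previous image's annotations; empty images yield zero rows; under the
  default append assumption galleries may only grow (violations are
  reported; the "not appending" flag permits backfilling), and per-step
  growth increments are computed on the totals.

Outputs are four tidy CSVs (`per_image`, `per_gallery`, `nodes`, `edges`)
plus per-image overlay renderings with galleries colored by rank and
nodes colored purple (entrance) / green (intersection) / yellow (end).

## Worked example

```python
from gallerytrack import Gallery, Point, assign_identities

galleries = [
    Gallery("A", [Point(0, 0), Point(120, 0)]),      # from the entrance
    Gallery("B", [Point(60, 1), Point(60, 80)]),     # branches off A
    Gallery("C", [Point(61, 40), Point(120, 40)]),   # branches off B
    Gallery("D", [Point(90, 2), Point(90, 39)]),     # off A, merges into C
]
for c in assign_identities(galleries, [Point(0, 0)], threshold_px=5.0):
    print(c.gallery_id, c.rank, c.parent_id, c.merged_end)
```

prints

```
A 1 None False
B 2 A False
C 3 B False
D 2 A True
```

A is primary (it starts at the entrance); B emerges from A's side, so it
is secondary; C off B is tertiary; D emerges from A (secondary) and its
tip lies on C, so its endpoint is a merge. Reducing the same system to a
network (`examples/03_network_extraction.py`) gives, at 0.2 mm/px:

```
node 0: entrance     at (   0.0,    0.0)
node 1: intersection at (  50.0,    0.2)
node 2: end          at ( 100.0,    0.0)
node 3: end          at (  50.0,   70.0)
edge 0-1:  10.00 mm  (gallery A)
edge 1-2:  10.00 mm  (gallery A)
edge 1-3:  13.90 mm  (gallery B)
```

— the junction where B leaves A splits A into two 10 mm edges, and the
sum of edge lengths equals the sum of gallery lengths.

The `examples/` directory has one short script per capability:
measurement and calibration, identity classification, network
extraction, growth time series, and the end-to-end export.

## Command line

```bash
# generate a synthetic 2-colony growth project (with rendered PNGs)
gallerytrack synthgen --output demo --seed 1 --groups 2 --steps 20 --render

# collect annotations headlessly from a prepared project file
gallerytrack measure --input demo --output demo/project.json \
    --from-annotations demo/project.json

# run the post-analysis: classify, measure, network, export CSVs + overlays
gallerytrack postprocess --input demo/project.json --output demo/out
```

`postprocess` exits 0 with logged warnings (append violations,
unclassified galleries, each tagged with group/serial/gallery id) unless
`--strict` is given. An interactive matplotlib annotator
(`gallerytrack measure` without `--from-annotations`) traces images with
click-to-draw keybindings; the headless path is the supported batch/CI
route. Annotations persist as versioned, diffable JSON
(`format_version`, `threshold_px`, `scale_mm`, per-group image records
with raw clicked coordinates).

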