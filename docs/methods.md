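# Methods

This note records the model behind gallerytrack's measurements, the
parameters that matter, the synthetic data the tests rest on, and the
design decisions taken where more than one reading was defensible.

## The measurement model

The unit of observation is a **gallery**: one tunnel traced as an ordered
polyline of clicked pixel points. Its first point is where it originates
(at an entrance or on its parent's side), its last is its current tip.
An **image annotation** holds one photograph's galleries plus a reference
landmark, a scale line, a status (analyzed / skipped / empty) and the
append flag; a **project** is an ordered collection of annotations per
group with two global parameters:

| parameter | unit | default | meaning |
|---|---|---|---|
| `threshold_px` (θ) | px | 10 | contact/snapping distance: two structures closer than θ touch |
| `scale_mm` | mm | none | real-world length of the scale object; without it outputs stay in px (mm ≡ px) |

θ is the single most consequential parameter: it decides parentage
(a gallery's start within θ of another polyline is a branch), merges
(a tip within θ of another polyline ends there), and node identity
(endpoint clusters under single-linkage `dist < θ`). The default of 10 px
suits photographs where tunnels are tens of pixels wide; it is a
per-project setting and a CLI flag. Contact is **strict** `< θ`: ties at
exactly θ do not merge.

Coordinates are stored raw, exactly as clicked; reference alignment
(`p − r_t`) is applied at analysis time only. This keeps the project file
an audit trail of user input and makes alignment reversible. Entrance
points, which must be comparable across repositioned photographs, are
stored in the aligned frame.

## Identity assignment

Ranks follow the branching-hierarchy convention: primary galleries
originate at the start point, a gallery emerging from the side of a
pre-existing gallery is a descendant (parent rank + 1), a shallower
branch at a split keeps the parent's identity, and a tip meeting a
pre-existing gallery is an endpoint (merge). Operationally:

* the parent candidate is the gallery whose polyline (projection onto
  segments, not just vertices) is nearest to the child's **start**, if
  within θ; ties break by distance then lexicographic gallery id;
* with declared entrance points, a start within θ of an entrance is
  primary regardless of nearby galleries (so primaries sharing one
  entrance never parent each other); without entrances, parentless
  galleries are primary;
* ranks propagate by iterating parent links to a fixed point; circular
  parentage (two galleries each starting on the other) and orphans under
  declared entrances are flagged `unclassified`, never silently ranked,
  and downstream stages refuse to run on them;
* attachment is judged from the start only: a gallery drawn backwards
  (start in open space, end on a parent) is reported `merged_end`, not
  re-parented — the drawing direction is semantic;
* the shallow-angle rule is a drawing convention for the user;
  `split_inheritance_check` validates it (arccos of normalized dot
  products, ties to the first branch with a warning) but the library
  never re-segments a polyline against the user's drawing.

Whether a parent's own endpoints should be excluded when testing "emerges
from the side" is genuinely open (a child starting exactly at a parent's
end could be read as a continuation); any attachment within θ counts as
descent here, and the per-gallery table carries enough information
(parent id, attachment arc length) for users to re-interpret such cases.

## Network reduction

Candidate nodes are every gallery's start and end plus every attachment
point (child starts and merged tips projected onto the gallery they
touch, so the graph is embedded on the drawn skeleton). Candidates snap
into nodes by single-linkage clustering under strict `< θ` (chaining is
accepted as the simplest reading of "within the threshold"; it can merge
a chain of mutually close endpoints, which is documented behavior).
The node coordinate is the cluster centroid.

Each polyline is split at the interior nodes lying on it, by arc-length
position; because split positions telescope, the sum of edge lengths
equals the sum of gallery lengths to float precision (the suite asserts
1e-6 relative). Split positions closer than 1e-9 px of arc collapse onto
one node. Node types: `entrance` if the cluster contains a declared
entrance point, else `end` for graph degree 1, else `intersection`;
a declared entrance with no gallery within θ produces no node. Merge-free
systems are forests (edges = nodes − components); every user-drawn merge
adds exactly one independent cycle.

## Temporal logic

Skipped images inherit a deep copy of the nearest preceding
analyzed/empty image's galleries, reference point and scale line (the
file stores no copy; materialization is idempotent). Whether the
original workflow inherits ref point and scale line on a skip is not
specified anywhere authoritative; inheriting both is this package's
dialect. An image missing only a scale line inherits the most recent
one, so drawing the scale once per sequence suffices.

Append consistency: with `append_mode` true, each previous gallery must
be a point-wise prefix of its successor after alignment, each point
within a tolerance that defaults to θ (re-clicked inherited points
jitter; exact equality would be brittle). With `append_mode` false — the
user declared backfilling — replacement is free and no violations are
reported. Violations are data (warnings with group/serial/gallery
provenance), not errors, except under `--strict`.

Growth increments are computed on per-image totals (the first image's
increment is its total). Per-rank length columns pool ranks ≥ 4 into a
single "4+" bin in the per-image table; the per-gallery table keeps true
ranks.

## The synthetic generator

`synthgen` emulates what the package is meant to measure — a branching
gallery system growing from a single entrance in a 2-D arena,
photographed every step with a slightly repositioned camera — while
keeping exact bookkeeping (true ranks, parents, attachment arc lengths,
merges, per-step cumulative mm, node/edge/cycle counts) that the
pipeline must recover. Defaults: 20 steps, 2 primaries radiating from
the arena center, elongation N(15, 4) px/step capped at 2θ, branch
probability 0.12 per gallery per step up to rank 5 and 40 galleries,
branch angles 50–70°, heading wobble N(0, 4°) inside a ±35° cone,
camera jitter N(0, 3 px), a fixed 100 px scale line for a 20 mm object
(0.2 mm/px). These sizes mirror a desk-scale tunneling arena where a
colony's system grows by a few tunnel-widths per interval.

The generator *constructs* unambiguous geometry rather than hoping for
it: attachment and merge points keep ≥ 2.5θ from every existing node and
unrelated polyline (1.3θ under `hard_mode`, which probes tie-breaking);
growth segments are capped at 2θ so a segment whose endpoints respect
that clearance cannot come within θ of an unrelated gallery; a child's
first segment leaves its parent at ≥ 50° with length ≈ 2θ, clearing the
parent immediately and guaranteeing the continuation/branch angle
convention. Optional merges are injected at the final step by steering a
tip onto a target point on another gallery along a checked-clear
segment. Optional skipped steps freeze growth to exercise copy-forward.

What this emulates — and what it does not: it produces realistic
*topology and bookkeeping* (nested branching, monotone growth, camera
shift, skipped/empty frames), not termite behavior (no digging dynamics,
no backfilling, no curvature statistics of real tunnels) and not
annotation noise beyond camera jitter (no mis-clicks, no threshold-
straddling contacts unless `hard_mode`). Passing recovery tests
therefore shows the pipeline is correct on cleanly traced input; it does
not certify robustness to sloppy tracing, which is what the overlay
images are for in real use.

## Numerical choices

* Lengths, distances and projections use exact Euclidean arithmetic
  (shapely for point-to-polyline projection); no grid discretization
  anywhere in the pipeline.
* Snapping uses a k-d tree pair query followed by union-find; pairs at
  exactly θ are filtered out (strict contact). Cluster output order is
  by smallest member index, making results order-independent at set
  level and deterministic.
* Serialization is versioned JSON; Python's shortest round-trip float
  repr makes save/load bit-exact on coordinates. Skipped images store no
  gallery copy.
* Degenerate inputs fail loudly: polylines need ≥ 2 distinct consecutive
  points, scale lines nonzero length, the first image of a group cannot
  be skipped, empty images cannot carry galleries.
* CSVs are written with full float precision and deterministic row
  order (group, serial, id); repeated runs are byte-identical.

## Problem sizes in the test suite

The suite exercises 100 independent growth sequences (20 steps each) for
classification recovery, 20 for the graph conservation laws, a
3-group × 20-serial project end-to-end through the CLI, and one
45-group × 25-serial batch (1125 images) as a throughput check —
sizes chosen to mirror an hourly multi-colony tunneling study at desk
scale while keeping the default test run fast on one CPU.

## Known limitations

* One entrance set per group; entrances are points, not regions.
* A gallery id must persist across a group's images; the pipeline does
  not re-identify renamed galleries.
* Network analysis stops at counts and lengths; centrality, meshedness
  and similar graph statistics are downstream users' territory.
* The interactive annotator is a thin convenience (matplotlib window);
  it is not tested under CI and the headless `--from-annotations` route
  is the supported batch path.
* Annotation files from other tracing tools (typically undocumented
  binary formats) are not readable; this package defines its own
  documented JSON project format.
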