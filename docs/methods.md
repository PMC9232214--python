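# Methods

## Model and conventions

A *pain recording* is one pencil mark: an axis-aligned square (the
pencil tip is square; the code accepts general rectangles) on a 2D
body template, stored with its top-left corner `(x, y)`, size
`(w, h)`, body region label, and visibility status. Coordinates are
template pixels with y increasing downward (the SVG convention), are
real-valued, and are never rounded. A rectangle's footprint is the
half-open box `[x, x+w) × [y, y+h)`, so abutting rectangles neither
overlap nor leave gaps. Zero-area recordings are rejected at ingest.

A *drawing set* is all recordings of one region together with `T`, the
total number of submitted drawings **including empty ones** (a
participant who reported no pain still submitted a drawing), and `P`,
the participants with at least one visible recording (`|P| ≤ T`).
Regions are processed independently; the recording's region label is
authoritative (no geometric inference).

## Overlap decomposition

The decomposition is coordinate compression followed by constrained
merging:

1. edge coordinates along each axis are collected, sorted and
   deduplicated;
2. consecutive edges become half-open interval windows; the x- and
   y-windows cross into grid cells, so every input rectangle is a
   union of whole cells;
3. every covered cell is labelled with its *overlap set*: the distinct
   participants owning at least one rectangle containing the cell.
   Multiple marks by one participant over the same cell count once
   (set semantics);
4. cells are merged into maximal rectangles in two passes. Pass 1
   fuses maximal runs of adjacent cells with identical overlap sets
   along the layout axis (x for the *horizontal* layout, y for
   *vertical*), within each cross-axis band. Pass 2 fuses pass-1
   results that have identical overlap sets and identical layout-axis
   extent and are edge-adjacent on the cross axis, to a fixpoint
   (fusing maximal runs of adjacent bands reaches the fixpoint in one
   sweep, since merging never changes the layout-axis extent).

The output is a set of pairwise disjoint rectangles tiling the drawn
area exactly, each constant in its overlap set and maximal under both
merge rules. Layout only changes how the tiling is cut (wider vs
longer rectangles); the total area per overlap set is layout-
invariant. Three strictly nested squares by three participants yield
nine rectangles in either layout; by a single participant, one.

The exact merge-eligibility conditions were an open design point; the
two-pass scheme above was chosen because it is the unique simple
scheme that reproduces the nested-squares counts in both layouts, and
its pass-2 relation is confluent (chains along one axis), making the
output independent of processing order. No claim of *minimal*
rectangle count is made — only maximality under these two rules.

Every output rectangle carries `|o|` (overlap frequency) and
`|o| / T` (overlap proportion). Using `T` — empty drawings included —
as the denominator is the default because the proportion should read
as "fraction of the cohort with pain here"; a flag substitutes `|P|`
for analyses restricted to participants who drew. Output rows are
sorted by `(y, x)`; overlap sets serialise as lexicographically sorted
ids joined with `;` (the CSV delimiter is `,`). Filter bounds
(frequency range, minimum width/height) are inclusive.

### Implementation notes

The grid is represented column-wise. Participant-set identity per cell
is established by summing per-participant 128-bit blake2b keys
(together with a distinct-participant count) over each participant's
coverage mask; cells with equal (count, key-sum) carry equal sets. The
member sets of each distinct label are then recovered exactly by
pairing every rectangle's participant with the labels under its
footprint, and verified against the per-cell counts — a key collision
(probability ~2⁻¹²⁸ per label pair) raises an error rather than
corrupting output. Merging is run-length encoding over the label grid.
This keeps maps with ~10⁶ output rectangles tractable (seconds, not
minutes) while the public contracts — the cell→set mapping, the
rectangle list — are thin views over the same single code path.
Large intermediate buffers are allocated once and filled in place; the
per-rectangle label lists are deduplicated while still cache-resident.

## Eraser and duplicate semantics

Capture tools erase by hiding a previously inserted element, so a
geometry can be drawn, erased and redrawn. Recordings with identical
(participant, region, x, y, w, h) — exact equality, no tolerance —
collapse to one instance whose visibility is the *last* occurrence's;
if that status is hidden, the recording is excluded. Identical
geometries from different participants are distinct recordings. The
operation is idempotent and keeps first-occurrence order.

## Null-drawing masking

The decomposition knows nothing of region outlines, so rectangles can
overflow the template where participants drew over a border. For heat
maps this is invisible (SVG clipping); for analysis, a synthetic
*null drawing* that tiles the template within its boundaries can be
added to the cohort before decomposition. Masking then keeps only
rectangles covered by the null drawing *and* at least one real
participant, removes the null participant from every overlap set,
decrements frequencies, and recomputes proportions with the null
drawing excluded from the denominator. Rectangles covered by the null
drawing alone are exactly the undrawn within-template locations and
are dropped; requesting a mask for an id absent from the map is an
error.

## Rendering

Each output rectangle is drawn on the blank template SVG in one
configurable colour (default `#ff0000`); the overlap is coded by the
element's opacity:

    opacity(f) = f / (F_max + 1)

with `F_max` the map's maximum frequency. This is strictly increasing
in `f` and strictly inside (0, 1) for every valid input — the most
common location never fully saturates, the least common is never
invisible. The exact formula was an open design point; any strictly
monotone map into (0, 1) serves, and this one is the simplest.
Geometry attributes are emitted exactly as the decimal strings of the
rectangle fields. The HTML wrapper embeds the SVG with a slider that
hides rectangles whose overlap proportion exceeds the chosen cutoff
(rectangles are visible iff proportion ≤ threshold; the default is the
maximum, showing everything). Optional per-region clip paths hide
overflow; off by default since overflow does not distort frequencies.

## Synthetic workloads and fixtures

Real cohort drawings are not distributable, so generators emulate
their structure on a 1000×1000 plane (origin top-left, one region
labelled `xy-plane`):

* **single-click** — n rectangles, one per participant; stresses pure
  overlap computation. Dataset sizes step by 10,000.
* **participant drawings** — 100 rectangles per participant (a typical
  freehand drawing); dataset sizes step by 100 participants.

Origins are sampled *without* replacement from the plane's integer
ordered pairs (default scope: the whole dataset; a flag restricts the
scope to each participant, under which cross-participant collisions
may occur). Widths and heights are sampled independently *with*
replacement from 10, 20, …, 100 (the pencil sizes). Rectangles may
extend past the right/bottom plane edge and are recorded as drawn.
One seeded PRNG stream per dataset; the seed is recorded as a
`# seed=` header comment, and equal seeds reproduce byte-identical
CSV.

These workloads emulate load, not clinical realism: real drawings
cluster anatomically, use a handful of pencil sizes (10/30/60 in the
motivating cohorts), and contain duplicates and erasures. Passing
tests therefore demonstrate geometric correctness and scaling, not
clinical validity of any particular map.

Deterministic fixtures (`concentric3`, `nested_single`, `venn3`,
`two_square`) provide the worked nested-squares examples, a three-way
overlap with nonempty triple intersection, and the two-square pair
used in unit tests.

## Validation

An independent brute-force *pixel oracle* rasterises integer-
coordinate instances to unit cells, assigning each pixel its
participant set directly (bitmask per pixel, ≤64 participants). Tests
assert, on randomized instances, per-pixel equality between the oracle
and the decomposition, pairwise disjointness, exact conservation of
the drawn area, merge-rule maximality, layout-invariance of per-set
areas, and invariance to input row order. The acceptance suite runs
200 such instances (≤10 participants, ≤100 rectangles, [0,200)²
plane).

Scaling is checked qualitatively on single-click workloads of 10k,
20k and 40k rectangles: runtime must grow monotonically and the
10k→40k ratio must stay clearly below the 16× that quadratic scaling
implies over a 4× size range (the check allows for allocation-cost
noise; no absolute wall-clock target is asserted, as that is
hardware-dependent). Problem sizes were chosen so the whole suite
runs in a few minutes on one CPU.

## Known limitations

* Overlap sets above 64 participants are unsupported by the *oracle*
  (not the decomposition itself).
* The pixel oracle requires integer coordinates (or a resolution that
  divides all coordinates); the decomposition itself handles reals.
* Presentation-style (CSS) visibility in SVG inputs is not
  interpreted; only the `visibility` attribute marks erasure.
* Body-region membership is taken from the `data-region` attribute /
  `region` column; there is no geometric assignment of marks to
  regions, and no coordinate harmonisation between different body
  templates.
* Merging optimises dimensions under the two stated rules only; the
  rectangle count is not globally minimal.
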