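# Methods

## Data model

A point is `(id, mz, rt, intensity, trace_id, envelope_id)`. m/z is in
Thomson, RT in seconds (scan times tagged in minutes are multiplied by 60
at import), intensity non-negative in arbitrary detector units. `trace_id`
(XIC membership) and `envelope_id` (isotopic-envelope membership) are
mutable metadata; 0 is the reserved "unassigned" sentinel on both, so CSV
rows without segmentation round-trip unchanged. A point's id equals its
record index in the binary point file.

Windows are half-open on both axes (`lo ≤ x < hi`). Chosen so that a tiling
of adjacent windows — the access pattern of navigation and of whole-file
sweeps — partitions the point set without duplicates. `QueryWindow.covering`
nudges the upper edges one ULP past a bounds' maxima so "full extent"
queries include boundary points.

## Weighted striding

Given `n` ordered points with intensities `I_0..I_{n-1}` and a requested
sample size `k ≤ n`:

1. `T = (Σ I_i) / k` (so the worked 10-point, total-30, k=3 window gives
   T = 10).
2. Visit points in the order `(j·s') mod n`, where `s'` is the smallest
   integer ≥ the stride length coprime with `n`. Coprimality makes the walk
   a full permutation; for stride 1 it is the natural order. The stride
   default is 42.
3. Accumulate each visited unselected point's intensity; when the
   accumulator reaches `T`, recruit the current point and subtract `T`
   (carryover). Wrap around, skipping already-recruited points, until `k`
   points are recruited.

Properties that follow: the sample is a subset of the input (never derived
points), has exactly `min(k, n)` distinct members, is returned in original
order, is deterministic, and is invariant under rescaling all intensities
by a positive constant. With uniform intensities and stride 1 the selected
indices are evenly spaced. The carryover means a very intense point can
recruit its low-intensity successors — which is what preserves the high/low
mix of the window.

Numerical guards, both degenerate-input choices of this implementation:

- **Zero total intensity** (`T = 0`): the accumulation rule degenerates, so
  the sample falls back to uniform index striding with step `⌈n/k⌉`.
- **Termination**: if a complete pass over the surviving points gains less
  than `T` while the carry is also below `T` (possible only through
  floating-point shortfall near the end of recruitment), the remaining
  slots are filled with the highest-intensity unselected points, ties to
  the lower index. In exact arithmetic this branch is unreachable: total
  unselected intensity always covers the remaining recruitment budget.
- The accumulator is preserved across the wrap boundary (not reset).

Scale invariance is exact in real arithmetic but can flip at
floating-point threshold ties; the test suite therefore probes it with
power-of-two factors, which rescale losslessly.

## Tree construction

Bulk loading is Sort-Tile-Recursive with alternating axes: a node with more
than `p` points sorts on the current axis (stable, tie-broken by the other
axis then id, so the tree shape is a pure function of the input), splits
into chunks of `⌈n/b⌉` consecutive points (equal cardinality — point
volume, not coordinate range), and recurses with the axis flipped. The
first level sorts by RT: raw MS data arrives RT-ordered, so the top-level
partition can in principle be assembled scan by scan. Leaves keep all their
ids; internal nodes keep a weighted-striding summary of size ≤ `p` drawn
from the concatenation of their children's id lists in child order (cost
`O(b·p)` per node, keeping the build `O(n log n)`), and their bounds are
the union of child bounds — equal to the exact extent of their descendant
points.

Defaults `p = 1000`, `b = 4`: a 10⁶-point run yields a ~5-level tree, and a
single node's summary (1000 points) is a usable thumbnail of its region.
`p` doubles as leaf capacity and summary size.

## Queries

Unbudgeted: descend every subtree whose bounds intersect the window, filter
leaf points by membership, sort by `(mz, rt, id)`.

Budgeted (`n`): level-synchronous breadth-first descent. At each level the
in-window points among the frontier's summaries are counted (leaves
contribute their full lists and stay in the frontier); the first level
supplying ≥ `n` candidates — or the all-leaf level, whichever comes first —
ends the descent. Candidates are sorted by `(mz, rt, id)` and, if they
exceed `n`, weighted-strided down to exactly `n`. Sorting before resampling
makes the response independent of traversal order; only in-window summary
points count toward the budget. Consequently the result is always a subset
of the unbudgeted result with exactly `min(n, window population)` points.

The level-synchronous stopping rule (no mixed summarize-some/descend-other
states) is a design choice: it is the simplest rule that is deterministic
and axis-neutral.

### Axis agnosticism

Because levels alternate axes, a window and its transpose across the
m/z = RT diagonal of a symmetric cloud do comparable work. The comparison
is structural — nodes visited, not wall-clock. On a ~10⁵-point symmetric
uniform cloud with the default tree, 100 transposed window pairs stay
within a factor of 2 in visit counts. The factor is not guaranteed on
shallow trees: with only 2–3 levels the counts are single digits, a ±1 node
difference looms large, and the odd/even parity of levels gives one axis
one extra cut; the property is meaningful at depth, which is where it
matters.

## Storage

- **Point file**: header `MZPTREE\0`, u32 version, u64 count, u32 record
  width; then little-endian `(f64 mz, f64 rt, f64 intensity)` records,
  24 bytes each, written leaf by leaf. Record `i` starts at
  `24 + 24·i`; a leaf occupies one contiguous range read with one seek.
  3×f64 is a deliberate precision choice — intensity round trips exactly
  through CSV and the store.
- **Ids**: assigned at write time as record indices; the builder's
  provisional ids are remapped throughout the tree. This makes the
  constant-time offset formula an identity rather than an index lookup.
- **Metadata**: SQLite tables `nodes`, `node_points` (summary id lists with
  explicit positions, so summaries reload in the exact order they were
  computed), `traces(trace_id, envelope_id)`, `point_trace(point_id,
  trace_id)`. Segmentation is normalized — envelope membership lives on the
  trace and points inherit it — while CSV export denormalizes both ids onto
  each row. Coordinates never enter SQLite; metadata edits cannot corrupt
  measurements.
- **Cache**: LRU hashmap id → point, capacity 80 % of a user-set memory
  limit (default 1 GiB), each entry costed at the 24-byte record width.
  The cache is transparent: enabled, disabled or cold, query results are
  identical. LRU is the natural fit for adjacent-window navigation, where
  consecutive queries re-touch most of their points.

## Interchange

mzML import streams spectra one at a time with an lxml `iterparse` walker
(32/64-bit float arrays, zlib or no compression), keeps MS1 only, uses the
scan start time as RT for every array pair, and excludes points with
intensity below 1 — a noise floor applied only to mzML, never to CSV, so
CSV is the lossless interchange path. "Below one" is read strictly
(`< 1`): an intensity of exactly 1 survives. The reader covers the MS1
subset of mzML this store ingests; MS/MS, ion-mobility and imaging
extensions are out of scope.

CSV is the 5-column `[m/z, RT, intensity, XIC ID, isotope distribution
ID]` schema, comma-separated, floats serialized at round-trip precision,
header detected by a non-numeric first field, blank ids read as 0.

## Synthetic data

The generator emulates what the method needs from real data — spatial
clustering into RT-elongated traces grouped into envelopes, a heavy-tailed
intensity mix, sparse noise — without claiming the statistics of any real
instrument. Each envelope draws a charge, 3–5 isotope peaks spaced
`1.003/charge` Th with geometrically decaying heights (ratio 0.7), a
Gaussian elution profile (σ uniform in 5–20 s) sampled once per scan
(1 s default over a 600 s gradient, m/z 400–1200 Th), apex intensity
uniform in 50–5000; per-point m/z jitter ±0.002 Th; uniform noise points at
a configurable density with trace id 0; nothing below the intensity floor
of 1 is emitted. Identical seeds give identical clouds, and every non-noise
point carries its ground truth, so import→build→query closures can be
asserted exactly.

Passing tests on these clouds show the engine's contracts hold
(conservation, determinism, budget containment, metadata liveness); they do
not show anything about centroiding quality, profile data, or real
instrument noise, which the generator does not model.

Navigation paths mutate a window by one of six moves — zoom in (scale
0.5–0.8), zoom out (1.25–2.0), pan ±RT, pan ±m/z (by 25–75 % of the window
edge) — clamped to the global bounds. Zooms keep the center and pans move
less than one window, so consecutive windows always overlap. The magnitudes
are this package's choice; any seeded choice preserving adjacency serves
the workload's purpose.

## Problem sizes and test scales

The suite exercises clouds from ~1.5 k to ~10⁵ points: full query/oracle
equivalence is property-checked at 10⁵ points over 200 random windows, the
memory-bound workload runs 25 paths × 100 queries against a ~25 k-point
store with a 2000-point cache budget, and structural axis-agnosticism uses
a 10⁵-point symmetric cloud. These sizes make every oracle (brute-force
scans, hand-simulated LRU traces, enumerated recursions) cheap to compute
exactly while still being two orders of magnitude above the tree's leaf
size, so all depth-dependent behaviour is engaged.

## Known limitations

- The point set is immutable after build: no incremental insert/delete or
  rebalance; only metadata mutates.
- One process, one store, single writer; the HTTP server handles requests
  sequentially.
- MS1 only; no mzXML/mz5/imzML readers, no mzML export, no drift time.
- The budgeted traversal's level-synchronous rule can overshoot the budget
  before resampling when summaries are dense in the window; memory use is
  bounded by the frontier's summary sizes, not by `n` alone.
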