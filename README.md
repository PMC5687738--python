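# mzvault

Axis-agnostic storage and retrieval for LC-MS point data, with
deterministic dynamic summarization, memory-bounded caching, and mutable
per-point segmentation metadata.

## The problem

A liquid-chromatography mass-spectrometry run is a cloud of millions of
three-dimensional points — mass-to-charge ratio (m/z, Th), retention time
(RT, s), and intensity. The standard raw formats (mzML and kin) are
arranged scan by scan along RT, so any question spanning an m/z interval
across many scans — exactly what viewers and feature-detection algorithms
ask — forces a traversal of the whole file. Tools that segment the data
into extracted-ion chromatograms (XICs) and isotopic envelopes additionally
need somewhere to *write* per-point membership as it is delineated, which
static formats cannot do.

`mzvault` stores each MS1 point individually in a spatial index that serves
rectangular m/z × RT window queries equally fast in either axis, returns a
bounded-cardinality *summary* of any window no matter how large, and keeps
segmentation assignments editable in real time. It is aimed at viewer
backends and data-processing pipelines in proteomics, lipidomics and
metabolomics.

## How it works

**Index.** Points are bulk-loaded into an R-tree-style hierarchy using
Sort-Tile-Recursive partitioning: each level sorts its data on one axis
(levels alternate RT ↔ m/z, starting with RT) and splits it into `b`
contiguous chunks of equal cardinality, recursing until a partition fits in
one leaf (`p` points). Alternating axes means neither m/z-major nor
RT-major queries are privileged.

**Summarization by weighted striding.** Every internal node keeps a sketch
of ≤ `p` real points chosen by a deterministic accumulation rule. For a
window of points with total intensity *I* and a requested sample of *k*
points, the accumulation threshold is *T = I / k*. Walking the point array
with a stride (default 42), intensities are accumulated; each time the
accumulator reaches *T* the current point is recruited and the excess
carries into the next iteration, wrapping around until *k* points are
recruited. High-intensity points are promoted, low-intensity points still
get in, every sampled point is a real measurement, and repeated queries
always receive the identical set.

**Queries.** A query is a window plus an optional point budget *n*. Without
a budget, every stored point in the window is returned. With one, the tree
is descended breadth-first until a level's in-window summary points can
supply *n*, then the gathered candidates are weighted-strided down to
exactly *n*.

**Storage.** Points live in an immutable fixed-record binary file, written
leaf-by-leaf so a leaf's partition is one contiguous byte range (one seek
per leaf); a point's id is its record index, so lookup is constant-time
offset arithmetic. Nodes, summaries and segmentation live in SQLite. A
point cache (LRU, hashmap id → point, 80 % of a user-set memory limit)
accelerates the adjacent-window access patterns of interactive navigation.

## Worked example

The summarizer's behaviour on a 10-point window with total intensity 30,
requesting 3 points at stride 1:

```python
from mzvault import MsPoint, compute_threshold, weighted_stride

window = [MsPoint(i, 500.0 + i, 60.0, 3.0) for i in range(10)]
print("threshold:", compute_threshold(window, 3))
print("selected indices:", [p.id for p in weighted_stride(window, 3, 1)])
```

```
threshold: 10.0
selected indices: [3, 6, 9]
```

The threshold is 30 / 3 = 10; accumulating 3 per point, the accumulator
reaches 10 at index 3 (12, carrying 2 forward), again at index 6, and at
index 9 — three real, evenly spread points from a uniform window.

End-to-end from the command line, with the bundled synthetic LC-MS
generator:

```sh
$ mzvault simulate --seed 1 --envelopes 8 --csv run.csv
wrote 27060 points to run.csv
$ mzvault convert run.csv store
indexed 27060 points into store
$ mzvault query store --mz 600:650 --rt 100:200 -n 5 --csv window.csv
wrote 5 points to window.csv
```

`window.csv` now holds 5 real points from the requested window, in the
5-column interchange schema `[m/z, RT, intensity, XIC ID, isotope
distribution ID]`:

```
mz,rt,intensity,xic_id,envelope_id
609.6991094245777,140.0,19.803198614166323,0,0
612.2212984601923,180.0,2.17857143252384,0,0
613.9049054892685,128.0,16.9647901616975,0,0
624.4565446987762,139.0,18.103931952271253,0,0
639.5802232815296,118.0,10.575739844562419,0,0
```

Repeating the query returns byte-identical rows. `mzvault serve store`
exposes the same queries over HTTP
(`GET /api/v1/points?mzmin=…&mzmax=…&rtmin=…&rtmax=…&n=…`) and
segmentation editing (`POST /api/v1/segmentation`), both JSON.

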