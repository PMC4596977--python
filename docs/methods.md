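# Methods

## Model and assumptions

The package segments a dermoscopy image by density-based clustering
(DBSCAN) of candidate pixels. The point set *D* is produced by
thresholding a single colour channel: a pixel is a *node* when its channel
value is ≤ `threshold`. Lesions are darker than surrounding skin and the
blue channel is empirically the most discriminative, so the defaults are
channel B, threshold 128. No other preprocessing (hair removal, contrast
enhancement, colour-space transforms) is performed; images are assumed
8-bit RGB (grayscale is promoted).

Distances are Manhattan, `d(p,q) = |Δx| + |Δy|`; the ε-neighbourhood is a
diamond of `ε² + (ε+1)²` pixels, clipped at the raster boundary. The
neighbourhood of a node contains the node itself (distance 0), so
`min_pts` counts the centre. Pixels are totally ordered by the row-major
id `pid = y·width + x`; every cluster is ultimately named by the smallest
pid among its members.

Definitions, for parameters ε ≥ 1 and MinPts ≥ 1:

* **dense (core)** node: `|N_ε| ≥ MinPts`;
* **cluster**: connected component of dense nodes under pairwise distance
  ≤ ε, together with its border nodes;
* **border** node: non-dense, within ε of a dense node;
* **noise**: non-dense with no dense node within ε.

A border node within ε of several clusters is attributed to the candidate
cluster with the smallest canonical id (minimum pid over dense members).
This replaces the order-dependent "first cluster wins" of textbook DBSCAN
and is what makes the serial and partitioned routes produce identical
bytes. Finally, clusters with fewer than MinPts members are demoted to
noise; this mirrors the cluster-count test of the node-classification
stage, and is applied identically in both routes (with minimum-id border
attribution a cluster can, rarely, retain fewer than MinPts members, so
demoting in only one route would break their equivalence).

## Serial scanner

`dbscan_serial` visits nodes in ascending pid order. Neighbourhood counts
are precomputed with a diamond-footprint correlation; a dense unclustered
node seeds a breadth-first expansion in which every node within ε of a
dense member joins and only dense members expand further (nodes
provisionally passed over as sparse are re-promoted to border when an
expansion reaches them). Border nodes are then re-attributed by the
minimum-canonical-id rule, small clusters demoted, labels canonicalized to
minimum member pid.

## Partitioned pipeline

**Shingled partitioning.** Core rectangles of `core_width × core_height`
(default 256×256; partition size is a throughput knob, not a result knob)
tile the image exactly; each partition's working view extends `2ε+1`
pixels past its core to the right and bottom, clipped at the image edge.
Consequently every pixel has its complete ε-neighbourhood inside at least
one view: the partition whose core contains the point ε up and ε left of
it (clamped at the raster edge) reaches at least ε past the pixel on the
right and bottom. The argument holds for any core size ≥ 1, and the
equivalence tests exercise cores both larger and smaller than ε.

**Label negotiation.** Within a partition every node starts with C = its
own global pid. One *scan* is a Jacobi sweep: each node with at least one
locally dense ε-neighbour adopts the minimum C among those dense
neighbours (a dense node sees itself, so its own C participates); other
nodes are unchanged. Reads always target the previous sweep's state, so a
scan is deterministic under any execution schedule. The loop stops when a
scan changes nothing; convergence is detected by the label checksum
(sum of C) *and* elementwise equality, since a checksum alone can collide
across distinct labelings. Restricting the minimum to *dense* neighbours
is deliberate: letting any neighbour's C in would propagate labels through
border nodes and merge two clusters that merely share a border node,
which the serial algorithm never does.

Termination: dense labels are pointwise non-increasing and bounded below
by each region's minimum pid. On a path-shaped cluster of k pixels a label
travels up to ε pixels per scan, giving roughly `ceil(k/ε)` scans; the
reported iteration count includes the final confirming scan, so a
one-pixel-wide serpentine of L pixels at ε = 1 takes exactly L scans —
one per pixel, the worst case.

**Merging.** A pixel is *globally dense* when any partition saw it dense
(its full-view partition always judges correctly; truncated views can
only undercount). For every globally dense pixel, all cluster ids it
received across partitions are unified with union-find whose class
representative is the smallest id; the closure is transitive, and the
result is independent of merge order. Border pixels are attributed only
*after* unification, on the merged labeling, to the adjacent cluster with
the smallest canonical id — a partition-local minimum would compare
pre-merge ids whose numeric order can disagree with the canonical order
(this is observable as rare one-pixel discrepancies if done locally).
Unification is deliberately *not* performed on shared border pixels, for
the same reason the scan restricts to dense neighbours. Demotion and
canonicalization then finish exactly as in the serial route.

The equivalence argument, informally: local density ≤ global density, so
local links are a subset of true links and no over-merge can occur; every
true core-core link is witnessed in the full-view partition of one
endpoint, whose labels reach the other endpoint either directly or via
that endpoint's own observations, so union-find recovers every component;
border and noise classification coincide because any dense neighbour of a
node is locally dense in its own full-view partition, where the node is
observed. The oracle-equivalence sweep in the tests checks the claim
end-to-end.

## Parameters

| name | default | meaning |
| --- | --- | --- |
| `eps` | 3 px | Manhattan neighbourhood radius |
| `min_pts` | 4 | density floor, centre pixel counted |
| `channel`, `threshold` | B, 128 | node = channel value ≤ threshold |
| `core_width × core_height` | 256×256 | partition core; affects speed only |
| `workers` | 1 | partition-processing threads; never affects output |

ε = 3 / MinPts = 4 is the standard operating point for density-based
lesion border detection on real dermoscopy imagery. The threshold of 128
(mid-scale) is the package's own choice and should be tuned per
acquisition setup.

## Synthetic data

The generators are first-class, deterministic functions of a seeded spec:

* `random_mask` — i.i.d. Bernoulli rasters for equivalence sweeps (sizes
  32–128 px, densities 0.2–0.7 in the shipped study conditions).
* `lesion_blob` — one dark irregular lesion: a radial bump plus smoothed
  Gaussian noise is thresholded at the 75th percentile, opened with a 3×3
  cross, reduced to its largest 4-connected component and hole-filled.
  The opening guarantees every lesion pixel keeps ≥ 5 nodes within ε = 1,
  hence density at the default parameters. Salt pixels are kept ≥ 5
  Manhattan pixels from the lesion and each other, so each is an isolated
  node for ε ≤ 4. Skin/lesion blue values are painted strictly above/below
  the 128 threshold, so thresholding recovers lesion ∪ salt exactly.
* `serpentine_path` — a 1-px boustrophedon of exactly L pixels starting at
  pid 0; non-consecutive pixels are ≥ 2 apart, so at ε = 1 labels can only
  crawl the path. The coil width defaults to `max(2, round(sqrt(L)))`, a
  near-square winding like the canonical worst-case figure.
* `split_cluster` — a full-span two-pixel-thick plus sign with seeded
  bumps: one connected cluster crossing every partition boundary, the
  adversarial merge fixture.

What the generators do *not* model: hair and ruler artifacts, specular
reflections, smooth lesion-to-skin intensity gradients, colour
calibration. Passing tests therefore demonstrate the correctness of the
clustering, merging, classification and scoring machinery — not clinical
segmentation accuracy on real dermoscopy images, whose reference values
require the original image set and manual borders.

## Numerical and design choices

* Labels are int64; +∞ is the sentinel `2**62`, above any pid.
* Noise is −1, non-node −2; both are distinct from every pid.
* Ties everywhere resolve toward the smaller id (minimum pid canonical
  ids, min-root union-find, smaller-id tie-break for the largest cluster).
* Neighbourhood counts and minimum scans use `scipy.ndimage`
  correlate/minimum_filter with diamond footprints, zero-padded (+∞ for
  minima) outside the raster.
* The lap width override in `create_partitions` exists only to demonstrate
  (negatively) that 2ε+1 is required; a narrower lap provably breaks
  serial equivalence and a regression test keeps that so.
* The empty manual mask is rejected in evaluation (border error
  undefined); empty-auto precision is NaN by convention.
* Label images are serialized as RGBA PNGs with the int32 label packed
  little-endian per pixel, since PNG lacks signed/32-bit grayscale.
* CLI exit codes: 0 success, 1 configuration error, 2 data error.
  Argument-parsing errors raised by click itself exit 2 per click
  convention.

## Problem sizes

The shipped test suite and acceptance script use 32–128 px masks, 16×16
or 64×64 partition cores, 10–100-case sweeps and ten 128×128 lesions —
sizes chosen so the whole suite runs in seconds while still exercising
multi-partition grids, seam-spanning clusters and every parameter
combination of the study conditions.

## Known limitations

* Thresholding is the only segmentation front-end; images whose lesion is
  not separable on one channel need external preprocessing.
* The evaluation operates on filled region masks, not on one-pixel
  contours; contour-based variants of precision/recall are out of scope.
* At the default ε = 3 / MinPts = 4 a solid lesion has no border-class
  pixels at all (even rim pixels are dense); visible border rings arise on
  speckled masks or stricter MinPts. The lesion *region* mask is
  unaffected.
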