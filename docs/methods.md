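# Methods

## Problem and model

An intra-oral scan (IOS) is a triangle mesh of one dental arch. An upstream
detector produces N tooth instances, each summarized by a point sample, a
binary tooth/gingiva mask, an axis-aligned bounding box and a center of mass
(COM, the unweighted mean of the tooth-class points). `archlabel` assigns
each instance one of the C = 32 permanent-dentition FDI codes via a binary
assignment matrix E ∈ {0,1}^(N×C) with row sums ≤ 1 (a detection carries at
most one code; a code may stay unused — missing teeth are the norm, not the
exception).

Exhaustive minimization over all assignments is combinatorially infeasible
at scan scale, so the assignment is refined through three nested searches,
each optimal within its own neighborhood:

* **Stage 1 (greedy, objective f₁ = f₁₁ + λ₁₂f₁₂ + λ₁₃f₁₃).** Detections are
  visited in increasing COM_x and given the free code of their own jaw with
  the lowest arch index; a detection stays unassigned when every assignment
  would raise f₁ (e.g. its jaw's 16 codes are exhausted). The jaw of a
  detection is its side of the *watershed* — the z component of the
  scan-wide mean COM — unless the scan carries a single-jaw hint.
  λ₁₂ = 0.1 and λ₁₃ = 0.01 order the penalties: one duplicate code (1.0)
  outweighs ten wrong-jaw assignments (0.1 each), which outweigh ten
  unassigned detections (0.01 each).
* **Stage 2 (permutation sort, objective f₂).** f₂ counts ordered same-jaw
  pairs whose left-right (x) order contradicts their code order along the
  arch; each unordered inversion therefore contributes 2. Sorting each
  jaw's detections by COM_x and handing out the used codes in arch order is
  the exact minimizer (0 whenever x values are distinct), so no search is
  needed.
* **Stage 3 (slot placement, objective f₃).** The sorted sequence of k ≤ 16
  detections is injected order-preservingly into the jaw's 16 arch slots;
  all C(16,k) ≤ 12,870 placements are enumerated exactly (vectorized over
  placements; no pruning heuristics are necessary at this size) and the
  placement minimizing the squared discrepancy between observed pairwise
  COM distances and the distance prior D wins. Ties go to the
  lexicographically smallest slot tuple, which biases toward mesial slots
  and makes the result deterministic.

The distance prior D is a 32×32 symmetric matrix of mean same-jaw
inter-tooth COM distances (mm) with zero diagonal, estimated as the plain
arithmetic mean over all labeled scans containing both codes
(`estimate_distance_prior`), with per-entry support counts. Pairs never
co-observed are flagged missing (NaN in memory, empty cell in CSV), and f₃
skips them with a warning rather than inventing a distance (a `strict`
switch raises instead). Cross-jaw entries are never used.

## Design choices where the design was open

* **Code order.** Raw FDI numerals are not monotone along the arch (the
  first quadrant counts 18→11 toward the midline, the second 21→28 away
  from it), so f₂/f₃ compare a per-jaw *arch index* 0–15; this is the only
  ordering under which "code order follows x order" is geometrically
  coherent across the midline. `LabelingConfig(order_by_arch_index=False)`
  restores the raw-numeral comparison for fidelity experiments.
* **f₃ exponent.** The squared difference is used: it is non-negative,
  smooth, and punishes one large mismatch more than several small ones,
  which is the behavior the slot search needs to reject off-by-one-slot
  placements. `f3_metric="abs"` is available.
* **f₃ covers both jaws** symmetrically.
* **Jaw conventions.** Upper-jaw teeth are expected at COM_z ≥ watershed;
  `upper_above_watershed=False` flips the convention for scans with an
  inverted axis. For single-jaw scans the watershed of the scan's own COMs
  is meaningless, so a `jaw_hint` on the scene overrides it both in f₁₂ and
  in the search spaces.
* **Detection matching for evaluation** (unspecified upstream): optimal
  one-to-one assignment maximizing total bounding-box IoU
  (`scipy.optimize.linear_sum_assignment`), pairs below a 0.5 IoU threshold
  discarded — standard object-detection practice, configurable. Table-style
  per-FDI detection metrics are label-aware by default; a label-agnostic
  mode isolates localization quality.
* **Undefined metrics** (zero denominators) are reported as NaN, never 0,
  so per-code means are not dragged down by codes absent from a scan.
* **Mesh annotations** travel in a JSON sidecar with the mesh's basename
  (`{"face_labels": [...], "fdi_map": {...}}`) since no mesh format carries
  per-face instance labels. "Uniform" downsampling is uniform random vertex
  subsampling without replacement under an explicit seed; geometric
  decimation is deliberately not implied. All coordinates are millimeters.
* **Box sampling** draws without replacement when the expanded box holds at
  least the requested 8192 candidates, with replacement otherwise, keeping
  the fixed-size output contract. The default box expansion factor is 1.2
  per axis — enough to include cervical margin, not enough for neighboring
  crowns to dominate.

## The synthetic generator

The generator stands in for a private scan corpus and trained detector and
segmentation networks; its defaults are the study conditions of the test
suite and acceptance script.

* **Arch geometry.** A parabolic curve in the occlusal plane (width/depth
  aspect 55/47 mm upper, 52/44 mm lower) uniformly scaled so its arc length
  equals the summed mesiodistal crown widths; slots sit at each crown's
  arc-length midpoint, with a mild quadratic curve-of-Spee z term (≤ 1.2
  mm). Crown extents are standard adult values (e.g. upper central incisor
  8.5 mm mesiodistal, first molars 10–11 mm).
* **Teeth are box-shaped point clusters** (default 200 tooth points plus 50
  cervical gingiva context points per tooth): the labeling algorithm
  consumes only COMs, masks and boxes, so realistic crown morphology would
  add nothing the tests could detect. A toy triangulated mesh
  (`scene_to_mesh`) exists for exercising the mesh I/O path.
* **Ground-truth COMs are the slot centers exactly**, so noiseless runs are
  analytically checkable and `template_prior` (slot pairwise distances)
  equals the estimated prior on noiseless scenes entrywise.
* **Detector noise** (all default 0): per-tooth miss rate; per-axis
  Gaussian COM jitter (points and box move rigidly with the COM); mask
  flips concentrated at the points farthest from the cluster center,
  emulating cervical segmentation errors; spurious detections at a per-slot
  rate, placed inside the arch's COM span. Congenitally missing teeth are
  drawn with a preferential weighting (third molars 8×, second premolars
  3×, first premolars 2×) mirroring where real failures concentrate.
* **What passing does not show.** The simulator has no crown morphology, no
  scanner noise, no malocclusion beyond COM jitter, and independent
  per-tooth errors; perfect recovery here demonstrates the correctness of
  the combinatorial pipeline under positional regularity, not clinical
  performance on real scans.

## Numerical notes and problem sizes

* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; generation and detector simulation use separate child streams of
  the scene seed, so the same truth can be degraded reproducibly.
* Stage-1 ties break toward the detection's own jaw and the lowest arch
  index; stage-2 x ties break by detection index; stage-3 cost ties take
  the first (lexicographically smallest) placement. The final label map is
  invariant to the input order of detections whenever COM x values are
  distinct.
* The test suite checks the staged search against brute-force enumeration
  on scenes of ≤ 6 detections per jaw (the full factorial oracle is guarded
  at 8 per jaw, beyond which enumeration is refused); pipeline-closure
  checks use 100 noiseless and 200 jittered scenes; the acceptance script
  uses 200 prior-fitting scenes and a 100-scene noisy test set. These sizes
  give stable Monte-Carlo estimates while keeping a full run in seconds.
* The mean-of-distances prior estimator is biased upward by ≈ 2σ²/d for COM
  jitter σ on a true distance d (≈ 0.03 mm at σ = 0.3, d = 6 mm) — the
  expectation of a noisy norm exceeds the noiseless norm. This is
  irrelevant for labeling, which uses the prior consistently with the data
  that produced it, but it is visible in recovery experiments whose
  Monte-Carlo standard error approaches that size; the seeded recovery test
  operates where the combined deviation stays within its three-standard-
  error band.

## Known limitations

* Axis-aligned boxes only; strongly rotated scans should be pre-aligned to
  the occlusal plane.
* The 32 permanent-dentition codes only: no primary dentition (5x–8x), no
  supernumerary teeth.
* Stage 3 assumes the x-order of COMs reflects arch order; a severely
  ectopic (e.g. palatally displaced) tooth violates that premise and will
  shift its neighbors' slots.
* Per-jaw scenes with more than 16 detections keep the first 16 in arch
  order and leave the surplus unassigned with a warning.
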