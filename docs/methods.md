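# Methods

This note documents the models, conventions and design choices behind
`cognimage`, in the spirit of a package methods appendix. It states nothing
the test suite or `scripts/acceptance.py` does not itself compute.

## Knowledge-base dialect

A knowledge base is a directory: a `node_list` file (one node per line,
defining tie-break precedence for the scheduler) and one attribute file per
node. The grammar is deliberately minimal:

* one attribute per line; whitespace-separated tokens; the first token is the
  attribute name; `#` starts a comment;
* scalars default to millimetres (or native image units); a `cm` suffix on a
  numeric token is converted to mm at parse time, so `5cm 10cm` and `50 100`
  express the same range;
* fuzzy membership functions are written as alternating
  value/confidence pairs on one line (`XSectionAreaFuzzy 100 0.0 500 1.0`);
* a `{bit_start, bit_end, lower, upper}` group immediately after a numeric
  token exposes that parameter for optimization.

Attributes are validated against a vocabulary shipped as data
(`data/vocabulary.yaml`), which fixes each attribute's parameter arity and
category; categories map one-to-one onto agent families. Users may pass their
own vocabulary file to extend the language. Multi-line attributes and quoting
are not supported; the dialect is single-line by construction.
`parse ∘ write` is the identity on valid networks (tested structurally).

## Fuzzy expectations

A fuzzy function is piecewise linear between vertices with flat extrapolation
outside, always in [0, 1]. Printed plausibility ranges [a, b] ("typically
50–100 mm") become trapezoids with full confidence on [a, b] and linear
shoulders of width 0.2·(b−a) per side; tolerances t ("within 3 cm") become
flat-inside functions falling to 0 over a shoulder of 0.4·t. The shoulder
fraction (0.2) is a single package-wide constant: large enough that borderline
anatomy keeps a nonzero score, small enough that implausible candidates hit
exactly zero. Search-area bands use the *support* of the same fuzzy function,
so a search area never clips a candidate that would have scored above zero.

## Coordinate and orientation conventions

Rasters are indexed `(z, y, x)` in 3D and `(y, x)` in 2D, 0-based; physical
position is index × spacing in mm. "Above" means smaller z (3D) or smaller y
(2D). "Patient right" is smaller x under the default `radiological`
orientation tag stored on the blackboard; `neurological` flips the lateral
sign. These conventions are a package decision — relational knowledge is only
meaningful relative to a declared axis convention, so the convention is
explicit and configurable rather than implied.

## Candidate generation and scoring

* Thresholding uses inclusive windows; connected components use full
  connectivity (26 in 3D, 8 in 2D); the minimum candidate size defaults to
  1 voxel. These are the most permissive defaults: the philosophy is that the
  reasoning layer, not the segmenter, does the rejecting.
* Morphological radii are physical (mm) and converted per axis, so
  structuring elements are ellipsoids under anisotropic spacing. Closing is
  computed on a padded array so regions touching the image border are not
  clipped. Set relations (open ⊆ input ⊆ close, fill) are property-tested.
* The aggregate candidate score is the *product* of per-expectation
  memberships (not the minimum): several weak matches should be penalized
  more than one, and the product keeps score differences informative for
  diagnostics. `NotPartOf` contributes 1 − overlap; `PartOf`/`InsideOf`
  contribute the overlap fraction itself. Expectations whose reference object
  was not recognized contribute 1 (non-informative): a missing object must
  not block recognition of its dependents.
* Selection is an argmax over candidates with score strictly above the
  acceptance threshold (default 0; per-node override via
  `AcceptanceThreshold`). Ties break toward the larger region, then the first
  found. If nothing qualifies the element is `not_found` and outputs nothing —
  rejecting is a feature, not a failure.

## Control loop

Exactly one agent activates per iteration; scores live in [0, 1] with fixed
family bases (scheduling 0.9, then search-area 0.8 → segmentation 0.7 →
scoring 0.6 → selection 0.5 for the focused element). The mechanism —
compute all activation scores, activate the highest, repeat until all are
zero — is the contract; the numeric scale itself is arbitrary and any fixed
total order reproduces the same behavior. The scheduler picks
the pending element with the highest fraction of computable requirements,
ties broken by `node_list` order; a terminal prerequisite of *any* status
(recognized, not found, unreliable) counts as resolved, which is what lets
the ordering adapt without exception rules. A hard cap of 100 activations per
node guards against non-termination and names the stuck element.

Landmark extraction: `InferiorTipOf`/`SuperiorTipOf` take the extreme
occupied level of the reference mask; `BifurcationOf` scans levels top-down
for the first in-plane split into ≥ 2 components that *persists for 3
consecutive levels* — transient single-level splits are segmentation
artifacts (e.g. a thin foreign object crossing the region), not anatomy.

Consistency checks compare estimate centroids; within tolerance (default
10 mm, a KB parameter) the fused estimate is the midpoint of points or the
intersection of regions, otherwise the fused element is `unreliable` and
decisions depending on it become indeterminate rather than wrong. The
path-containment decision requires 90% of path voxels inside the reference
region by default — the knowledge is crisp ("the path must be within"), the
10% slack absorbs raster discretization at mask boundaries.

## Chromosome encoding

Bit positions in `{a, b, lo, hi}` are 0-based inclusive indices into the
chromosome. Ordinal-vs-index is genuinely ambiguous in prose descriptions;
0-based was chosen and documented, and only absolute gene placement — never a
decoded value — depends on the choice. Gene values are equidistant grid
points computed as exact rationals then rendered to float, monotone in the
unsigned bit index. Unused bits between genes are permitted and ignored.

## Genetic algorithm

Defaults: population 30, 10 generations, elitism 2, tournament size 2,
single-point crossover with probability 0.8, per-bit mutation 1/L. Selection
scheme and rates are standard textbook settings exposed in `GAConfig`; no
compatibility with any other implementation is claimed. Elitism makes
best-so-far fitness non-decreasing (asserted per run). Fitness of a think run
that fails outright is 0, not an exception — optimization must tolerate
degenerate parameter sets. Fitness evaluations are memoized per chromosome
within a run (they are deterministic), and the optimizer/distributor split
keeps evaluation pluggable; the reference distributor is sequential, retries
a failed job once, then records fitness 0. All randomness flows from a single
seed; fixed seeds reproduce trajectories byte-exactly.

## Phantoms: what they emulate, and what they do not

The abdominal phantom (default 32×96×112 voxels at 3×2.5×2.5 mm) encodes the
anatomy the kidney knowledge base describes: a spine cylinder at bone
intensity (1200), two kidney ellipsoids at contrast-enhanced soft-tissue
intensity (400) placed 70 mm laterally from the spine (inside the expected
50–100 mm band) at the same craniocaudal level, a stray distractor blob at
kidney intensity placed 125 mm out (outside the plausible band), and Gaussian
noise (σ = 20 HU). For parameter-recovery studies the kidneys can carry faint
concentric shells (scales 1.15/1.3 at intensities 250/150), which plants a
unique optimal window low bound at 300 on the decoded grid: lower thresholds
swallow the shells, higher ones erode the kidney.

The tube phantom (256×192 pixels at 0.5 mm) has a dark trachea column that
bifurcates at the carina (y = 100 mm) into two diverging branches, and a
bright 1 mm tube line ending a configurable distance above the carina
(default 50 mm, mid safe-zone). The tube occludes the air column, which is
why the knowledge base routes the bifurcation landmark through a
morphologically closed trachea node.

Phantoms are bit-deterministic given spec + seed. They emulate geometry and
intensity contrast only: no organ texture, partial-volume effects, bias
fields, pathology, or patient variability. Passing the phantom suites
demonstrates that the *reasoning machinery* behaves as specified (rejection
of implausible candidates, explained decisions, recoverable parameters); it
does not demonstrate clinical segmentation accuracy, which depends on the
segmenters plugged into the predictor hooks.

## Study scales used by the tests and the acceptance script

Stray-region rejection is measured over 200 seeded phantoms with jittered
geometry (kidney offset 55–85 mm, level jitter ±10 mm, stray offset
118–128 mm); GA parameter recovery over 20 seeded runs at population 30 and
10 generations; scheduler oracle equivalence over 100 random DAGs. These
sizes make the checks statistically meaningful at desk scale while keeping a
full run under a minute.

## Out of scope / limitations

* DNN training is out of scope: learned segmenters attach through the
  external-predictor hook contract, and bias-field correction is likewise a
  hook (identity by default).
* Distribution backends beyond the sequential reference implementation
  (cluster schedulers, workflow engines) are contract-only.
* One candidate is selected per object; merging several candidates into one
  object is not supported.
* Blackboard output files are a JSON dialect defined by this package, with
  masks as NIfTI (3D) or PNG (2D); no compatibility with other tools'
  blackboard formats is claimed.
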