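# Methods

`sootylung` implements a five-stage pipeline for nodule analysis on 2-D
chest-CT-like slices: lobe segmentation by automatic single-seeded region
growing, border-concavity repair, adaptive local-binary-pattern texture
features, sooty-tern-optimization feature selection, and a CNN-GRU
classifier. A synthetic phantom generator provides ground-truthed inputs so
every stage is testable without external data. This note records the models,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic validation does and does not show.

## Synthetic phantoms

Each phantom emulates the gross geometry of an axial chest-CT slice on the
8-bit intensity scale: a bright soft-tissue body ellipse (base intensity
drawn uniformly from [120, 200]), two mirrored dark air-filled lobe ellipses
(base from [5, 35], always below the 40-intensity air test), optional bright
nodules and vessels (base from [90, 180]), and additive Gaussian noise
(default sd 2 intensity units) applied after rasterization and clipped to
[0, 255]. One base value is drawn per structure, so each region is
homogeneous up to noise — the regime in which a fixed growth threshold
separates air from tissue cleanly.

Ground-truth lobe masks record the *air* region of each lobe: the lobe
ellipse minus any pixels overwritten by bright structures. That is the
region an air-threshold criterion can recover, and it makes segmentation
scores meaningful for every nodule kind.

Nodule kinds:

- **isolated** — a disc strictly interior to the lobe (≥ 2 px margin);
- **juxtapleural** — centred on the lobe boundary, carving a bite of depth
  ≈ radius into the dark region. Placement is restricted to the lateral
  (chest-wall) sector of the lobe (parametric angle ±60° about the lateral
  axis), where the pleural boundary is flat — both the anatomically typical
  attachment site and the regime in which concavity repair is well-posed
  (bites at the strongly curved lobe poles lose a chord-to-arc crescent that
  no mask-based repair can recover; see below);
- **juxtavascular** — attached to a bright vessel strip that enters the lobe
  from its medial border and terminates inside it. The vessel does not cross
  the lobe completely: a full crossing would disconnect the air region, and
  a single-seed growth can only ever reach one connected component.

Class semantics are a documented convention, not a claim about real
morphology: *benign* is a small smooth disc (radius from the lower 40 % of
the 4–12 px range), *malignant* a larger disc (upper 40 %) with 3–5
satellite bumps giving a lobulated margin. For juxtapleural malignant
nodules the bumps face the lobe interior — real pleura-attached nodules are
flattened against the wall — which also keeps the carved bite recoverable.
Per-sample seeds derive from the master seed by a counter
(`numpy.random.SeedSequence([master, index])`), so datasets reproduce
bit-identically and generation is parallel-safe.

What the phantoms do **not** emulate: Hounsfield calibration, parenchymal
texture, vascular trees, the mediastinum, partial-volume effects, or 3-D
continuity. Passing tests therefore demonstrate algorithmic correctness
under the stated geometry and noise model, not clinical performance.

## Lobe segmentation (seeded region growing)

Each image half is segmented independently (midline split; for odd widths
the left half is the narrower). Seed choice: the central pixel is accepted
if it is dark (< `air_threshold`, default 40, strict) and a strict majority
of its 8-neighbours are dark; otherwise candidates expand outward over
concentric square rings, each scanned clockwise from its top-left corner,
and the first pixel passing both tests wins. The grown region is the
connected set of pixels whose intensity differs from the **seed** intensity
by less than `grow_threshold` (default 25, strict) — the comparison anchor
is the static seed intensity, not a running mean, which keeps the operation
deterministic and monotone in the threshold. Implementation: a vectorized
candidate mask plus a connected-component labelling; an independent BFS
flood fill backs it in the tests.

`grow_threshold` is the one load-bearing free parameter: it must exceed the
within-region spread (noise sd of a few units) and stay below the ≥ 55
intensity gap between air and any bright structure. The default 25 sits
comfortably in that window; it is exposed and tunable for other data.

Otsu thresholding (between-class variance over the 256-bin histogram, ties
to the smallest maximizer) is provided as an optional global alternative and
pre-check; the default pipeline does not use it.

## Border-concavity repair

An air-threshold lobe loses pleura- and vessel-attached nodules: being
soft-tissue bright, they are carved out of the dark region, leaving a
concave notch. The repair chain: pad by `line_width + 2` on all four sides;
remove small spurious objects by **opening-by-reconstruction** (erosion with
a radius-`opening_radius` disc followed by morphological reconstruction) —
chosen over a plain opening because it erases sub-footprint objects without
blunting the notch-mouth corners, which a plain opening truncates by the
footprint radius, systematically clipping recovered bites; fill holes;
normalize with a 3×3 median filter; keep the largest 8-connected component;
Moore-trace its outer boundary (clockwise from the topmost-leftmost pixel);
take the convex hull of the boundary; merge: walk the traced boundary and
replace a run between consecutive hull vertices by the straight hull chord
exactly when the run's maximum chord-to-boundary depth exceeds
`opening_radius` (deep concavity), otherwise keep the trace (shallow);
rasterize the merged contour as a closed Bresenham polyline dilated to
stroke width `n = line_width ≥ 4`; run Canny edge detection on the stroke;
among closed edge loops enclosing at least half the lobe area, select the
smallest (the inner ring); fill its interior; complete the filled region
back to the contour centerline (the inner Canny ring sits ~n/2 inside it);
across **bridged** chord segments only, include the full stroke width —
the true border across a closed concavity is uncertain by at least the
chord-to-arc sagitta, and the stroke width quantifies exactly that
uncertainty — and finally remove the padding.

Two geometric facts shape the above. First, any convexity-based repair is
bounded by the hull: the circular segment between a bridge chord and the
original arc is unrecoverable from the mask alone (for a 90° sector wedge it
is a scale-invariant 36 % of the wedge). Keeping bites on the flat pleural
sector and including the bridge stroke keeps this loss below a few pixels.
Second, the repaired border must sit on the contour centerline, not n/2
inside it, or a convex region would shrink on every pass; the centerline
completion makes convex inputs near-fixed-points (Dice ≥ 0.99 on discs) and
the operation approximately idempotent.

Canny thresholds default to 0.4/0.8 × the Otsu threshold of the gradient
magnitude. `opening_radius` (default 3) doubles as the shallow/deep
concavity cut: bites shallower than it are left to the trace, consistent
with the smallest nodule radius (4 px) the phantoms generate.

## Adaptive LBP features

At every masked interior pixel, `P = 8` neighbours are sampled on a circle
of radius `R = 1` (bilinear interpolation, indexed counter-clockwise from
east). With differences `d_p = g_p − g_c` and their population standard
deviation σ: the **magnitude code** sets bit p iff `d_p ≥ σ` — an adaptive
threshold that scales with local contrast; the **direction code** sets one
bit per opposite-neighbour axis (0°, 45°, 90°, 135°) iff the absolute
difference across the axis exceeds σ. On a perfectly flat patch σ = 0 and
all `d_p = 0`, so all magnitude bits are set: constant regions map to
`2^P − 1`, deliberately distinct from edge codes. Differences below 1e-6 are
treated as exact zeros so interpolation noise cannot corrupt the σ = 0 tie
rule. Both codes depend only on differences, making the descriptor invariant
under global gray shifts. The per-image feature vector concatenates the two
normalized histograms (256 + 16 bins).

## Sooty tern optimization

The continuous minimizer follows the published equations exactly: per
iteration the movement coefficient decays linearly `MSA = Cfac − i·Cfac/T`
(Cfac = 2); each agent, in index order, draws `Ran` then the spiral angle
`a` from one seeded generator; the collision-avoided move is `MSA·P`, the
best-directed move `0.5·Ran·(P_best − P)`, their sum the gap `G`; the attack
position is `G · (x′ + y′ + z′) · P_best` element-wise, with spiral offsets
`x′ = r sin a`, `y′ = r cos a`, `z′ = r·a`, `r = u·e^{v·a}` (u = v = 1),
clamped to the search box. The global best updates only on strict
improvement, so the best-so-far history is non-increasing by construction
(asserted, not just tested). Note the multiplicative attack form draws new
positions toward scalings of the incumbent best; on the sphere benchmark
(optimum at the origin) it converges essentially exactly.

**Binary wrapper.** For feature-subset selection the multiplicative attack
cannot work: for any component where an agent agrees with the incumbent, the
update's sign equals the incumbent's (the spiral sum `r(sin a + cos a + a)`
is strictly positive on [0, 2π] for u = v = 1), so a selected feature can
never be deselected — masks ratchet toward all-ones. The wrapper therefore
keeps the algorithm's skeleton (population, linear MSA anneal, best-centred
attack, strict elitism) and realizes exploration as per-feature bit flips of
the incumbent with probability `0.5·MSA/Cfac`, floored at `1/n_features` so
refinement continues after the anneal. Positions are the bound values
realizing the bits under the sigmoid transfer (bit = 1 iff sigmoid > 0.5).

The wrapper objective is `(1 − CV accuracy of a 1-nearest-neighbour
classifier on the masked features) + alpha · |subset|/n_features`, with the
empty subset pinned to the worst value 2.0. The scorer precomputes
per-feature squared-difference matrices, so subsets are scored by a stack
sum and one argmin per fold — cheap enough for exhaustive enumeration up to
16 features, which the tests use as the ground-truth optimum. Deterministic
folds (round-robin within class) or leave-one-out are available.

**Identifiability of planted-feature recovery.** Recovering a planted
informative pair out of 16 features requires the penalty to dominate the
cross-validation resolution: with n samples, a noise feature can lift CV
accuracy by ~1/n by luck, so recovery is only well-posed when
`alpha/n_features > 1/n`. The bundled planted problem uses n = 120, a 3σ
class shift on the informative pair, leave-one-out CV and alpha = 0.3;
exhaustive enumeration confirms the planted pair is then (up to occasional
single-feature ties) the true optimum, so the experiment measures the
optimizer rather than CV overfitting. The pipeline default alpha remains
0.01 — a weak tie-breaker appropriate when features are many and n is
moderate.

## CNN-GRU classifier

Architecture (structural counts fixed): four valid-padding 3×3 stride-1
convolutions with ReLU — 128, 64, 64, 32 maps; the first takes 50×50×3 to
48×48 — 2×2 max-pooling after the first three, one dropout after the first
pooled block on the conv path; flatten (128 units); two 512-unit
fully-connected layers with heavy dropout; the 512-vector reshaped to an
(8, 64) sequence feeding a 512-unit GRU whose last hidden state passes to
the final softmax layer over three classes. The recurrent axis of a
flattened feature vector is a pure convention; (8, 64) is the package's
choice and is configurable. The GRU is the standard completion of the
reset/update gate equations (tanh candidate on the reset-gated hidden
state, convex update mix); the two gate equations are exposed as standalone
operations and verified against an explicit-loop oracle.

Dropout rates: the architecture's printed defaults are 0.3 (conv path) and
0.9 (first two FC layers); a single `drop_rate` override (the training
profile uses 0.25) replaces every dropout layer. Dropout appears once on
the conv path: stacking a dropout after every conv block leaves the
training signal below the SGD noise floor at the profile's ~60 total
updates, and the net cannot converge.

Training: plain stochastic gradient descent (momentum 0) on softmax
cross-entropy, learning rate 0.05, 15 epochs, batch 64. Two numerical
safeguards, applied identically everywhere: global gradient-norm clipping
at 2.0 (unclipped SGD at lr 0.05 oscillates on this model) and zero-centred
inputs (pixels scaled to [−0.5, 0.5]). The whole stack — weight
initialization, dropout masks, batch shuffling — draws from one seeded
generator in a pure-numpy engine (float32, im2col convolutions), so
training is bit-reproducible; there is no backend nondeterminism caveat.

**Classifier input.** The pipeline feeds 50×50 *candidate-nodule crops* at
native resolution: the largest bright connected component inside the
border-corrected lobes but outside the grown air region (nodule, possibly
with its vessel) is the candidate, and the crop is centred on its centroid;
slices with no candidate (normal) are cropped at the lobe-union centroid.
Candidate mining is unsupervised — no ground truth or label enters input
preparation. Whole-lobe crops and raw resized slices are available as
alternative modes; under the training profile above they are not learnable
(≈ 50 SGD updates cannot build position-invariant nodule detectors), which
is itself evidence that a candidate-patch pipeline is the right reading.

## Evaluation

Per-class metrics are one-vs-rest from the confusion matrix: precision,
recall, specificity and F-score in percent, the binary Matthews correlation
of the collapsed 2×2 table, and one-vs-rest accuracy; overall accuracy is
the trace over the total; averages are macro. Division by zero yields 0 with
a warning so reports stay total. The 70:30 split is stratified with
largest-remainder rounding; k-fold evaluation (default k = 5) uses
stratified folds and reports per-fold accuracy, recall, specificity, MCC
and their means. ROC pools benign and malignant as positive against normal
as negative; AUC is trapezoidal over the threshold sweep and equals the
rank-sum (Mann-Whitney) statistic, which the tests assert on tied data.

## Problem sizes and study conditions

The bundled experiments use: 50 mixed phantoms for segmentation recovery;
20 juxtapleural phantoms for border repair; 10 seeds each for the sphere
benchmark (pop 30, 200 iterations), the 8-feature exhaustive comparison
(60 samples) and planted recovery (120 samples, 16 features); and 300
balanced phantoms (70:30 split, 3 seeds) for end-to-end learnability at the
training profile above. Phantom defaults (256×256, noise sd 2, nodule radii
4–12 px) are fixed once in `PhantomSpec`.

## Known limitations

- The repair is 2-D and convexity-bounded; concavities that real anatomy
  shares with nodule bites (hilum, mediastinal recesses) would be bridged
  indiscriminately.
- The seeded growth assumes one connected air region per half-image and
  fails (by design, with a `NoAirRegion` error) on slices without air.
- The phantom class signal (size + margin) is far easier than real
  benign/malignant discrimination; held-out accuracy on phantoms says
  nothing about diagnostic accuracy on CT data.
- The continuous STOA attack equation is used as printed; its known origin
  bias means minimizers whose optimum is far from the origin converge
  slowly, and the binary adaptation described above is this package's own.
- DICOM support is single-frame, read-only, min-max rescaled to 8 bits.
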