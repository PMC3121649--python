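# Methods

This note documents the models and procedures implemented in `neuromorph`,
the parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Image model and enhancement

The input is a single-channel 2D raster of non-negative integers with a
declared maximum gray level `gmax` ∈ {255, 4095, 65535}; 12-bit data in
16-bit containers is recognized by its value range. All arithmetic clamps to
[0, gmax]; internal computation uses float64 and rounds once at the end of
each operator.

Enhancement classifies a pixel as background iff it is simultaneously

* **low-contrast**: `I − gauss(I, blur_sigma)` (clamped at 0) ≤ `lowc`, and
* **low-intensity**: `rolling_ball(I, ball_radius)` ≤ `lowi`,

and sets background to zero, leaving every other pixel bit-identical to the
input. The two branches both read the original image, not a chained result.

**Why AND, not OR.** Combining the two "low" masks with OR and treating the
union as background would delete dim-but-sharp neurites (low intensity,
high contrast) and flat-but-bright soma interiors (low contrast, high
intensity) — the two structure classes the method exists to keep. The AND
rule preserves both; under an inverted-mask convention the same rule can be
written as OR of the two masks followed by a multiply (De Morgan). This
polarity is asserted by tests: a 1-px line of amplitude 30 survives
`lowi = 40`, and a flat disk interior survives `lowc` far below its
amplitude.

Consequences used downstream: after enhancement any positive pixel is
signal, so the binarization thresholds `th1` (soma) and `th2` (neurites)
are fixed at 1.

## Morphological quantification

* **Somata**: grayscale opening (disk, radius `nwidth`) removes everything
  thinner than ~2·`nwidth`+1 px — neurites and debris — then threshold
  [1, gmax] and 8-connected particle analysis. If `nwidth` is set to the
  width of the thickest neurite, somata are the only survivors.
* **Neurites**: binarize at [1, gmax]; remove components with area <
  `psize`; thin to a 1-px skeleton; subtract the soma mask; length is the
  raw foreground pixel count. No diagonal √2 correction is applied — length
  is a pixel count by definition here; physical units are an output-side
  conversion when a pixel size is supplied.
* **Attachment points**: dilate the soma mask by one pixel (count 1),
  intersect with the (still soma-crossing) skeleton, strip the tips of the
  resulting 1-px "stem" fragments with a count-7 erosion, and keep stripped
  tips that are outside the soma proper. Counting is by 8-connected
  component, so a 2-px tip cluster counts once.
* **Ending points**: count-7 erosion residue of the soma-free skeleton,
  minus the dilated soma (this discards the artificial cut ends where the
  skeleton was severed at the soma border). A closed loop has no pixel with
  7 background neighbors and yields no ending point, by construction.

Count-based erosion/dilation semantics: per iteration, a pixel flips iff at
least `count` of its 8 neighbors are of the opposite phase; out-of-image
neighbors are background. Erosion and dilation are exact duals away from
the border.

Skeleton spurs: subtracting the soma from the skeleton of a soma-plus-
neurite blob can leave short spurs at the boundary. These are accepted —
they are bounded by the tip-suppression against the dilated soma and are
covered by the documented tolerances; no spur pruning is applied.

## Scoring detections

Against a manual count `Ma` with detected count `Ne`, true positives `TP`,
false positives `FP` and false negatives `FN`:

* accuracy = 100·TP/Ma (undefined when Ma = 0),
* error rate = 100·(FP+FN)/Ne (undefined when Ne = 0).

The error rate deliberately includes false negatives in the numerator while
normalizing by the detected count: this is the convention that reproduces
the published per-image scores this scorer is validated against, even
though prose descriptions of such error rates often mention only the false
positives. Averages over images are computed from the unrounded per-image
values.

`match_points` makes the TP/FP/FN assignment algorithmic: candidate
detected-truth pairs within a match radius are accepted greedily in order
of increasing distance, each point used at most once. On well-separated
point sets this equals the exhaustive optimal assignment (tested); in
ambiguous clusters greedy may differ from optimal by design simplicity.

## Dose-response fitting

Responses are fit with the four-parameter logistic
`y = bottom + (top − bottom) / (1 + (c/ic50)^hill)` by unweighted least
squares in log-concentration space (Levenberg–Marquardt), with the
deterministic initialization top = max response, bottom = min response,
ic50 = geometric midpoint of the positive doses, hill = 1. Zero-dose
controls are excluded from the log-domain fit but inform the top-plateau
initialization. A constant response is rejected as degenerate (bottom =
top); non-convergence raises an error carrying the initialization and the
initial residual.

IC50 from a five-dose grid is intrinsically sensitive: a few-percent
perturbation of a single mid-curve response can move the estimate by tens
of percent. The recovery contract is therefore stated for the *median* of
the recovered IC50 over repeated noisy simulations (a bias measure), which
is stable at the percent level, rather than for each individual noisy fit.

## Synthetic scenes and ground truth

The generator emulates low-magnification (~10x) images of neurite-stained
neurons on a 384×384 8-bit field: flat-topped soma disks (radius 9–14 px,
amplitude 180) with a narrow Gaussian edge (σ = 1.2 px); 2–4 neurites per
soma drawn as smooth random walks (step 2.5 px, heading jitter σ = 0.10
rad) of width 1–3 px, with per-neurite peak amplitude 80–160 tapering to
55% at the tip and optional single-level branching (p = 0.25); a planar
illumination gradient (amplitude 20 gray levels); additive Gaussian noise
(σ = 5); and 3–12-px bright debris blobs. Amplitudes were chosen so soma
interiors exercise the intensity branch of the enhancement and dim neurite
tips exercise the contrast branch; debris is always smaller than the
`psize` used in analysis so the particle remover's effect is observable.

Ground truth is recorded from the construction: soma centers/radii, one
attachment point per accepted root polyline, one ending point per terminal
tip (branch junctions are not tips), the Euclidean polyline length, and the
rasterized 1-px centerline count outside the soma disks. Candidate neurites
whose rasterization would touch another neurite or a foreign soma are
redrawn (bounded retries) and dropped if no placement is found, so the
recorded truth always matches what was actually drawn.

Matched analysis parameters for these scenes: `lowc = 15` (≈3× the noise
scale, so background is low-contrast while the dimmest tapered tip at ~45
gray levels keeps contrast above it), `lowi = 40` (above the ≤ ~30
background band after flattening, below all signal), `nwidth = 3`,
`psize = 20`.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate: optics (no PSF, no out-of-focus halo), neurites in bundles
or crossing each other (crossings are excluded by construction to keep
truth exact), densely clustered or touching somata, intensity saturation,
and the tree-like skeleton artifacts of high-magnification imagery. Real
images need their thresholds chosen with the `explore` workflow and may
show higher error rates, particularly for ending points.

The canonical four-neuron suite (A–D) uses axis-aligned 1-px rays so that
rasterized pixel lengths agree by construction: A and B differ only in
total length, B and C in attachment count at equal length, C and D in
ending count at equal length and attachment count.

The dose series draws scenes whose total drawn neurite length follows a
4PL inhibition curve (defaults top = 600 px, bottom = 100 px across 9
neurites); because walks truncate at borders and rasterization is biased
for short segments, the requested per-neurite length is calibrated
iteratively against the measured drawn length (accepted at 0.4% or best of
20 draws).

## Numerical choices

* **Rolling ball**: for radii ≤ 8 px the exact rolling-ball background is
  used; for larger radii the image is box-filtered and downscaled (factor
  2/4/8 as the radius grows), the ball rolled at reduced radius, and the
  background bilinearly interpolated back and clipped under the image.
  This preserves the operator's contract — constants map to zero, slow
  ramps flatten to near zero (< 5 gray levels on a 30-level ramp over
  1000 px at radius 50), thin features keep ≥ 80% of their contrast — at
  a small fraction of the cost.
* **Thinning**: iterative hit-or-miss thinning (Guo–Hall style) to an
  8-connected unit-width skeleton. Topology is preserved exactly;
  unit-width holds everywhere except the irreducible case where four
  diagonal arms meet in a 2×2 junction whose every pixel is non-simple —
  no homotopic thinning can reduce it.
* **Pixel length vs geometric length**: a rasterized 1-px polyline has one
  pixel per chessboard (Chebyshev) step, so pixel counts track the
  Chebyshev path length (within 5% in tests), not the Euclidean length —
  a 45° segment has ~29% fewer pixels than its Euclidean length. The
  generator's truth records both.
* **Determinism**: the pipeline has no randomness; the generator uses one
  `numpy` Generator per scene keyed by the scene seed. Batches process
  files in lexicographic order, one image in memory at a time; derived
  ratios are reported as absent (None/empty CSV cell), not zero, when
  their denominator is zero.
* **Problem sizes**: validation uses 20 scenes of 384×384 per noise
  condition, 100 simulations for the noisy IC50 recovery, and 15 scenes of
  256×256 for the end-to-end dose series; the full test suite runs in
  about half a minute.

## Known limitations

* No per-neuron assignment: all readouts are per image; neurites are not
  attributed to individual somata.
* Touching somata merge into one particle; soma *area* remains informative
  when counts saturate.
* Ending-point detection inherits every skeleton artifact; it is the least
  robust readout, consistent with its scoring benchmark being the weakest.
* The error-rate convention (FP+FN)/Ne can exceed 100% when detections are
  few and misses are many.
* `lowc`/`lowi` remain user-determined; no automatic threshold estimation
  is provided.
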