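# Methods

## The model

The localizer treats lesion finding as visual-attention deployment over a
single grayscale B-mode frame. Three assumptions drive it:

* lesions are hypoechoic — darker than surrounding tissue — so darkness is
  evidence (blackness-ratio feature, darkness weight in the superpixel
  score);
* lesions contrast with their neighborhood at some spatial scale
  (center–surround differences over a Gaussian pyramid);
* lesions are compact regions in the mammary layer and never touch the
  image border, whereas the dark subcutaneous fat layer and shadowing do
  (the junction-count veto `L_j > 0`).

The attention machinery (winner-take-all, inhibition of return) is
implemented at its fixed point: the WTA winner is the global maximum of the
combined map, with a row-major-first rule on ties; simulating
integrate-and-fire dynamics would change latency, not the winner.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| ε | 0.001 | blackness-ratio denominator regularizer |
| pyramid levels | 9 | level σ has `ceil(input / 2^(σ−1))` pixels per side |
| kernel | `[1,5,10,10,5,1]/32` | 6-tap separable smoothing before decimation |
| (c, s) pairs | c ∈ {3,4,5}, s = c+3, c+4 | center–surround level pairs |
| working level | 5 | all saliency maps fused at this resolution |
| N iterations | 3 | DoG competition rounds (operator is used with 1–5) |
| DoG | σ_ex 2 %, w_ex 0.5; σ_inh 25 %, w_inh 1.5 | fractions of map width |
| K, m | 400, 40 | SLIC region count and compactness |
| SLIC iterations | 10 | assignment/update rounds, fixed |
| δ | 0.05 | reach of the superpixel-contrast kernel (diagonal units) |
| FOA radius | min(H, W)/8 | attention circle, original-image pixels |
| max attempts | 3 | rejection-loop cap |
| μ | 0.2 · 255² | Chan–Vese length weight (gray² per boundary pair) |

All knobs live in `PipelineConfig` and round-trip through YAML.

Fixed conventions: 0-based row-major `(row, col)` indexing; all internal
arithmetic on float64 in [0, 255], quantized only at file output; bilinear
resampling on a corner-aligned grid for every scale change; reflective
padding for every convolution (avoids dark frame halos that would read as
edge saliency); inputs smaller than 32×32 are rejected.

Ordering choices that matter: features are extracted from the pyramided
channel planes (pyramid first, then per-level feature), which is the only
order compatible with the blackness ratio being nonlinear; `N{·}` is
applied to each contrast map *and* to the across-scale sum; each feature
map is divided by its global maximum so the three maps share a [0, 1] scale
before averaging. A map whose peak is at numerical-roundoff scale
(≤ 1e-9) is treated as all-zero rather than normalized, so constant inputs
yield "no salient region" instead of amplified noise.

## SLIC

Superpixels are grid-seeded local k-means in joint (gray, space)
coordinates with distance `sqrt(d_gray² + (d_xy/S)² m²)`, searched in
2S × 2S windows, S = sqrt(N/K); the seed grid is `gr × gc` with
`gr = round(sqrt(K·H/W))`, so the actual region count tracks the image
aspect. Connectivity is enforced afterwards: components below N/(4K)
pixels merge into their largest 4-adjacent neighbor, smallest first.
Gray values are used raw (no color-space conversion: the input is
single-channel) and the iteration count is fixed rather than
tolerance-based, which keeps the pipeline bit-deterministic.

The superpixel score uses the *absolute* gray difference `|g_k − g_i|`.
A signed difference would score dark regions negatively, inverting the
declared purpose of the darkness weight; the absolute form is the standard
global-contrast formulation. Centroid distances are normalized by the image
diagonal (the maximum possible distance, giving d ∈ [0, 1] exactly). When
every region has the same mean gray the darkness weight is defined as 0
for all regions — a constant image has nothing salient. The rendered map
is computed at full resolution, rescaled to [0, 1], and downsampled to the
working level.

## Chan–Vese stage

Two-phase piecewise-constant model on the discrete energy
`Σ_in (I−c1)² + Σ_out (I−c2)² + μ·Per(mask)` with Per the 4-neighbor
boundary-pair count. The minimization alternates exact mean updates with a
threshold-dynamics label update
`mask ← [G_σ ∗ mask − ((I−c1)² − (I−c2)²)/(2μ) > ½]` (σ = 1.5 px): the
diffusion drives mean-curvature flow, the data force is scaled by the
length weight, and no signed-distance reinitialization is needed because
only the contour feeds the junction count. Two refinements address local
minima that matter on speckle:

* each candidate is cleaned by checkerboard single-flip descent (ICM)
  before its energy is judged — the diffusion step cannot price the
  perimeter of pixel-scale speckle debris, ICM can;
* the evolution restarts from the seed circle at radii r, r/2 and r/4 and
  the lowest-energy result wins. The attention-sized circle is mostly
  background when the lesion is small, which otherwise strands the means
  in a mixture fixed point (c1 between lesion and background) that keeps
  dark clutter attached to the object. For the same reason the initial
  object mean is seeded from the 10 % dark quantile of the circle interior.

An iteration whose energy would increase is rejected and evolution stops,
so the recorded energy history is non-increasing *by construction*; the
invariant tests verify the histories, not the update rule. The returned
foreground is the 4-connected component of the winning phase containing
the seed center: the seeded object, not every dark pixel in the frame.
A constant image (c1 = c2 immediately) is flagged degenerate with an empty
mask.

## Rejection loop and inhibition

A fixation whose segmentation touches the frame (`L_j > 0`) is rejected.
What gets inhibited afterwards is the *segmented region* (downsampled to
the working grid, dilated one cell, plus the fixation cell itself), not
the fixed-radius FOA disk: the veto is about that region, and a fat-layer
band spans far more of the map than one attention disk, so disk inhibition
would spend all attempts inside the same band. Disk-only inhibition
remains available (`ior_mode="disk"`). With post-processing off the first
winner is accepted outright — that contrast is what the hard-cohort
experiment measures.

## Phantom generator

Phantoms are piecewise-mean images — background 140–180 gray, one dark
elliptical lesion (35–60 gray, contrast ≥ 60 gray levels, strictly interior),
optional bright bands/blobs (205–240 gray) and an optional fat band glued
to the top edge — multiplied by unit-mean multiplicative speckle: an
exponential (squared-Rayleigh) field smoothed to a 1.5 px correlation
length and scaled to standard deviation 0.25, roughly display-domain
(log-compressed) speckle contrast. Lesion semi-axes cycle through three
size classes (12–20, 25–40, 42–58 px on a 256×256 frame) to cover small,
medium and large lesions. In the hard cohort the fat band is drawn darker
than the lesion (15 gray up to lesion−8) — the distractor regime the
rejection loop exists for, where the band genuinely out-competes the
lesion in saliency — and bright artifacts appear with probability 0.7/0.4.
Ground-truth masks are constructed analytically, never thresholded.

What the generator does *not* model: attenuation and time-gain
compensation, the probe point-spread function, acoustic shadowing and
posterior enhancement, scan-cone geometry, tissue texture beyond
first-order speckle statistics. Passing cohort tests therefore shows that
the implementation realizes the method's behavior under its own
assumptions (dark compact lesion, speckle, dark/bright distractors), not
clinical performance.

A cohort "hit" means the accepted FOA center lies inside the true lesion
mask — the weakest defensible reading of successful localization, since
the circle is a segmentation seed rather than a contour.

## Problem sizes and evaluation choices

Cohort experiments use 100 phantoms of 256×256 px per condition; the
working saliency grid at level 5 is then 16×16, so a fixation carries a
quantization of about ±8 px when mapped back — small lesions (semi-axes
12–20 px) are the dominant source of near-miss errors. The Chan–Vese
quality check uses 10 random noise-free disk placements on 96×96 frames,
where the two-phase optimum is the generating disk itself.

## Known limitations

* Exact mirror symmetry of the saliency maps does not hold: the 6-tap
  (even) pyramid kernel carries a half-sample phase, and the iterated
  competition operator amplifies that tie-break between equally salient
  objects. Peak *locations* mirror; peak amplitudes need not.
* A dark distractor that is salient, compact and interior (e.g. a
  shadowing patch in mid-image) passes the junction-count veto; the method
  has no further cue to reject it. This is the documented failure mode of
  the approach, and it is visible in the hard cohort: rescue raises the
  hit rate by 8–15 percentage points across seeds but does not reach the
  easy-cohort level.
* The fat layer is vetoed only through `L_j > 0`; no anatomical layer
  segmentation is attempted.
* SLIC's region count is approximate (grid seeding plus orphan merging),
  as in any SLIC implementation.
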