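# Methods

`kneemetry` measures two geometric quantities on an anteroposterior (AP) knee
radiograph — the lateral joint space distance (LJSD) and the height of the
lateral tibial spine (HLTS) — and reports their ratio LJSD/HLTS, a marker
that is elevated in knees with a discoid lateral meniscus (roughly 1.0–1.1
in discoid knees versus ~0.7 in controls). This note describes the model
behind each pipeline stage, the synthetic phantom that provides ground
truth, the numerical choices, and what the test results do and do not show.

## Pipeline model

The measurement is a two-phase procedure.

**Phase 1 — localization.** The knee joint is cropped out of the full
radiograph before any measurement. The original system used a trained
object detector for this step; `kneemetry` keeps that stage pluggable (any
callable returning a box and a confidence can be injected, and a
caller-supplied box always wins) and ships a classical fallback,
`profile_roi_proposer`. The fallback exploits the universal intensity
structure of an AP knee: a dark joint-space band flanked above and below by
the brightest bone bands in the image. It locates the deepest such valley in
the smoothed row-mean profile, takes the bright-column span near the band as
the joint width, and sizes the box with fixed anatomical proportions
(height = 0.78 × width, 43% of the height above the band center; bright
columns at 35% of the local column-mean range). Images without the
bright–dark–bright signature (uniform images, inverted contrast) are
rejected rather than guessed at — a wrong crop would silently corrupt the
measurement, so "no answer" is the safer output. The reference detector's
training hyperparameters are retained as documented constants
(`config.REFERENCE_DETECTOR_HYPERPARAMS`) but no network is bundled.

**Phase 2 — enhancement.** The crop is median-filtered (3×3; removes
salt-and-pepper impulses that violate the Gaussian-noise assumption of
block-matching denoisers) and then denoised with a block-matching
collaborative filter. When the optional `bm3d` package is installed it is
used; otherwise scikit-image's non-local means (patch 5, search radius 6,
h = 0.8 σ) stands behind the same contract: PSNR against the clean
reference must strictly improve on noisy inputs while anatomical edges stay
localized. After enhancement the number of traceable edges is counted
(polylines of ≥ 20 px with the first Canny group); if fewer than 10 emerge,
the image is treated as pathologically low-contrast, the attempt is
discarded, and the *original* crop is re-enhanced with median filtering
plus global histogram equalization instead. Equalization is never applied
on the normal path because it amplifies noise along with contrast; the two
branches are mutually exclusive.

**Phase 3 — edges.** Canny edge detection (Gaussian σ = 1.4) with the
hysteresis retry groups (20, 80) then (20, 90); the second group is consumed
only when a landmark stage fails with the first. The thresholds are quoted
in the 3×3-Sobel convention of classic implementations and divided by the
Sobel kernel gain (8) for scikit-image's Gaussian-derivative gradient.
Edge pixels are traced into polylines: 8-connected components are reduced
to their longest path plus branches of at least `min_len` (10 px) pixels,
then split at strictly vertical runs longer than 12 px and wherever the
chain's x direction reverses with ≥ 4-column persistence. The splits matter:
every landmark operator treats an edge as a height profile over columns
(h = (H−1) − y, y-up), and a chain that runs along a bone border, around a
silhouette corner and back along another border is not a function of x.
Per column the topmost pixel is the representative.

**Phase 4 — landmarks.**

* *Femur boundary (POFB).* An edge is femur-boundary material iff it is
  markedly horizontal (column span ≥ 20% of the ROI width and ≥ 3× its
  height span) and no other such edge lies above it over more than half its
  span. Qualifying edges are merged left-to-right (overlaps resolved to the
  *lower* height — the joint's upper boundary is the femur's lowest
  silhouette; flare-top edges can also satisfy both rules), gaps up to 10%
  of the ROI width are bridged linearly, and the widest contiguous block is
  kept (it must cover ≥ 30% of the ROI width).
* *Condylar points.* The boundary profile is smoothed (moving average,
  window 5; profiles shorter than 15 columns are used raw so that tiny
  profiles behave exactly as enumerated by hand), the two deepest separated
  height minima are the condyle bottoms, the highest interior point between
  them is the intercondylar notch, and the up-left/up-right points are the
  raw minima of the two segments. The femoral axis is their x midpoint.
* *Tibial spines.* Tip tops are interior window maxima of an edge profile:
  column X qualifies iff F(X) is the maximum over in-domain columns of
  [X−K, X+K], with K = max(3, 0.05 d) for condylar distance d. Runs of tied
  qualifying columns collapse to their midpoint; a run wider than the full
  window (2K+1) is a ridge, not a tip, and a tip must rise ≥ 3 px above the
  lowest profile value in its window span (pixel-jitter bumps on flat
  texture edges are not anatomy). Tips above the femur boundary, at edge
  end points, or on the boundary's own member edges are removed. Among
  candidate pairs that are separated by 5–60% of d, lie strictly between
  the condyle points, and are symmetric about the femoral axis within
  0.15 d, the pair with the greatest lower tip wins; ties (common with
  integer pixel heights) break first to the greater total height, then to
  the most axis-symmetric midpoint.
* *Plateau border points.* Candidates are edge-profile points below the
  femur boundary and not above the condyle baseline (the line through the
  condylar points — this exclusion is what keeps femoral flank points out).
  A 45° ruler is slid against each side: the border point maximizes
  B(x) = F(x) cos45 ∓ x sin45, computed as the exactly equivalent h ∓ x so
  that integer ties stay exact and break to the outermost column. If the
  local slope at the tangent exceeds 70° the point is walked inward along
  its edge to the first place with slope ≤ 45° (capped at 25% of the edge
  span, with a warning). The baseline is the line through the two border
  points.

**Phase 5 — measurement.** LJSD is the perpendicular distance from the
lateral condylar point to the baseline; HLTS the perpendicular distance
from the lateral spine tip; the output is their quotient. The laterality
(which image side is anatomically lateral) is an input: CLI flag, DICOM
laterality metadata under the AP convention (a right knee's lateral
compartment appears on the image left), or a default, in that precedence.
A perpendicular (not vertical) distance is used so a tilted plateau is
handled consistently. HLTS below 0.5 px is rejected as degenerate.

### Sub-pixel refinement

Canny landmarks are pixel-quantized (±0.5 px per landmark), which is too
coarse for a ratio of two ~30 px distances. Before measuring, each
measurement-relevant height is refined on the enhanced crop:

* *Edge heights* by a 3-point parabola through the vertical
  intensity-gradient magnitudes around the detected pixel (the gradient of
  a blurred step is Gaussian; its peak marks the boundary). The gradient
  width also yields a local blur estimate σ̂².
* *Curved extrema* (spine apices, condyle bottoms) are additionally
  corrected for blur displacement: the gradient ridge of a blurred edge
  with profile curvature κ shifts toward the centre of curvature by
  ≈ σ²κ. With κ from a quadratic fit of the landmark's own column profile
  (κ = 2|a|), the correction −2σ̂²a (clipped to ±1.5 px) removes the
  systematic apex erosion. Condyle bottoms also take their x from the
  profile-parabola vertex, since the arc is nearly flat and the raw pixel
  minimum wanders by several columns.
* *Plateau corners* are refined by fitting the plateau line inboard
  (outlier-trimmed; the steep drop's pixel staircase is never fitted
  directly), calibrating its absolute offset with a gradient probe on the
  clean plateau edge, fitting the drop on clearly off-plateau pixels only,
  and intersecting the two lines. The corner height inherits the plateau
  line's accuracy because its slope is small.

Refinement is on by default (`measure.subpixel`); switching it off restores
pure pixel-level landmarks.

## Suite evaluation

`evaluate_suite` scores a batch against ground truth. An image counts as a
success only if the pipeline completes *and* the measured ratio is within
15% relative error of truth — completion with a wild value is not a usable
measurement. Over the successes it reports mean ± SD of the measured
ratios, bias and RMSE against truth, and a two-tailed paired-samples t test
of measured versus true ratios (zero-variance differences report p = 1.0
with a warning; fewer than two successes omit the statistics).

## The synthetic phantom

Clinical radiographs and the trained detector are not distributable, so
every stage is validated against a synthetic AP knee phantom with exact,
analytically defined ground truth (never re-detected; independence of the
algorithm under test). The phantom is a 2-D silhouette model — the
measurement consumes only 2-D edges, so no 3-D projection is needed:

* a femur whose lower border is two circular condylar arcs (radius ~68–80%
  of the plateau halfwidth, condylar distance 1.3× the plateau halfwidth)
  joined by a sinusoidal intercondylar notch, flaring wider than the shaft;
* a tibia whose upper border is the plateau line (tilt ≤ 5°) carrying two
  Gaussian spine bumps, dropping at the corners (4 px/column for 14
  columns) into a flared metaphysis and shaft;
* a soft-tissue envelope, short dark trabecular streaks inside each bone
  parallel to the articular borders (they keep the edge census realistic
  without adding long contours), optional sinusoidal bone-texture stripes,
  Gaussian blur (σ ~0.9–1.4), Gaussian and salt-and-pepper noise, and
  affine contrast compression toward the mean.

Rendering is vertically anti-aliased (per-pixel coverage), so the
50%-intensity crossing of every articular border lies exactly on the
analytic boundary that the truth record quotes; binary masks would offset
every edge by half a pixel. The lateral compartment is built on the image
left and mirrored column-exactly for right-lateral images.

True LJSD and HLTS are spec parameters: the lateral condyle bottom sits at
perpendicular distance `ljsd_true` above the baseline, the lateral spine
apex at `hlts_true`, so `truth.ratio` is exact by construction. Suites draw
the true ratio from the cohort's generating normal distribution — control
0.7 ± 0.2, discoid 1.0 ± 0.3 (automatic-measurement cohort statistics) —
truncated to [0.3, 1.8] to stay anatomically renderable, realized by
HLTS ~ U(30, 50) px and LJSD = ratio × HLTS. Control/discoid suites carry
mild noise (Gaussian σ=2); the mixed suite applies the standard
degradations (Gaussian σ=5, salt-and-pepper 0.5%, contrast 0.6–1.0,
texture stripes on half the images) and flips a fair coin per image
between the two cohorts.

The sampler enforces in-scope anatomy. Radiographs where a tibial spine
crosses the femur border are explicitly out of scope, and a joint space
narrower than the imaging blur scale is unresolvable, so the
femur-to-tibia gap must be ≥ 9 px everywhere (the notch is deepened, and
the spine bumps narrowed, until it is; specs with a gap under 3 px are
rejected outright). Spine bumps may neither merge into one mesa
(σ ≤ separation/2.2) nor sharpen into needles (apex curvature ≤ 0.45/px —
real spines are much blunter than their height); both limits keep the
phantom inside what the method claims to handle.

**What the phantom does not model:** projective geometry and beam
divergence, realistic trabecular texture (only streaks and stripes),
osteophytes and joint pathology other than the ratio itself, the patella
(its overlap is an open problem for the measurement method), the fibular
head, rotation/flexion malpositioning, and detector physics (scatter,
heel effect). Passing the synthetic suites therefore demonstrates the
geometric correctness and noise robustness of the implementation, not
clinical-grade performance on hospital images.

## Numerical and degenerate-input choices

* Heights use h = (H−1) − y exactly once (in `column_profile`); all
  landmark math is y-up, all rendering y-down.
* Tie-breaks are fully deterministic everywhere (documented per operator);
  polyline ids are assigned in raster order of their extents, independent
  of memory layout.
* All randomness flows from explicit seeds; same (spec, seed) renders a
  bit-identical phantom, and the pipeline itself is deterministic.
* Degenerate inputs fail typed and early: images without intensity
  structure fail detection; boundaries without two separated valleys fail
  at `condyles`; missing spine pairs at `spines`; empty candidate sets at
  `plateau`; coincident border points at `baseline`. `run_pipeline` never
  raises — the Report records the last failed stage across all Canny
  retry groups.
* Problem sizes used by the test and acceptance suites: 200-phantom
  cohort suites, a 200-phantom mixed suite, a 300-phantom detection suite,
  100 noiseless recovery specs, and 1000 random small edges per
  brute-force oracle; together they complete in a few minutes on one CPU.

## Known limitations

* The fallback ROI proposer assumes one knee per image and the standard
  AP intensity signature; multi-knee images return only the first joint.
* The border-shift rule implements only the steep-to-inward direction;
  an outward shift (conceivable for concave corner artifacts) is not
  implemented.
* Histogram-equalized extreme-low-contrast images (contrast factor ~0.05)
  complete but with reduced landmark accuracy, as only a handful of
  intensity levels survive quantization.
* Sub-pixel corrections assume locally Gaussian blur and locally quadratic
  contours; violently non-Gaussian noise would degrade them toward plain
  pixel accuracy, not toward bias.
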