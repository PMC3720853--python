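# Methods

`qpimass` converts time-lapse quantitative-phase image stacks into
single-cell dry-mass trajectories and classified T-cell-mediated killing
events. This note documents the model behind each stage, the tunable
parameters and their defaults, what the phantom generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Dry mass from optical path difference

A quantitative phase microscope measures, per pixel, the optical path
difference (OPD) of light through the specimen relative to the surrounding
medium. OPD is stored in micrometres throughout this package, not radians,
so that the dry-mass relation is dimensionally direct:

    m = k · A_pixel · Σ OPD_i                            [pg]

with `k = 5.56 pg/µm³` the inverse specific refractive increment
(Δρ/Δn measured against water — hence *dry* mass: everything in the cell
that is not water), `A_pixel` the pixel footprint at the sample in µm², and
the sum running over a cell's pixel support after background referencing.
Because the refractive increment of biological dry matter is nearly
composition-independent, `k` is treated as a constant; it is configurable in
`OpticsConfig`.

Default optics: wavelength λ = 0.530 µm (single-wavelength LED
illumination), pixel pitch 0.6 µm at the sample, 256×256 px fields, one
frame every 3.5 min. The pixel pitch matters more than it looks: the
steepest cap rendered by the phantom (a freshly balled-up dying cell) has an
OPD slope near 0.25 µm/µm, and phase unwrapping is only well-posed while the
per-pixel OPD step stays below λ/2. At 0.6 µm/px the worst-case step keeps
an ≈8σ noise margin below λ/2; at substantially coarser sampling the balled
cap would alias and *no* unwrapper could recover it.

## Phantom generator

Every downstream stage is validated against rendered phantoms with exact
ground truth. A cell is a radially symmetric power cap

    OPD(r) = h · (1 − (r/R)²)^q ,   q = 1 by default,

whose continuous integral is hπR²/(q+1); `h` is set from the scripted mass,
so the rendered pixel sum reproduces the prescribed mass to quadrature
accuracy (<0.5% relative at the default sampling, ~0.1–0.2% in practice).

Scripted kinetics per role:

* **healthy target** — multiplicative growth, default +15% of initial mass
  per 4 h (per-cell scatter σ = 3 percentage points); initial mass
  ~N(840, 60) pg, radius ~N(15.5, 0.7) µm.
* **killed target** — healthy growth until the scripted event time `t0`,
  then an instantaneous "ball-up": the footprint radius contracts to 0.6 R
  with `h` rescaled to conserve mass (area −64%, mean OPD ×2.8), followed by
  an exponential-to-linear decay `1 − f·(1 − e^{−3τ})/(1 − e^{−3})`,
  τ = (t − t0)/duration, reaching the loss fraction f ∈ [0.2, 0.6] exactly
  at the end of the 1–4 h loss window, after which the mass holds.
* **activated CTL** — piecewise-linear mass: rate `r_pre` before t0,
  `4·r_pre` during the first 100 min after t0, `2·r_pre` afterwards.
  The attacking CTL approaches its target, holds contact (overlapping
  footprints) for the 45 min before t0, and steps back ~4 µm as the target
  detaches, matching the separation seen at the onset of death.
* **unresponsive CTL** — healthy-like growth; initial mass ~N(60–65, 8) pg,
  radius ~N(4.4, 0.25) µm.

The rendered OPD field is the sum of all caps plus additive zero-mean
Gaussian noise (σ = 0.004 µm per pixel) applied *before* wrapping; the field
is then wrapped into [0, λ) and the integer wavelength counts removed per
pixel are stored as ground truth, together with a per-pixel cell-id map and
the per-frame truth table. The noise amplitude was chosen so that the
repeated-measurement CV of a static cell through the full pipeline stays
comfortably inside the ~2% total-mass precision quantitative phase imaging
is known for. The matched "intensity" image is a monotone decreasing
transform of the clean OPD (`exp(−OPD/0.8 µm)`) with its own noise — enough
structure for the wrap-boundary classifier, with no claim of optical
realism.

The named scenarios pin the study conditions: `healthy-default` (300 target
cells across 38 fields, 4 h), `death-default` (20 killed targets with loss
fractions drawn uniformly over [0.2, 0.6] and durations over [1, 4] h, each
with an attacking CTL), `activation-default` (10 CTL–target event pairs,
r_pre ≈ 6 pg/h), `mixed-population-default` (24 event pairs among 84
unresponsive CTLs), `static-cell` (one motionless, non-growing 240 pg cell,
50 frames) and `mass-fidelity-default` (the 20-cell, 256×256×60 benchmark
field). In the mixed population the generator *encodes* the headline
contrasts as defaults: activated endpoint mass = 2.8 × the expected
unresponsive endpoint mean, activated endpoint footprint area = 1.4 × the
unresponsive mean (the pre-event rate is back-computed per cell from its
endpoint target, preserving the 4× rate step). The pipeline's job in
validation is to recover these numbers from the rendered wrapped images.

What the phantom does **not** emulate: optical diffraction and the point
spread function, interferogram fringe formation, camera shot noise,
background drift/tilt, debris, cell division, and irregular cell shapes.
Passing the phantom suite therefore demonstrates correctness of the
*computational* chain under a realistic geometry/kinetics model — not
robustness to every optical artefact of a real instrument.

## Phase unwrapping

Each frame is unwrapped independently by minimising the total residual
discontinuity — the objective of minimum-discontinuity (Flynn-style)
unwrapping. The implementation finds the L1-minimal set of integer
corrections to the wrapped pixel-difference field that makes it curl-free:
phase residues are detected on every 2×2 loop and, when present, routed
through a min-cost-flow linear program (scipy's HiGHS; the constraint matrix
is totally unimodular, so the LP optimum is integral). Residue-free frames —
the overwhelmingly common case at the default sampling — take a vectorised
fast path that integrates the wrapped differences directly. The output is
congruent to the input modulo λ *exactly* (it is computed as
`input + λ·K` with integer `K`), anchored so the correction at pixel (0,0)
is zero; the pipeline then zeroes the gauge by subtracting the image median
(the background), since the anchor pixel's own wrap state is arbitrary.
Unit edge weights are used (no quality map), and 4-connectivity defines the
discontinuity count.

A classical 1-D cumulative (Itoh) unwrapper is included as an independent
test oracle.

## Supervised wrap-error correction

Real unwrappers leave occasional whole regions offset by one wavelength.
The repair stage is supervised, mirroring how such pipelines are built in
practice:

1. **Features** — 16 per-pixel channels: the raw wrapped image, the
   intensity image, and 14 fixed edge/texture statistics (Sobel and Scharr
   magnitudes, directional first differences, Laplacian, smoothed-gradient,
   local SD at two window sizes, morphological gradient, local range,
   distance of the wrapped value to λ/2, smoothed phase and intensity,
   intensity gradient). The menu is pinned (`qpimass-16ch-v1`) for
   reproducibility.
2. **Fisher discriminant** — closed form, `w ∝ S_w⁻¹(µ₁ − µ₀)` on
   standardised features, initial score threshold at the midpoint of the
   projected class means; ridge `10⁻⁶·tr(S_w)/16` if the pooled covariance
   is singular. Training data are ~200 phantom sub-images of wrapping cells;
   positive labels are the ground-truth wrap-count boundary pixels dilated
   by one — the phantom's stand-in for manually curated corrections.
3. **Genetic refinement** — a real-coded GA (population 32, 50 generations,
   tournament size 3, Gaussian mutation σ = 10% of the search range,
   elitism 2, fixed seed) tunes the score threshold and the watershed flood
   threshold. Fitness is the pixel F1 of the corrected-pixel mask against
   ground truth after a full correction pass over a fitness subset
   (12 sub-images, half with deliberately mis-shifted wrap regions). The
   incumbent model is injected into the initial population, so refinement
   never reduces fitness, and the whole procedure is seed-deterministic.
4. **Region correction** — the discriminant score map is thresholded;
   areas fully enclosed by the boundary band are candidate regions
   (watershed from a unified interior marker against the outside splits the
   band along its score crest). Because the crest locates the wrap fringe
   only to a pixel or two, the shift decision is made against a local smooth
   reference: the candidate box is re-wrapped, re-unwrapped and
   gauge-anchored on pixels away from the region; each pixel's integer
   wavelength offset is read off, the majority offset over the region gives
   the sign (zero ⇒ the region is consistent and left untouched), and the
   refined mask is exactly the offset-sharing pixels — which by construction
   minimises the boundary discontinuity after the ±λ shift. Every shifted
   pixel moves by exactly one wavelength per pass; a 3×3 median filter on
   the phase values closes the pass. Multi-wavelength errors are handled by
   iterating the pass, not by larger shifts.

On frames whose unwrapped dynamic range is below λ no single-wavelength
region error is representable, so the detector is skipped and only the
median filter is applied — an algebraic fast path, not an approximation.

## Segmentation

Detection follows Gaussian low-pass (σ = 2 px) → global Otsu threshold
(256-bin histogram) → 8-connected components → minimum size 30 px. Two
robustness measures around the plain Otsu recipe:

* the histogram is clipped at a robust ceiling (max of median + 20·MADσ and
  the 99th percentile) before Otsu, so a single very bright object (a
  balled-up cell) cannot drag the global threshold above dim T cells;
* dry mass integrates over the Otsu component *grown* by a label-constrained
  dilation (`skimage.segmentation.expand_labels`, default 10 px). The Otsu
  level sits at an appreciable fraction of a cap's height, so the raw
  component misses the low-OPD skirt — several percent of true mass; the
  dilated support recovers it while competing labels keep touching cells
  from claiming each other's pixels. Background statistics (median and MAD)
  are estimated from pixels outside *all* dilated supports, and the median
  is subtracted before integration.

Projected 2-D area uses a separate local adaptive threshold inside the mass
support: a pixel is in-cell if its OPD exceeds the local mean over a
201-px-sided square minus an offset (default 0.015 µm), floored at
background + 3σ so sparse fields cannot produce near-zero thresholds. Mass
is never integrated over the adaptive support; area is never taken from the
Otsu support. Components larger than a configurable area are flagged
merge-suspects. Centroids are OPD-weighted.

## Tracking

Frame-to-frame linking minimises total squared centroid displacement with a
penalty of `max_disp²` per unmatched detection (Hungarian assignment; links
longer than `max_disp` forbidden). Defaults: `max_disp` 15 µm/frame — ample
for T-cell motility at a 3.5-min cadence — and gap closure over up to 2
missing frames with a √(gap+1)-inflated radius. Ties are broken by a
vanishing lexicographic epsilon so output is deterministic.

When two cells press together, segmentation returns one component. The
displaced track *rides* the shared detection: it keeps its identity, holds
its last separate centroid for future matching, and both tracks flag those
frames as merged with mutual partner references. Merged-frame mass is the
*combined* mass of the pair and is attributed to both, never split; all
single-cell analyses exclude merged samples. Tracks that end in the field
interior are labelled washed-away (perfusion), at the border left-field.

## Mass trajectories and rates

Trajectories carry per-frame mass, adaptive area, mean OPD, and merge flags.
Normalisation divides by the (linearly interpolated) mass at a reference
time — the first sample for growth curves, the ball-up time for event
curves. Mass-accumulation rates are ordinary-least-squares slopes of mass
vs time in pg/h over three windows around the event time: pre = [start,
t0), during = [t0, t0 + 100 min] (boundary sample inclusive), post =
(t0 + 100 min, end]. A window with fewer than 3 usable samples yields NaN.
The pre-event fit additionally ends at the onset of persistent contact
minus 7 min when a contact interval is known: once footprints overlap,
hard pixel assignment biases single-cell masses, and those approach frames
would contaminate the baseline slope.

## Event detection and statistics

* **Contact** — two coexisting tracks are in contact at a frame if they
  share a merged detection or their Otsu supports come within 1 px;
  intervals are maximal runs tolerating 1-frame gaps.
* **Ball-up (t = 0)** — earliest frame where the projected area drops ≥30%
  against the trailing 5-frame median while the mean OPD rises ≥30% within
  two frames. Both conditions together reject area loss without
  densification (e.g. a cell sliding off the field).
* **Death** — confirmed iff a ≥30 min contact interval precedes or overlaps
  t0 and the mass falls ≥20% of the (interpolated) t0 mass within 4 h; the
  reported loss fraction is the maximum fractional loss in that window.
  Unattributed mass loss (no contact) is never an event — the label-free
  analogue of antigen-specificity controls.
* **Activation** — the attacking CTL's rate triplet about t0; flagged
  activated when r_during/r_pre ≥ 2 (deliberately looser than the ~4×
  effect so noise cannot un-flag real events); the ratio and the
  endpoint-mass fold-change versus the unresponsive mean are reported
  unconditionally, so the flag threshold never biases summaries. The CTL
  endpoint mass is the last unmerged sample within 4 h of t0.
* **Populations** — CTL-role tracks are grouped activated (attributed to a
  confirmed event) vs unresponsive (no confirmed event — the operational
  definition chosen here); groups are compared on endpoint mass and area
  with two-tailed Welch t-tests (Welch–Satterthwaite df; p = 1 when both
  variances vanish with equal means), starred at p<0.05 / p<0.01 / p<10⁻³.
  The summary also reports the implied volume fold (area fold)^1.5 for
  near-spherical cells. Note that with the phantom's modest within-group
  scatter the 1.4× area contrast *does* reach significance; in real data
  its significance depends on the biological spread, which the phantom does
  not model. Cell roles (target vs CTL) are assigned by first unmerged mass
  against a 400 pg threshold — the populations differ several-fold in mass.

## Determinism and problem sizes

Every stochastic step (scene layout, rendering noise, GA, subsampling)
derives from explicit seeds; identical (config, seed) reproduce outputs
bit-for-bit, and each run's manifest records the full parameter set with a
config hash. Validation problem sizes are chosen to exercise the pipeline
at realistic density while keeping a full recovery run in the
tens-of-minutes range on a single core: 38 healthy fields of 8 targets,
5 death fields of 4 pairs (320² px), 3 activation fields totalling 10
pairs, 8 mixed event fields (3 pairs + 8 bystanders each) plus 2
bystander-only fields, one 20-cell benchmark field, and a 50-frame static
cell. The mixed population (24 events vs 84–95 unresponsive) is a
scaled-down analogue of the hundreds-of-cells populations such experiments
produce; fold-change recovery tolerances account for the smaller n.

## Known limitations

* Hard pixel assignment between overlapping cells biases single-cell masses
  by a few percent during approach/contact frames; merged-frame bookkeeping
  and the pre-window trim mitigate but do not eliminate this.
* The wrap-error corrector assumes errors are single-wavelength per pass
  and regions are enclosed by detectable boundaries; open-ended (half-plane)
  unwrap failures are outside its design.
* Per-frame independent unwrapping ignores temporal continuity; a cell
  whose per-pixel OPD step exceeds λ/2 is unrecoverable by any single-frame
  method, which constrains the phantom's pixel pitch as discussed above.
* Watershed splitting of touching cells is deliberately absent; merged
  objects are handled by combined-mass bookkeeping, so per-cell masses are
  simply unavailable (not wrong) during contact.
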