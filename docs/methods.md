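# Methods

This note documents the models, parameters and numerical choices behind
`perisr`, and what its validation does and does not establish.

## Stimulus engine

**Geometry.**  Coordinates are arcmin of visual angle relative to
fixation (x temporal-positive, y up); images are row-major with pixel
centers at half-integer offsets, 1.05 arcmin/pixel at the default 75-Hz
display.  The Landolt target is the standard geometric ring — outer
diameter *d*, stroke *d*/5, and a square-profile radial slot of width
*d*/5 (the gap) centered on one of the four oblique axes — rather than
a font outline; the 20% critical-detail ratio is what matters for the
simulation logic, and the staircase manipulates the gap with
*d* = 5 × gap.  Rendering supersamples ×4 and area-averages, so edges
are anti-aliased; a degenerate-stimulus error is raised below one pixel.

**Mask.**  The 7°×7° occluder is an 80×80 grid of 5.25-arcmin elements.
Opacity is an exact-count draw — round(density × 6400) elements chosen
uniformly without replacement — so a density-0.5 mask has exactly 3200
opaque elements.  Opaque elements render *at background luminance*:
they remove target information without adding any visible structure,
emulating silent losses in a sampling array.

**Motion.**  Moving targets (and the moving mask) follow an
isoeccentric arc of radius 10° at 2°/s, i.e. 1.6 arcmin of arc per
frame at 75 Hz, with the trajectory span symmetric about the horizontal
meridian; with 25 frames the mid-trajectory point lies exactly on the
meridian (the plausible alternative — anchoring the start at the
meridian — is a half-span offset and does not change any contrast).
Shuffled trajectories are a seeded permutation of the same positions,
so the position multiset is identical and only temporal order differs.
Per-frame-updating masks redraw the opaque set each frame from a seeded
stream under one master seed: sequences are bit-reproducible while
frames stay independent.

**Canvas.**  The default canvas is a 480×480-arcmin scene window
centered on the 10° meridian point — large enough to contain the mask
at every configured path position.  The fixation cross (0.5°, white) is
drawn whenever it falls on-canvas; `DisplayModel.full_field()` gives a
wider, fixation-inclusive canvas used for stimulus export.  Observers
never analyse the fixation region.

## Model observers

The observer stage is a modelling layer of this package (the paradigm
itself makes no commitment to a mechanism); its components were chosen
so that each hypothesised strategy is represented by its cleanest
formulation.

**Front end.**  Three stages, applied per frame within the attended
processing window:

1. Gaussian blur, σ = 2.5 arcmin — peripheral optical/neural spatial
   filtering at 10° eccentricity.
2. Fixed-pattern noise, sd = 4 cd/m², correlation scale 12 arcmin —
   a Gaussian random field tied to retinal (display) coordinates, drawn
   once per trial and identical across the 25 frames.  It models static
   inhomogeneity of the sampling array (receptor/ganglion gain
   variability, coarse-grained at the peripheral pooling scale).  This
   is the component that makes *bona fide* super-resolution possible in
   the simulation: temporal noise averages out for any integrating
   observer, but retina-fixed noise only averages out when the image
   moves across the array and the frames are motion-registered.
   Because the field is smooth, it mainly disturbs coarse spatial
   judgments — the large-gap regime that masking forces observers
   into — and has little effect on the fine-gap regime of unmasked
   thresholds, which is how the simulation reproduces "motion helps
   only when masked".
3. Temporal noise, sd = 6 cd/m² per pixel, independent across frames.

The noise magnitudes were calibrated once so that unmasked static
thresholds fall in the small-gap regime (≈1.5–2 arcmin) and masked
thresholds at density 0.75 in the 6–12 arcmin range, and then frozen.

**Decision.**  Normalized cross-correlation of the analysis window
(3 × target diameter, centered on the known mid-trajectory target
position — observers know where to attend, as subjects did) against
four noiseless Landolt templates rendered at the matching sub-pixel
position; argmax with a seeded uniform tie-break.  A zero-variance
window yields all-zero decision variables and hence a uniform guess,
which produces the exact 25% floor on fully occluded trials.

**Strategies.**
- *single_frame*: decide on the middle frame.
- *prob_summation*: per-frame decision variables at the true per-frame
  target position, pooled across frames with a max rule (the standard
  signal-detection reading of "more independent looks"); no cross-frame
  image synthesis.
- *super_resolution*: shift-and-add.  All frames are registered to the
  middle frame and averaged (cubic-spline translation; per-pixel sample
  counts returned), and the decision is made on the composite.
  Registration uses one of three policies: `oracle` (true path
  metadata), `none` (zero shifts — a deliberate misregistration
  control), or `estimated`.

**Estimated registration.**  The `estimated` policy is a
predictable-trajectory search: the observer assumes a constant-velocity
path along the (locally vertical) arc, scans candidate speeds −3…+3°/s
in 0.25°/s steps, scores each by the best orientation-template match of
the corresponding integer-pixel registered average, and adopts the
winning velocity for the final sub-pixel shift-and-add.  Direct
pairwise frame-to-frame correlation was evaluated and rejected: with a
static occluder the visible-fragment envelope is itself static, so the
correlation peak is pulled toward zero lag and chained estimates
underestimate the velocity by ~50% with near-floor confidences.  The
trajectory-search formulation retains the essential property that
motion estimation is easy for smooth paths and impossible for
frame-shuffled ones, which is precisely the contrast the
trajectory-predictability experiment manipulates.  `estimate_shift`
(FFT cross-correlation with quadratic sub-pixel refinement) remains in
the API and is exact for clean translations.

## Staircase

3-down-1-up: gap starts at 17.8 arcmin, step 4.5 arcmin; errors move
the gap up, every third consecutive correct response moves it down; the
consecutive-correct counter resets on every gap change and every error
(standard transformed up-down bookkeeping).  A direction change is a
reversal; on every size-increasing reversal the step is halved, the
halved step governing subsequent moves.  The phrasing of the halving
rule admits a second reading (halve *before* applying the reversal's
own increase); that variant makes up-steps systematically smaller than
down-steps and biases long-track convergence to ≈0.5 arcmin below the
transformed up-down target, so the subsequent-moves reading was
adopted.  Runs terminate after 8 reversals or 50 trials; the gap is
floored at 1.05 arcmin (one pixel), the rasterization limit.  Against a
logistic responder the rule tracks p = 0.5^(1/3) ≈ 0.794, i.e.
x\* = μ + 0.97σ; long simulated tracks settle ≈0.2 arcmin above x\*, a
residual of the decreasing-step schedule, within the ±0.3-arcmin band
used for validation.

## Psychometric fitting

Bernoulli ML on pooled trials of
p(x) = 0.25 + 0.75/(1 + e^((μ−x)/σ)) — guess rate fixed at the 4AFC
floor, no lapse parameter (upper asymptote 1).  Optimisation is a
coarse grid (μ ∈ [1, 30] arcmin × σ ∈ [0.1, 10], log-spaced in σ)
seeding L-BFGS-B refinements on (μ, log σ) with analytic gradients;
deterministic given the data and verified against an exhaustive
fine-grid search.  Data with fewer than two gap levels or only one
outcome class raise a non-identifiability error.  Bootstrap CIs
resample *trials* with replacement (the exchangeable unit; run-level
resampling is a noted alternative), refit warm-started at the
original solution, and take 2.5/97.5 percentiles of the bootstrap μ;
failed refits are dropped and more than 20% failures raise an error.
Default 1000 resamples (500 in the validation runs).  Measured
performance: mean μ-recovery error −0.015 arcmin (100 × 400-trial
datasets), CI coverage 95.0% (200 datasets).  When an observer is at
ceiling down to the smallest tested gap (common in small pilot runs),
the ML fit extrapolates and μ can fall below the 1.05-arcmin
rasterization floor — such values mean "better than measurable", not a
physical threshold.

## Experiments and statistics

Eight simulated subjects by default, each a lognormal (±20%) jitter of
the base observer parameters; seeds form a logged hierarchy master →
subject → run → trial, so every table is bit-reproducible.  The
threshold table is balanced over subjects × conditions × densities
(densities {0, 0.5, 0.75} for the masking experiment, {0.5, 0.75} for
the others).  Motion benefits are per-density subject-mean threshold
differences with percentile bootstrap CIs over subjects.  The
repeated-measures ANOVA partitions sums of squares directly (each
effect tested against its effect×subject interaction); the partition is
checked against the total to 10⁻⁹ relative tolerance and the F values
against an independent brute-force computation and `pingouin`.

Human F and p values are not reproduction targets — they are
measurements of people.  The pipeline instead validates the *orderings*
the mechanism predicts, using fixed-probe-gap accuracy contrasts as a
threshold surrogate (accuracy is monotone in threshold through the
psychometric function, so the benefit sign is preserved; probe gaps sit
at each condition's sensitive operating point: 8 arcmin at density
0.75, 1.5 arcmin unmasked, 5.5 arcmin for the shift-and-add observer
under updating masks).  The scaled-down protocol (20 master seeds,
24–96 trials per condition per seed) keeps each check within a few
minutes at ≳95% per-seed sign reliability.

## What the synthetic data do and do not show

The generator reproduces the experiment's design exactly (frame
counts, geometry, densities, staircase rule, trial records), and the
model observers reproduce the qualitative phenomena: motion benefit
confined to masked targets; strong attenuation under information
matching with a residual benefit only for the registration-based
observer; smooth-trajectory advantage under self-estimated
registration.  They are not fitted to any human threshold, so absolute
thresholds and effect magnitudes are calibration-dependent and should
not be compared numerically with human data.  Known limitations: no
fixational eye movements (the static-target conditions are perfectly
stabilized, which no human fixation is); the front end is additive
Gaussian rather than physiological; the target-motion vs mask-motion
asymmetry is not built in — the registration-policy knobs allow
exploring it, but the default observers treat the two as equivalent
relative motion; and the prob-summation observer can inherit a small
benefit from fixed-pattern-noise decorrelation at finite trial counts,
which the validation bounds rather than assumes away.
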