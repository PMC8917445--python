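# Methods

This note records the models, conventions and design choices behind the
package, in the order data flows through it.

## Synthetic experiment model

The raw recordings behind this kind of maternal-provisioning experiment are
rarely deposited, so the package ships a generator that reproduces the
*statistical structure* of the design and provides ground truth for every
downstream stage. All generators draw from one root seed via
`numpy.random.SeedSequence.spawn`, with one sub-stream per fish/mother and
per trial, so identical parameters reproduce identical data and a given
fish's data does not depend on how many others are generated.

### Startle trials

Each trial is latently a responder or non-responder
(`responder_fraction`, default 1/3 as in the emulated data set where about
two thirds of trials showed no response). Speed follows a single-peaked
asymmetric pulse

v(τ) = peak · (τ/t_r · exp(1 − τ/t_r))^s,  s = t_r / t_d,

which rises to `peak` at τ = t_r after the drawn latency and relaxes with
time constant t_d. Defaults: responders peak ~N(180, 40) mm/s with
t_r = 20 ms, t_d = 35 ms and latency ~N(85, 8) ms, so pulses peak near
0.105 s — inside the 0.103–0.120 s window where the classifier looks;
non-responders peak ~N(15, 5) mm/s with a slower, broader shape. The true
pulse parameterization of the fish is unknown; these are modelling choices
tuned only to reproduce the qualitative single-peaked profiles and the
bimodal pooled histogram, not measured values.

Every trial also carries a per-trial *drift floor* (~N(8, 3) mm/s, combined
with the pulse by `max` so the true peak speed remains the drawn peak).
Real centroid tracks never measure exactly zero speed; without this floor
the pooled speed histogram develops a spurious spike at zero that defeats
any two-peak valley search. The floor forms the histogram's low mode, as in
real pooled data.

Positions integrate the speed pulse along a wandering heading
(Gaussian turns, sd 0.05 rad/frame). Step *i* has length v_i·dt, and a step
crossing the dish wall is split at the intersection with the heading
specularly reflected, so the emitted path length equals the speed integral
exactly (reflections are counted per trial; on reflected steps the stored
polyline shortens chords slightly, so conservation checks use
reflection-free trials). The centroid keeps a 4 mm wall margin — half a
~7 mm body plus clearance — so rendered silhouettes stay fully inside the
dish.

The default frame interval is dt = 0.017/6 s (≈353 Hz): the experiment's
frame rate is not published, but a 7-frame window spanning 0.103–0.120 s
fixes 6 intervals to 17 ms. At this dt the 0–0.157 s response interval
contains 56 frames.

### Feeding sessions

Swimming during feeding is modelled as discrete bouts: homogeneous Poisson
arrivals per segment (default 0.05 bouts/s without food, 0.25 with food)
with the same single-peaked pulse shape (t_r = 0.15 s, t_d = 0.3 s) and
peak speeds drawn per (treatment, age); the defaults make bout speed grow
with age more strongly under high maternal food, the ontogenetic pattern
the analysis should detect, while control-period bouts share one
treatment-independent speed spec. The supply interval (default 20 s between
the 300 s control and feeding periods) is contaminated with large erratic
disturbance speeds that the analysis must excise. Ground truth records the
bout list and the per-segment mean of the clean signal. Sessions are
generated at 50 Hz — feeding analyses need no high-speed sampling, and the
per-session frame rate is carried with the data, never assumed global.

### Cohorts

Dry mass (mg) and √body-fat follow linear models in treatment (LF=0/HF=1),
experimental day, day², age (0/7) and the treatment×day and treatment×age
interactions, plus a maternal random intercept and residual noise; body fat
is squared back to the measurement scale and lean mass is *derived* as
dry − fat so the trait additivity invariant holds by construction (the two
generated traits are the ones with reported slopes/transforms). Default day
slopes are −0.010 (LF) and −0.003 (HF) mg/day — the reported decline of
offspring dry mass — with intercept 1.40 mg, day² = −2×10⁻⁵, and age
effects giving modest first-week growth. The cohort has 50 mothers (the
study housed one female in each of 50 aquaria), delivering on twice-weekly
collection days across days 1–51 with probability 0.7 per mother-day
(~500 offspring, matching the study's ~590). The alive flag follows a
day-dependent logit (slope −0.065/day) and never censors traits — it is a
covariate in the exported design, as in the original analysis.

### Rendering

Fish are drawn as filled ellipses (length 7 mm — the average newborn body
length — aspect 0.35) centred on the true centroid, oriented along the
instantaneous heading, over a uniform bright field (grey 230) with dish
rims at grey 200, fish at grey 70, and optional additive Gaussian noise
before 8-bit quantization. The analytic centroid per frame is emitted as
ground truth; rasterized-silhouette centroids agree with it to < 0.1 px for
the default geometry.

## Tracking

Default segmentation is a direct dark-silhouette threshold ("backlit"
mode): Otsu's threshold on within-ROI intensities, keep pixels below it,
then the largest connected component within the area gate
(20–5000 px). This mirrors the LED-backlit recording geometry and — unlike
any temporal-background method — works for a fish that sits still, which
non-responders do for most of a 0.25 s startle clip (a median background
absorbs such a fish and biases its centroid by several pixels; this failure
is measured, not hypothetical). Median and high-quantile temporal
backgrounds with |frame − background| thresholding remain available for
scenes without a clean backlit field; the quantile variant (default q=0.9)
exists because a dark fish cannot contaminate a high quantile unless it
occupies a pixel in >10 % of frames.

Centroids are unweighted component means (an intensity-weighted option
exists; whether the original in-house tracker weighted by intensity is
unknown). Coordinates: image (row, col) are 0-based; physical coordinates
are mm with origin at the dish centre, x rightward, y downward. Gaps of at
most `max_gap` = 3 frames are linearly interpolated and flagged
`gap_filled`; longer gaps stay invalid rather than fabricating positions.
Scale comes from dish geometry (px_per_mm = 2·radius_px/diameter_mm),
cross-checked across dishes (CV < 5 %).

## Kinematics

Derivatives use Savitzky–Golay fits, default quadratic over 7 frames,
recorded in every profile's metadata; runs of valid frames shorter than the
window are invalidated with a warning, and frames within half a window of a
run edge are flagged lower-confidence. Acceleration is by default the
magnitude of the vector second derivative; a signed tangential option
(d|v|/dt) exists because "linear acceleration" is ambiguous on curved
paths (the two differ by the centripetal term — 40 mm/s² vs 0 on the test
circle). The robust extremum uses numpy's linear-interpolation quantile and
*strictly greater* comparison, falling back to the sample maximum when no
value exceeds the quantile (e.g. constant profiles); `summarize_kinematics`
additionally clamps v_max ≥ v_mean against 1-ulp rounding on constant
input. Ln transforms are applied only at export; stored values keep
physical units.

## Fast-start classification

The valley threshold builds a fixed-width histogram from zero
(bin 2 mm/s), smooths with a 3-bin moving average, takes the two most
prominent local maxima at least 3 bins apart (histogram padded so boundary
maxima count), and returns the bin-centre of the minimum count strictly
between them; ties resolve to the lower speed, and a histogram with fewer
than two peaks sets a fallback flag and returns the configured default of
60 mm/s. The threshold is estimated from the pooled experiment, not per
fish. Localization accuracy is limited by the counts in the valley: when
the two modes are far apart the intermodal region is nearly empty and the
argmin wanders over a flat stretch of near-zero density, so the estimate
scatters (behaviourally harmlessly — any threshold in the empty gap
classifies identically) even though detection of the two modes is reliable.

"Speed during a 7-frame window exceeded the threshold" is read as the
window *mean* by default — the most stable statistic — with "any frame"
and "all frames" selectable; the three rules are nested
(all ⊆ mean ⊆ any), response counts are non-increasing in the threshold,
and `sensitivity_sweep` crosses thresholds × rules to make robustness
checkable. Comparisons are strictly greater; a window clipped at the
response-interval edge is used clipped and flagged; a window with no valid
frame leaves the trial unclassifiable rather than defaulted.

## Feeding analysis

Frames are assigned to control/supply/feeding by half-open [start, end)
intervals on the timestamp, so the four classes (including out-of-window)
partition the recording with no double counting; supply frames enter no
summary, making results provably invariant to disturbance magnitude. The
feeding period starts at supply end by default (whether timing restarted
after supply is unknown; the events are inputs, not constants). The supply
duration is likewise an input.

## Cohort estimator

The original analysis fits Bayesian multivariate mixed models; refitting
them is out of scope here — packaged samplers do that, and the package's
contract is the design/transform layer plus a transparent recovery check.
The desk-scale estimator regresses each treatment arm's trait on
(day, day², age) after mother-mean centring, which removes maternal
intercepts exactly (so σ_mother never biases the slope), and reports the
day coefficient per arm and the LF−HF contrast. Uncertainty comes from
resampling mothers — the top-level cluster — with replacement; because each
mother's demeaned normal-equation block is invariant under resampling, the
bootstrap sums precomputed per-mother Gram matrices, making 1000 replicates
take milliseconds. Percentile intervals are widened, if necessary, to
bracket the point estimate. With ~25 mothers per arm the percentile cluster
bootstrap undercovers slightly (measured ~0.90–0.93 for a nominal 0.95
under a zero-interaction generator), a known property of percentile
intervals at modest cluster counts.

## Problem sizes used in tests

The test suite and acceptance script run entirely on generated data:
270-trial startle sets (90 or 207 fish), 100-seed threshold-recovery
batches at 15,120 pooled speeds (270 trials × 56 window frames), 20-seed
9-dish imaging round trips at 4 px/mm, 10-min feeding sessions at 50 Hz,
and 200-cohort recovery batches with 200 bootstrap replicates. These sizes
mirror the emulated study's scale.

## What passing tests do and do not show

The generator captures the design's statistical skeleton: mixture structure
of responses, bout-driven activity with an excisable disturbance, trait
trajectories with maternal clustering, and rendered silhouettes with exact
ground truth. It deliberately omits body bending and posture (centroid
kinematics only), prey items and capture success, hydrodynamics, occlusions
and reflections at the dish wall, illumination gradients, and habituation
beyond the trial index. Passing the round trip therefore validates the
chain's correctness on clean, well-posed scenes; it does not certify
performance on real video with touching fish, debris, or uneven lighting.

## Known limitations

- Valley localization in near-empty intermodal gaps is noise-dominated
  (see above); report the histogram alongside the threshold.
- The specular wall reflection slightly shortens stored polyline chords on
  the rare reflected step, so speed-integral/path-length equality is exact
  only away from the wall.
- The slope estimator handles one trait at a time and ignores residual
  correlation between traits; it is a recovery check, not a replacement
  for the multivariate mixed model.
- The backlit segmentation assumes one dark fish per dish; multi-animal
  identity maintenance is out of scope.
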