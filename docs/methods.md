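# Methods

This note documents the models, conventions and design choices behind
`gaitcog`, in the spirit of a model-description appendix: what each stage
computes, which knobs matter, and what the synthetic data does and does not
establish about real recordings.

## Signal model and preprocessing

A recording is a uniformly sampled shank motion signal (one axis, or three
axes from which one is selected) for one subject, foot and task. The analysis
chain is fixed in order: **trim → resample to 200 Hz → median filter
(window 5) → 4th-order Butterworth low-pass**.

- *Trimming* is an explicit input (start/end seconds): in clinical practice
  the walk is cut out of a longer recording by hand, and the package mirrors
  that rather than auto-detecting walk bouts.
- *Resampling* uses polyphase anti-aliased decimation for any rational
  ratio ≥ 1 (e.g. 8 kHz → 200 Hz). Upsampling is refused: event timing at
  better than 5 ms resolution would be an illusion.
- *Butterworth cutoff*: 10 Hz by default (configurable). Human gait energy
  in shank signals lies below ~10 Hz; the cutoff only needs to sit between
  the gait band and the noise band.
- *Zero-phase filtering* (forward–backward) is used so that peak and trough
  timestamps are not lagged by the filter group delay; a causal 4th-order
  filter at 10 Hz would shift events by tens of milliseconds and bias every
  duration built from them. The effective magnitude response is the squared
  8th-order one, which is immaterial for event timing.
- *Median edge handling* uses reflect padding to avoid fabricating boundary
  extremes.
- *Axis selection* for 3-axis files defaults to the axis with the greatest
  variance over the walk — during straight walking the sagittal-plane axis
  dominates — and can be forced explicitly.

## Gait events

On the smoothed signal, each gait cycle presents one dominant positive peak
(max swing velocity, MSV) flanked by a toe-off (TO) trough before and a
heel-strike (HS) trough after. Detection finds local extrema whose amplitude
*and* prominence both exceed `min_prominence_frac` (default 0.5) times the
SD of the mean-centered signal, separated by at least `min_separation_s`
(default 0.25 s, shorter than any plausible half-stride even at fast walk).
The amplitude criterion matters: the flat stance phase between an HS trough
and the next TO trough forms a shallow local maximum that is *prominent*
relative to its flanking troughs but sits near the baseline; requiring
amplitude ≥ the threshold rejects it.

Labeling assigns each surviving peak the nearest preceding trough as TO and
nearest following trough as HS. Peaks without both flanking troughs
(incomplete leading/trailing cycles) are dropped, as are cycles that would
reuse the previous cycle's HS trough, so the output always satisfies
TO(n) < MSV(n) < HS(n) < TO(n+1). Fewer than two complete cycles is an
error. When two troughs are equally plausible the nearest in time to the
MSV peak wins, consistent with the flanking-trough reading of the waveform.

## Temporal parameters

With cycles indexed by n:

- swing(n) = HS(n) − TO(n) — k values for k cycles,
- stance(n) = TO(n+1) − HS(n) — k−1 values,
- stride(n) = MSV(n+1) − MSV(n) — k−1 values.

These telescope: stride(n) = swing-ish + stance(n) up to the MSV anchor
position inside the swing phase, so stride ≈ swing + stance within two
sample periods on any consistent series.

**Turn removal.** The mid-walk turn produces one anomalously long
pseudo-stride (and a matching long stance). Durations deviating more than
2 sample SDs from the series mean — mean and SD computed once over the
unfiltered series, sample (n−1) SD — are flagged, independently per series.
The rule is single-pass (not iterated) and leaves series with fewer than 3
values untouched. Note that on an otherwise near-constant series a 2-SD rule
will also flag the occasional extreme ordinary stride; that is inherent to
the rule, and the summary row reports the total count removed.

**Velocity.** 20 m divided by the total walking time. By default the total
walking time is the trimmed recording duration, which *includes* the turn;
this is the convention a stopwatch over the whole task would give, and it
systematically deflates velocity by roughly the turn duration over the walk
time (~15% at normal pace). `summarize(..., velocity_from="events")` uses
the first-TO-to-last-HS span instead. The default was chosen because manual
trimming to the task is the only boundary the protocol defines; nothing
downstream depends on which convention is used, since the velocity–cognition
coupling is monotone under both.

**CoV.** 100 × sample SD / mean of the retained stride times (percent).
Sample (n−1) SDs are used everywhere a convention is unstated.

## Multiscale entropy and the complexity index

Coarse-graining at scale τ replaces the series by non-overlapping block
means of length τ (remainder dropped), giving ⌊N/τ⌋ points. Sample entropy
SE(m, r) = −ln(A/B), where B counts ordered template pairs of length m
within Chebyshev distance r (self-matches excluded) and A the same pairs
extended to length m+1; both counts use the N−m start positions. Units are
nats. Defaults m = 2 and r = 0.2, with r interpreted as a fraction of the
SD of the *scale-1* series; the resulting absolute tolerance is reused at
every scale (the standard multiscale-entropy convention), which makes the
complexity index exactly invariant to affine rescaling of the input.

The curve runs over τ = 1…40 ("40 scales"): scale 1 is the original signal
and scale 40 the most granulated series. A 20 m walk at 200 Hz yields
3,000–4,000 samples, so even scale 40 retains ≥ 75 points. Scales whose
coarse series is shorter than 10·m points, or where A = 0 (no extended
match), are marked invalid, excluded from the area, and warned about —
excluding them keeps ±∞ out of the index; imputation was rejected as
invented data. The complexity index is the trapezoidal area of SE over the
valid scales (scale axis in units of τ); at least two valid scales are
required. The index is computed from the trimmed, 200 Hz, *unfiltered*
signal, since smoothing would strip exactly the fast fluctuations the
entropy is meant to see.

## Synthetic walks and cohort

The generator emulates the study conditions, not shank biomechanics:

- **Waveform.** Each cycle is a sum of three Gaussian lobes on a zero
  baseline: a positive MSV lobe (σ = 0.10 swing) mid-cycle and two negative
  troughs (σ = 0.05 swing, depth 0.6 of the MSV amplitude) at ±swing/2.
  The shape is configurable; nothing downstream depends on it beyond the
  peak–trough–peak morphology.
- **Timing.** MSV times are laid down as a renewal process with stride
  times T·(1 + jitter·ε), ε ~ N(0,1), so the true stride-time CoV equals the
  requested `stride_jitter_cov` exactly. Swing is held constant within a
  walk and the cycle is anchored at MSV; the jitter is therefore carried by
  stance, and stride = swing + stance holds exactly (up to snapping of all
  event times to the sample grid, which lets noise-free detection recover
  them to the sample).
- **Distance bookkeeping.** The stride count is the nearest integer to
  20 m/(v·T) and the nominal stride time is rescaled (≤ ~2.5%) so that with
  zero jitter the total walking time is exactly 20 m / v.
- **Turn.** A single low-amplitude (0.1 × MSV) sway bump of 3 s between the
  two 10 m halves, deliberately below the detection threshold: downstream it
  appears as exactly one long MSV-to-MSV pseudo-stride, which is what the
  2-SD rule removes. Modeling the turn with its own detectable peak would
  split it into two moderate outliers instead and change the rule's target.
- **Cohort defaults** encode the two study groups (44 controls, 94 T2DM)
  with per-task velocity/swing/stance/jitter distributions in which the T2DM
  group is ~0.2 m/s slower with longer strides, carries a higher additive
  noise level (0.08 vs 0.05 of the waveform amplitude — the driver of a
  higher complexity index), greater BMI, and covariate distributions (age,
  sex, education) matching the recruited groups. The T2DM normal-walk
  velocity SD is set to 0.17 m/s, consistent with all other velocity SDs.
- **Cognition.** MoCA = 15.9 + 3.0·(v_normal + v_fast + v_dual) + ε,
  ε ~ N(0, 1.5), +1 point for ≤12 years of education, truncated to [0, 30]
  and rounded *last* (rounding first would attenuate the calibrated
  correlation). The linkage of 3.0 MoCA points per m/s per task was derived
  once from the group moment algebra to put the pooled Pearson correlation
  between normal-walk velocity and MoCA near 0.4 (moderate band, 0.3–0.5) at
  n = 138. MoCA subdomains are drawn from group-specific distributions;
  CANTAB z-scores carry only a weak (r ≈ 0.15, sub-threshold) velocity
  coupling, so screening correctly leaves them unselected.

What passing tests on this generator do **not** establish about real data:
the waveform is noise-plus-lobes, with no double-support dynamics, no
sensor drift or gravity component, no missed/extra real-world peaks from
shuffling or turning hesitations, and left/right feet differ only by a 2%
velocity factor and independent jitter. Event-recovery rates and screening
patterns on real recordings must be validated separately.

## Cohort statistics

Normality of each group is tested by Shapiro–Wilk at α = 0.05; both normal →
unpaired two-sided t-test, otherwise Mann–Whitney U (two-sided). Constant
samples are treated as non-normal; degenerate variance in both groups is an
error. Covariate-adjusted group effects come from OLS of the gait variable
on a T2DM indicator plus age, sex, BMI and education, with Wald 95% CIs;
collinear designs are rejected rather than silently dropped.

Screening computes pooled-cohort (both groups together) Pearson r for each
gait variable × cognitive score cell via the covariance formula (verified
against `scipy.stats.pearsonr` in tests), and selects |r| ≥ 0.3, inclusive.
The threshold is a correlation-coefficient bound: a squared-correlation
reading of a ±0.3 band is not satisfiable, and the velocity–MoCA
correlations (~0.33–0.47) that motivate the band are r values. Raw r is
reported with no multiple-testing correction; cells with constant columns or
fewer than 3 complete pairs carry NaN and are never selected.

## Cognition models and validation

**MLR.** OLS of MoCA on the six velocities with intercept; 95% CIs for all
seven parameters. The reference coefficient set (5.74, −4.39, 1.03, 0.61,
1.01, 1.21; intercept 21.2) is shipped as `reference_predictor()` for worked
examples; the opposite-signed left/right pair is the signature of nearly
collinear per-foot velocities and is reproduced qualitatively by fits on the
synthetic cohort.

**Network.** Widths n, n−1, …, 2, 1 (for n = 6: 85 weights+biases), sigmoid
at every node including the output, MSE loss, full-batch Adam at the default
learning rate 0.001. Inputs are z-standardized; since a sigmoid output lives
in (0, 1), the target is min–max scaled into (0.05, 0.95) on the training
split and predictions are inverse-scaled before MAE. Training runs at most
10,000 epochs with early stopping: patience 50 on the validation MSE,
best-validation weights restored; non-finite loss aborts. All randomness
flows through a seed, so training is bit-reproducible.

**Validation.** "20-fold validation" is implemented as 20 independent random
80/20 holdouts (not a k-fold partition): per repeat, the 20% holdout both
drives the network's early stopping and provides the MAE, and the 20
holdout MAEs give the mean and a t-based 95% CI. Complete-case rows only.
Rows are put into a canonical (lexicographic) order before splitting so the
report does not depend on how the cohort table was sorted. The standardizer
and target scaler are fit on the training split only (leakage-free); a
whole-dataset standardization can be had by standardizing before calling.
Model comparison uses the 20 paired per-repeat MAE differences with a
t-based 95% CI; "ns" when the CI covers zero. On linearly generated cohorts
the network does not beat the linear model — the expected outcome, since the
truth is in the MLR's hypothesis class.

## Pipeline and reproducibility

`run_pipeline` chains simulate (or load) → preprocess → events → temporal →
complexity → screening → model validation, writing delimited tables plus a
manifest of every stage's parameters and seeds. Per-stage seeds are derived
from the master seed combined with the CRC-32 of the stage name, so adding a
stage never changes earlier stages' draws. Two runs with the same config and
master seed produce byte-identical tables. Default cohort size for a demo
run is 12 subjects (72 walks), which keeps a full run under a couple of
minutes on one core; all defaults scale.

## Known limitations

- The generator's waveform and turn model are deliberately minimal; event
  detection tuned here may need different prominence/separation defaults on
  real shank data, where signal morphology varies with sensor placement.
- Velocity-including-turn deflates absolute speeds relative to stride-level
  speed; comparisons across conventions require the `velocity_from` switch.
- Sample entropy is O(N²) memory/time per scale; fine at walk lengths
  (≤ 4,000 points), not intended for hour-long recordings.
- The reference predictor's printed third slope (1.03) lies outside its own
  reported CI [1.79, 3.83]; only the point estimates are used here.
- No spatial gait parameters (step/stride length) — the single-shank setup
  cannot produce them.
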