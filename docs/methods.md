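# Methods

This note documents the models and procedures implemented in twitchlab,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not establish about real recordings.

## Scope and data model

The package analyzes head-fixed infant-rodent sessions in which behavior
cycles between NREM sleep, REM sleep and wake. Times are float seconds from
session start; frame indices are 0-based; every interval and histogram bin
is half-open `[start, end)`. Behavioral states are `NREM`, `REM`,
`quiet_wake` and `active_wake`; a state timeline partitions the session
span exactly, with no gaps or overlaps. Movement events carry an onset,
body part (forelimb, hindlimb, whiskers, tail, or whole-body ROI), a class
(`twitch`, scored only in REM; `wake`, scored only in wake) and optional
kinematics.

## Video synchronization

An LED pulses every 3 s for 100 ms in the camera's view; at the nominal
100 frames/s every inter-pulse gap must contain exactly 300 frames. Gaps
with fewer frames indicate dropped frames and receive that many dummy
frames. Two sub-decisions were open:

- *Placement*: dummies are appended at the gap end (evenly spaced between
  the last observed frame and the gap boundary). Observed timestamps are
  never moved. With at most one drop per 3 s gap — the realistic regime,
  since drops are rare — every frame index stays within one frame (10 ms)
  of its pulse-linear position. A gap that lost d frames can drift by up to
  d frames for the frames after the drops, since drop positions inside a
  gap are unobservable.
- *Surplus frames*: a gap with more frames than expected has no analogous
  repair and raises an unrecoverable-clock error.

Repair is idempotent; pose-table rows (one per captured frame) are mapped
to time through the non-dummy frames of the repaired clock.

## Movement detection and behavioral scoring

ROI pixel-change series (counts of pixels changing intensity by more than
5%, per frame at 100 Hz) drive detection. A candidate movement starts at
the first frame strictly above threshold and ends when the series falls
below it. The original procedure confirmed candidates manually from video;
as an automatic stand-in the threshold defaults to median + 3 × scaled MAD
of the series (configurable, logged) and bouts shorter than 2 frames are
discarded as sensor noise. Whisker candidates closer than 100 ms are
collapsed into the first, since whisker protraction/retraction cycles lack
clean boundaries.

Wake-movement onsets keep only candidates preceded by at least 500 ms of
quiescence (inclusive), measured from the end of the previous candidate —
a greedy-from-left rule whose output is maximal. Twitch isolation for
somatotopy keeps twitches with no other-body-part twitch within ±100 ms
(`cross_bodypart`); displacement and kinematic analyses additionally
require 100 ms to same-body-part neighbors (`same_bodypart`), because
overlapping excursions corrupt single-event amplitudes.

State scoring is a rule-based classifier over a nuchal-EMG tone trace and
a cortical delta-power trace on a shared time base: REM = atonia bouts
(tone below its 20th-percentile threshold) containing twitch candidates;
NREM = delta above its 70th percentile with behavioral quiescence;
everything else wake, with samples within 3 s after a movement labeled
active wake. Quantile thresholds stand in for expert visual scoring, which
has no published numeric rule; comparisons are strict so constant
(degenerate) traces trigger neither sleep rule. On synthetic sessions with
matched feature traces the classifier recovers ≥90% of time-weighted state
labels (tested), which validates the rule logic, not the realism of any
particular threshold on real EMG.

EMG event inclusion requires the rectified trace to reach z ≥ 2.0
(inclusive) relative to a per-event pre-onset baseline window (default
−1.0..−0.2 s). Grand-mean EMG profiles are two-stage: mean within animal,
then unweighted mean across animals, so animals with many events do not
dominate.

## Perievent analysis

Histograms use a −3..3 s window with 10 ms bins (600 bins); counts are
binned half-open relative to each onset. The trial-mean trace (spikes/bin)
is z-scored against the mean and standard deviation of its baseline bins
(−3..−0.5 s). An open choice: the baseline SD is taken across baseline
bins of the *mean* histogram, not across per-trial counts — the
alternative shrinks z magnitudes by roughly √n_events and is not what a
histogram-level criterion implies. Neurons whose baseline SD is zero are
unclassifiable.

Movement-active classification is exactly the threshold rule: max z ≥ 3.5
inside −100..250 ms (twitch) or −100..500 ms (wake), with no additional
shape test, requiring strictly more than 20 events (`min_events = 21`);
fewer events yield an `insufficient_events` status rather than
"inactive". The preferred body part is the argmax of super-threshold peak
z over isolated-twitch histograms; ties break to the earlier peak time,
then lexically, and are logged (ties are measure-zero in practice).

The false-positive rate of the z ≥ 3.5 rule under a homogeneous-Poisson
null depends on the baseline rate: at low rates per-bin counts are small
and Poisson skewness fattens the upper tail of the z-trace. The null
calibration is therefore run at the generator's default REM baseline of
13.1 spikes/s, where the acceptance suite requires (and the script
reports) a rate below 5% at 100 events per neuron.

## Temporal metrics

- **Peak latency**: bin-center time of the z maximum in the response
  window; ties go to the earlier bin. Bin centers make the estimate
  unbiased under 10 ms binning; resolution is one bin.
- **Width at half-height**: smooth with a 5-bin kernel, upscale 10 ms →
  1 ms by linear interpolation, normalize baseline → 0 and peak → 1, count
  the contiguous run of 1 ms bins above 0.5 containing the peak. The
  kernel shape was unspecified; a boxcar (moving average) is used, with
  edge-shrinking normalization. Interpolation is linear (the default of
  the interpolation routine the procedure names).
- **Premovement proportion (twitch)**: trapezoidal integral of z over
  [−0.2, 0] divided by the integral over the analysis window (−0.2..0.2 s
  for region comparisons, −0.2..0.75 s for developmental ones). Integrals
  interpolate the piecewise-linear z-trace at the exact bounds — stopping
  at bin centers loses the half-bin adjacent to onset, where premovement
  kernels concentrate mass, and biases the proportion low by several
  percentage points. Negative numerators clamp to 0; non-positive
  denominators leave the metric undefined and the neuron excluded.
- **Premovement proportion (wake)**: pre-onset activity is contaminated by
  earlier movements, so the baseline is re-zeroed at the minimum of the
  20-bin-smoothed histogram in the 500 ms before onset, and the window
  runs from that minimum to +1 s. The numerator is taken over
  [window start, 0]; the interaction between the two published window
  descriptions is ambiguous and this reading is flagged here rather than
  silently resolved.
- **Fano factor**: sample variance (n−1) over mean of per-event counts in
  −70..70 ms (twitch) or −100..500 ms (wake) windows; undefined at zero
  mean.

## Kinematics and tuning

Movement origin is the limb position at the onset frame; amplitude is the
maximum Euclidean displacement within 150 ms (twitch) or 500 ms (wake),
converted at 5.75 px/mm; the angle is the direction of the onset→peak
vector in math convention (counterclockwise from +x, 0° = forward), with
image y negated. A config switch (`angle_mode="path_mean"`) instead takes
the circular mean of per-frame onset→position vectors up to the peak,
since the published phrasing supports either reading; at-peak is the
default. Zero-amplitude movements have no angle.

η² uses the grand-mean one-way decomposition over 12 equal 30° bins with
empty bins dropped; all-equal counts give 0 and fewer than two occupied
bins leave it undefined. r² is the squared Pearson correlation (identical
to simple-regression R² with intercept); zero count variance gives 0, zero
amplitude variance is undefined. Selectivity uses strict > 0.1. The
preferred/non-preferred split is inclusive at both boundaries
(count ≤ 0.5 × expected; count ≥ 1.5 × expected) — the only reading
consistent with thresholds of "2 or fewer" and "6 or more" at an expected
count of 4.

Pose points with likelihood below 0.85 are flagged, not dropped: the 0.85
figure is a network-retraining criterion, not a per-point filter.

## The synthetic-session generator

The generator defines the study conditions under which the pipeline is
validated; its defaults are fixed, not tuned per experiment:

- **States** cycle NREM → REM → wake with exponential dwell times (means
  60/45/60 s — infant sleep cycles are short), truncated to partition the
  session exactly.
- **Events**: twitches are Poisson per body part (0.3 events/s per part
  during REM; 0.5 in recovery experiments) restricted to REM; wake
  movements are Poisson candidates (0.2–0.5/s) thinned to ≥500 ms spacing.
  NREM carries no events by construction. Poisson placement is an
  assumption; real inter-twitch intervals beyond the 100 ms isolation rule
  are uncharacterized.
- **Spikes** are inhomogeneous Poisson: a state-dependent baseline
  (defaults 13.1 spikes/s REM, 7.2 wake, 5 NREM — the first two are
  published region values used as realistic parameters) plus, per event, a
  skew-normal rate kernel of area `gain` whose mode sits at the response
  latency and whose shape parameter is solved numerically so the kernel
  mass before onset equals `premove_fraction`. This makes the
  premovement-proportion metric directly checkable against a single
  ground-truth number. Feasibility is geometric: a kernel peaked
  `latency` after onset with scale σ can place at most `2Φ(−latency/σ)` of
  its mass before onset; infeasible requests raise an error (the solver
  brackets on an α grid because mode-pinning makes the pre-onset mass
  non-monotone in α near that bound). Rates are discretized at 1 ms and
  realized as per-bin Poisson counts with uniform within-bin jitter —
  exact for the discretized rate.
- **Kinematics**: von Mises angles (default μ = 129°, κ = 1) and
  log-normal amplitudes with class means 0.96 mm (twitch) and 6.95 mm
  (wake), σ_log = 0.5. Trajectories realize each event as a triangular
  excursion — exactly zero at the onset frame and exactly the drawn
  amplitude at the mid-window peak frame — so amplitude ground truth is
  representable on the frame grid. A smooth profile sampled on that grid
  would leak displacement into the onset frame (shifting the extraction
  origin) and place its peak between frames, biasing recovered amplitudes
  low by several percent.
  Gaussian positional noise (0.3 px) and a likelihood column complete the
  pose table.
- **Tuning**: direction-tuned neurons scale wake-event kernel gain by
  `exp(κ_t (cos(θ−μ_t) − 1))` (peak 1 at the preferred direction) and
  amplitude-tuned ones by `1 + slope × amplitude`. Note the two interact:
  strong direction tuning inflates count variance and dilutes the
  amplitude r² at small n, which is why tuning recovery is specified at
  ~400 movements.
- **Pixel series and frame clock**: events add decaying count pulses
  (5 frames twitch, 40 wake) on Poisson noise (λ = 2); frames drop
  independently at `dropped_frame_prob` with pulse times every 3 s.

Determinism: one seed fans out to per-stage generators through a seed
sequence; identical parameters give bit-identical sessions, and the CSV
writers/readers round-trip floats exactly (`%.17g` out, round-trip parsing
in).

What passing recovery tests shows: the analysis correctly inverts the
generative model at realistic rates and event counts. What it does not
show: robustness to non-Poisson spiking, EMG artifacts, tracking failures,
camera occlusion, or expert-scoring disagreements — none of which the
generator emulates. Pixel-change series are generated directly; no video
is rendered.

## Statistics

Group inference dispatches to classical tests (one-way ANOVA, two-sample
or paired t, χ² without continuity correction — the procedure names no
correction) with Bonferroni adjustment within each post-hoc family, capped
at 1, at α = 0.05. The scaled-MAD outlier rule flags points more than
3 × 1.4826 × MAD from the median; exclusion is single-pass and intended
for summary displays only — tests always run on full data.

## Problem sizes

Validation experiments use 2400 s sessions (~300 forelimb twitches, ~250
isolated, ~150–200 wake movements), dedicated single-state sessions of
~1000 events per class for amplitude means, 1000 null neurons at 100
events for classification calibration, and 1000 replicates for the ANOVA
null — sizes at which sampling error is comfortably inside the recovery
tolerances (one 10 ms bin for latency; ±0.05 for premovement proportions;
5% for amplitude class means).

## Known limitations

- Theta-oscillation features of older pups' REM sleep are not modeled or
  used in state scoring.
- The ROI threshold, tone and delta quantiles are explicit stand-ins for
  manual scoring; on real data they need per-session review.
- Surplus video frames are treated as unrecoverable rather than trimmed.
- Spike sorting, unit quality control and pose-network training are out of
  scope; spike tables and pose tables are taken as given.
- Session inclusion (more than 40 forelimb twitches and at least one
  twitch-active neuron) is enforced in the pipeline but meaningful only
  when sessions are long enough for the event counts to be informative.
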