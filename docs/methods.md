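# Methods

This note documents the statistical procedures, the synthetic-data model
behind the test suite, and the numerical and design choices that were
genuinely open.

## Ensemble identification

The tuning statistic for neuron *n* is s(B, Cₙ) = 2B·Cₙ/(|B|² + |Cₙ|²),
with B the frame-wise 0/1 annotation of one behavior and Cₙ the neuron's
nonnegative trace. By the AM–GM inequality s ∈ [0, 1] for nonnegative
inputs, with equality to 1 iff B = Cₙ. Before the statistic, each trace is
min–max scaled to [0, 1] per neuron; this guarantees the stated range, puts
B and C on a common amplitude scale, and makes classification exactly
invariant to per-neuron trace rescaling (the 0/0 case of a constant trace
maps to the all-zero vector and ends up labeled Other through tie handling).

The chance distribution is built by shuffling behavior *epochs*: the maximal
runs of 1s keep their durations, are randomly re-ordered, and are placed at
random non-overlapping positions (≥ 1 frame apart, so the epoch count is
conserved; cumulative gaps are drawn as sorted uniform integers, which is
exactly uniform for a single epoch and indistinguishable from uniform at the
epoch densities of these sessions). Preserving epoch structure preserves
the regressor's autocorrelation, which frame-wise permutation would destroy.
A circular frame-shift null is available as a config switch
(`null_method="circular"`), since whether gaps were preserved in the
original procedure is not documented. For binary B, B·C is the sum of C
over ON frames, so each shuffled similarity costs only one cumulative-sum
lookup per epoch; a test verifies this shortcut against direct evaluation
on explicitly shuffled vectors.

Labels use the empirical 0.83% / 99.17% order-statistic quantiles (linear
interpolation) of 5000 shuffles with strict inequalities; ties fall to
Other. Under a continuous null this implies P(ON) ≈ P(OFF) ≈ 0.0083 per
behavior, which the calibration test checks with a 99% binomial band on 200
untuned neurons. Each (neuron, behavior) pair draws from an independent,
order-invariant substream of the top-level seed.

One structural property worth knowing: with two mutually anti-correlated
behaviors, a neuron whose tonic activity is suppressed during reward epochs
is genuinely *relatively elevated* during poking epochs compared with its
own epoch-shuffle null, and can be labeled Poking-ON as well as Reward-OFF.
ON and OFF sets for the *same* behavior are mutually exclusive by
construction; cross-behavior labels are reported independently, and planted
poking-tuned and reward-tuned ON classes recover without crosstalk in the
acceptance suite.

## Subensembles

"ON response in a trial type" is operationalized as a permutation test: the
observed mean windowed z-score over that trial type's windows is compared
with means recomputed after resampling from the pooled trial windows and
same-length baseline windows (baseline = all frames outside every annotated
epoch), at α = 0.05 with 1000 draws. This is the central interpretive
decision of the module — the original criterion is not documented — and a
threshold-on-mean-z rule is available via `SubtypeConfig(rule="threshold")`.
Fewer than 3 trials of a type yields "untestable", never a silent negative,
and untestable flags propagate to Unclassified.

Trigger-like vs Visual-stim discrimination uses the sign of the median
detected-event time relative to poke onset (events attributed to a poke
within ±2 s). Poking-aligned responses use the poking window (−0.5→1.5 s,
aligned to poke onset); reward-aligned responses use the reward window
(−0.5→3.5 s) aligned to water delivery on correct trials and to the
(unrewarded) choice lick on incorrect and licking-only trials.

Previous-outcome modulation excludes the first trial and any trial whose
predecessor was neither correct nor incorrect, compares after-correct vs
after-incorrect means with a two-sided permutation test, and accepts a
trial slice for split-half comparisons. Port preference is the analogous
two-sided side-label permutation test on correct-trial responses at
α = 0.05.

## Spatial statistics

Global Moran's I with w_ij = 1/d²_ij, w_ii = 0, computed exactly as the
double sum (verified against a naive O(N²) oracle to 1e−12). Duplicate
centroids and constant membership vectors are rejected. I is invariant to
translation, rotation and uniform scaling of coordinates, so pixel units
and micrometers (2.75 μm/px) give identical values. Significance comes from
(a) a label-permutation test, default 999 permutations, two-sided rank
relative to E[I] = −1/(N−1), and (b) the analytic z under the randomization
assumption (Cliff–Ord moments); the original workflow used a GIS package
for this step, which is replaced here by these two reproducible routes.

## Decoding

SGDClassifier (hinge loss, default regularization, tol = 1e−3) predicts the
behavior indicator per frame. Folds are frame-wise uniform random splits
per the stated procedure; because frame-wise splitting of autocorrelated
traces leaks temporal information across the train/test boundary, a
contiguous-block option (`split="blocks"`) is provided for users who want a
conservative estimate. Balanced accuracy is the mean of the two class
recalls per fold, averaged over folds ("percentage of accurate
classification incidence" is ambiguous; this reading gives the documented
anchors: 0.5 for any constant or uninformative predictor, 1 for perfect
classification). A held-out fold containing a single class (not observed at
these session lengths) would be scored by plain accuracy of that class.
Class weighting is off since balanced accuracy already compensates.

Shuffle controls permute each designated neuron's trace independently over
frames, preserving its value distribution. The size-balanced control
subsamples ON to |OFF| ten times and reports the mean.

## Synthetic sessions

The generator emulates the recording and task structure the analyses
assume: 10-Hz frames, ~100 self-initiated trials per session, outcome
probabilities 0.70/0.15/0.10/0.05 (correct/incorrect/omission/licking-only),
reaction time Uniform(1.5, 3.0) s between poke and side choice, 10-s
timeout after incorrect choices, 20-s omission limit, inter-trial gap
Uniform(2, 5) s, and 5 s of quiet recording at the session edges. The
reaction-time floor of 1.5 s reflects the task geometry (the animal must
leave the center port and reach a side spout) and keeps the poking window
(−0.5→1.5 s) and reward window (−0.5→3.5 s) disjoint in time, as they are
in the task.

Traces are event trains convolved with a unit-peak difference-of-exponentials
kernel (rise 0.1 s, decay 1.0 s — a GCaMP6f-like shape; the indicator
kinetics of the original recordings are not parameterized anywhere, so these
are package defaults, not measurements). Event amplitudes are the spec'd
response amplitude with ±20% uniform jitter; additive Gaussian noise
(SD 1.0 DF/F unit) is applied and the trace is shifted by its minimum so
DF/F ≥ 0, which keeps the similarity statistic in range. Planted amplitudes
are therefore approximately z-units. Spike latencies are class defaults
(Trigger-like −0.5 s pre-onset so that the transient *peak*, which lags the
spike by ≈0.26 s and is what event detection marks, falls before poke
onset; Attention-like +0.2 s; Visual-stim +0.4 s; Reward-pursuing +0.1 s
after the choice lick; Rewarded +0.2 s after delivery, sustained 2 s).
OFF classes carry 1-Hz tonic events deleted inside the matching behavior
epochs plus a one-decay-constant fringe. ROI centroids scatter uniformly in
a 400×400-px field (2.75 μm/px), with an optional cluster knob for positive
Moran's I fixtures. Previous-outcome gains multiply amplitudes on trials
following a correct trial (first trial excluded); port bias multiplies
left-port reward responses.

Two-stage recordings draw a tracked subset (default 67% of stage 1), assign
stage-2 classes per a retention matrix (rows must sum to 1; the default
keeps 60% in class, sends 30% to untuned, and never switches directly
between poking- and reward-tuned classes), and re-simulate stage 2 with an
offset seed.

What the generator does *not* model: photobleaching, drift, motion
artifacts, demixing errors, correlated noise across neurons, and behavioral
nonstationarity. Passing tests therefore demonstrate the statistical
machinery — calibration of the nulls, recovery at stated effect sizes,
decoder anchors — not robustness to those real-data pathologies.

## Event detection

Calcium events are local maxima of the zero-phase low-pass-filtered trace
(second-order Butterworth, 1 Hz) whose topographic prominence exceeds
k·MAD with k = 3, where MAD is the normal-consistent median absolute
deviation of the *raw* trace (a robust noise-SD estimate that the transients
themselves barely move). At these settings filtered-noise bumps reach
≈2.6 noise SD, so the 3-SD threshold rejects them while a 10-SD transient
is detected with its peak within ±0.5 s. A minimum inter-event distance of
one kernel rise time prevents double-marking a single rising phase.

## Problem sizes and numerical choices

The permutation default is 5000 shuffles (production); calibration and
recovery suites run at 1000 and the pipeline demo at 500, sizes at which the
quantile thresholds are stable to well under the band widths being tested.
The acceptance script uses a 100-neuron, 6000-frame session for the decoder
anchors (20 seeds for the chance level), 1000 label permutations on a
500-neuron map for the Moran mean, and 1000 random pairs for the similarity
bound. Windows are closed at both ends in frames with seconds converted by
round(t·rate); edge trials whose window crosses the session boundary are
excluded from peri-event tensors and reported, never silently dropped.

## Known limitations

- The similarity statistic is amplitude-sensitive by design (s(B, αC) < 1
  for α ≠ 1 when B = C); classification is nonetheless scale-free because
  the null is computed per neuron on the same preconditioned trace.
- Frame-wise CV folds overestimate absolute decoding accuracy on
  autocorrelated traces; the shuffle controls and configuration *contrasts*
  are the meaningful quantities.
- Subtype rules assume the session annotates exactly the poking and reward
  behaviors; additional behaviors enter identification but not subtyping.
- The permutation significance of Moran's I conditions on the observed
  centroid configuration; very close ROI pairs dominate the inverse-squared
  weights and fatten the null's tails, which the permutation test (unlike
  the analytic z) handles correctly.
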