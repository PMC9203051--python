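# Methods

This note documents the models, estimators, and numerical choices behind
`valencecode`, and what the synthetic-data tests do and do not establish
about real recordings.

## Task and data model

The analyzed experiment presents a fixed set of conditioned stimuli — by
default five odors paired with graded outcomes (strong airpuff, weak
airpuff, nothing, small water drop, large water drop) — to head-fixed,
water-restricted mice while neurons are imaged at 5 Hz.  Each trial is a
6 s peri-trial window: time 0 at window start, stimulus onset at 1.0 s,
outcome at 2.3 s (1.3 s stimulus→outcome delay), stimulus duration 1.5 s.
All windows are half-open `[start, end)`; frames are 0-based with frame
`f` stamped at `f / rate`.  Thirty trials of each type are delivered per
training day, randomly interleaved under the constraint that each half of
the session contains equal counts of every type; 10% of trials omit the
outcome.  A probe session appends a sated "Block 2" (default 16 trials
per type) in which all outcomes are omitted and licking nearly vanishes.
An odor–sound variant (two odors, two tones, valence-matched) is provided
as an alternative configuration; the scoring formulas generalize to it
unchanged because pair sets are derived from the valence classes, not
from odor identities.

Sessions store *raw* fluorescence; normalization is always recomputed so
no derived quantity ever becomes the primary record.

## Preprocessing

**Baseline normalization.** ΔF/F per (neuron, trial) against the mean raw
fluorescence of the 1 s pre-stimulus baseline.  Non-positive baselines
flag the entry invalid — dropped per (neuron, trial), never zero-filled
and never cause for dropping a whole neuron.

**Smoothing.** A minimal locally weighted linear smoother: tricube
weights over a centered window (default span 5 frames), distances scaled
by half-width + 1 so the outermost frames keep nonzero weight.  At the
window center the symmetric weights cancel the slope term, so interior
frames reduce to a normalized convolution; edges use explicit weighted
degree-1 fits.  The smoother therefore preserves constants and linear
ramps everywhere, and span 1 is the identity.

**Transient detection.** On each neuron's session-concatenated smoothed
ΔF/F trace, a frame is supra-threshold when it strictly exceeds
`median + 3 × 1.4826 × MAD` computed over sub-threshold frames within the
trailing 20 s.  Design choices, made where the detection criterion is
under-specified:

- trailing (not centered) window, so the estimate is causal and cheap;
- robust location/scale (median, MAD-based SD) so transients that slip
  into the window cannot inflate the threshold;
- *all* supra-threshold frames are barred from the baseline estimate, not
  only frames of accepted events — simpler and strictly more conservative;
- frames seen before 5 baseline frames have accumulated are never
  flagged (warm-up);
- an exactly flat history gets a machine-epsilon SD floor, so flat traces
  yield no events;
- "lasting longer than 5 frames" is read strictly: events need ≥ 6
  frames.

The test suite holds this rule against an independently written
exhaustive-scan oracle on random traces (exact interval agreement).
Neurons with fewer than two detected transients per session are excluded
from every downstream analysis.

## Responsivity

The per-trial scalar response is the mean ΔF/F over the 1 s window ending
at outcome time (the same window used for population displays); the full
stimulus-onset→outcome window is available as an alternative.
Classification per (neuron, stimulus) uses a two-sided one-sample
Wilcoxon signed-rank test against zero plus a ±30% ΔF/F mean-deviation
threshold; the signed-rank test is chosen for consistency with the
non-parametric statistics used throughout (the accompanying test is not
otherwise pinned down).  Fewer than five valid trials give class `none`
with a missing p-value.  One shared rule serves both activated/inhibited
calls and score eligibility (any non-`none` class).  Preferred stimulus =
largest-magnitude classified response, ties broken by stimulus order.
Population proportions use Fisher's exact test on activated-vs-not 2×2
counts; overlap between activated sets is reported as Jaccard × 100.

## Coding scores

For responses `r(s)`, valence classes V(s) ∈ {aversive, neutral,
rewarded} and salience classes S(s) ∈ {high, medium, low}:

```
valence  = [mean |r_i − r_j| over cross-valence pairs
            − mean |r_i − r_j| over within-valence pairs] / |max r − min r|
identity = (|r|(1) − |r|(2)) / |r|(1)         (magnitude-ranked)
salience = valence formula over salience classes
```

Numerical and design choices:

- "differences" are absolute differences; without that the numerator's
  sign would depend on arbitrary pair orientation, and boundedness in
  [−1, 1] (|r_i − r_j| ≤ max − min) would fail;
- the neutral stimulus is excluded from both pair sets but can still set
  the max/min denominator; likewise the low-salience stimulus for the
  salience score;
- identity ranking uses magnitudes so an inhibited single-stimulus
  responder scores as a perfect identity coder (signed ranking is a
  documented alternative);
- flat profiles (zero denominator) are undefined, excluded from
  distributions rather than imputed;
- all three scores are scale-free: multiplying a profile by any c > 0
  leaves them unchanged.

**Shuffle nulls.** Each shuffle draws one permutation of the class labels
over the stimulus set — preserving label multiplicities — and applies it
to every neuron before recomputing scores; permuting population-wide
(rather than per neuron) preserves cross-neuron correlation.  The pooled
distribution over shuffles is the null.  Identity scores never reference
class labels, so they have no shuffle null.  For exchangeable profiles
(responses i.i.d. across stimuli) the null mean sits at zero, which the
acceptance suite verifies at 200 neurons × 1000 shuffles.

Distribution comparisons: unpaired → two-sided Wilcoxon rank-sum; paired
(same neurons across blocks, taken as the intersection of neurons scored
in both) → two-tailed paired t-test.

## Population geometry

Condition matrices are trial means of ΔF/F per stimulus (neurons ×
frames) over QC-included neurons.  Norm and cosine contrasts use the 1 s
pre-outcome epoch by default (configurable); PCA trajectories use the
full peri-trial window.  Subgroup vectors are the neuron-concatenated
trial-averaged time courses — a vectorization choice that preserves both
neuron identity and temporal shape.  Block-1-defined subgroups are reused
on Block-2 data, so "same cells, outcomes removed" is the comparison
being made.  The Euclidean contrast is
`100·(mean cross-valence pair norm − mean within-valence pair norm) /
mean within-valence pair norm` with the neutral stimulus excluded; a zero
within-valence mean makes it undefined (flagged, not fabricated).
Dimensionality reduction is plain PCA on the condition-stacked,
feature-centered matrix (samples = condition·frame, features = neurons);
no GPFA/LDA or time warping.

## Behavior

Anticipatory licks are counted in the 1 s window *ending at outcome
delivery*.  The stimulus-onset→outcome delay (1.3 s) exceeds 1 s, and the
odor needs transit time from valve to nose, so anchoring the counting
window at the outcome rather than at nominal stimulus onset absorbs that
latency; a start-anchored window is available.  The sated-block gate
drops every Block-2 trial containing ≥ 1 anticipatory lick before any
neural analysis; kept trials have zero anticipatory licks by
construction, and the excluded fraction estimates the per-trial lick
probability.

## Synthetic-data generator

The generator emulates the task conditions stated above (trial counts,
timing, omissions, half-session balance, sated block) with these
defaults, chosen once and documented here:

| parameter | default | rationale |
| --- | --- | --- |
| transient kernel | `exp(−t/τd) − exp(−t/τr)`, unit peak | standard fast-rise/slow-decay indicator model |
| τr, τd | 0.2–0.3 s, 1.0–1.5 s per neuron | GCaMP7s-like kinetics at 5 Hz |
| amplitude | 0.8–1.2 ΔF/F | robust single-transient responses |
| reliability | 0.8 per trial (Bernoulli) | per-trial response probability is not reported anywhere; a realistic sparse-failure rate |
| amplitude jitter | lognormal, σ = 0.3 | trial-to-trial variability without sign flips |
| noise | additive, SD 3% of baseline per frame | typical shot-noise scale after source extraction |
| baseline drift | random walk, 0.2% of baseline per frame | slow fluctuations that per-trial normalization must absorb |
| spontaneous transients | 0.002 per frame | keeps nonresponsive neurons above the 2-transient QC bar, as real idle neurons are |
| inhibited fraction | 0.3 | both response signs occur in all archetypes |
| anticipatory lick rates | 2.7 Hz (large reward), 2.0 Hz (small), ≈0 otherwise | matches trained-day lick counts in the 1 s counting window |
| sated lick probability | 0.05 per trial | the stated ~5% residual lick-trial rate |
| learning ramps | lick rate and valence gain ramp 0.3/0.4 → 1.0 over days 1–4 | acquisition curve shape; applied only when simulating multi-day training (a single-day simulation represents trained animals) |

Inhibited responses are multiplicative dips (negative gain on the kernel,
ΔF/F clipped at −0.95) since ΔF/F is bounded below by −1.

**What passing tests show — and don't.** The generator produces
well-separated archetypes with stationary noise, no neuropil
contamination, no motion artifacts, no correlated noise across neurons,
and lick streams that are exactly Poisson.  Recovery results on it
demonstrate that the estimators measure what they claim under known
ground truth (direction and approximate magnitude of score separations,
geometry contrasts, gate behavior); they do not certify performance on
real data, where baseline nonstationarity, overlapping sources, and
mixed-selectivity neurons blur all of these quantities.

## Problem sizes

The canonical studies use one simulated day of 30 trials × 5 stimuli:
200 mixed-archetype neurons (50 valence, 50 identity, 10 salience, 90
nonresponsive) for score recovery, 60-neuron pure populations for the
geometry contrasts, an 80-trial sated block for the behavioral gate, and
a 4-day single-neuron session for the learning curve.  Shuffle nulls use
1000 shuffles.  These sizes make a full acceptance run reproducible in
about a minute on one CPU while keeping every comparison far from its
decision threshold.

## Known limitations

- Transient detection is threshold-based on smoothed ΔF/F; no spike
  inference or deconvolution is attempted.
- The 30%-deviation eligibility rule and the detection window/estimator
  are package choices where the criterion is under-specified upstream;
  both are configurable.
- Scores are computed from mean responses in a single scalar window;
  temporally heterogeneous coding within the window is invisible.
- The odor–sound configuration treats modality only through the stimulus
  set; no cross-modal interaction terms are modeled.
- Reading raw microscope movies or motion-correction/source-extraction
  outputs in their native formats is out of scope; sessions must be
  converted to the CSV bundle or HDF5 layout first.
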