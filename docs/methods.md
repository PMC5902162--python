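# Methods

This note documents the models, estimators and numerical choices behind the
`firstspike` pipeline, and what the synthetic-data generator does and does
not emulate.

## Task model and behavioral readout

A trial presents either a target or a distractor grating; the animal's
continuous response is reduced to the *hold time*, the time the stimulus
spends in the reward zone. A trial is a **stop trial** when
`hold_time >= hold_time_threshold` (boundary inclusive; default threshold
0.9 s, within the 0.6–1.0 s range used in training). **Accuracy** is the
average of percent stop trials on targets and percent non-stop trials on
distractors, which makes 50% the chance level for *any* stimulus-blind
stopping policy, whatever its overall stop rate. Binomial CIs are exact
Clopper–Pearson rather than a normal approximation: stop counts per
condition are often small and near the boundaries, where Wald intervals
misbehave.

The **ideal-observer ROC** on hold times is the cross-pair probability
`P(hold_T > hold_D) + ½·P(=)`, computed via midranks (equivalent to the
Mann–Whitney U statistic divided by n₁n₂). Rank-sum choice tests use the
exact permutation null when the combined sample is ≤ 20 and tie-free, and
the tie-corrected normal approximation otherwise. Trials that never enter
the reward zone carry hold time 0 s.

## Cortical onset from the LFP

Trial-averaged voltage traces are low-pass filtered at 300 Hz (4th-order
Butterworth, applied bidirectionally, so the magnitude response is squared
and a sinusoid at the cutoff emerges at half amplitude). Baseline mean and
SD are computed per channel over [−80, +20) ms around stimulus onset, on the
*filtered* trace (filtering precedes thresholding). The onset is the
earliest sample in (0, 300] ms whose absolute deviation from the baseline
mean exceeds 3 SD, minimized over channels; the winning channel is reported.
The criterion is sign-agnostic: the evoked deflection is typically
negative-going in the thalamo-recipient layer but its sign varies with
recording depth, and a two-sided rule subsumes both cases.

One robustness addition: the crossing must be **sustained** for
`min_duration_ms` (default 20 ms, a few correlation times of trial-averaged
LFP noise) to count, with the onset reported at the first sample of the
sustained run. A bare single-sample 3-SD rule fires spuriously on band-
limited noise often enough (a few percent of 40 ms pre-onset windows per
channel) to be unusable when minimizing over channels; a 20 ms run
requirement drives the false-alarm rate to ~0 while leaving the detected
time of a genuine deflection unchanged, since a real evoked response stays
suprathreshold for tens of milliseconds. Setting `min_duration_ms=0`
recovers the bare rule.

On synthetic blocks with a 10×-noise-SD deflection injected at 40 ms the
detector recovers the onset within ±5 ms in ≥ 95% of seeded runs with a
mean bias under 3 ms (about half the rise of the filtered deflection to its
threshold crossing).

## Windowed ROC discrimination

Spike counts are taken in half-open windows `[onset, onset + t)` anchored at
the cortical onset, for t on a default grid of 20 ms steps up to the
defining 300 ms window. Per unit, the AUC is the cross-pair probability
oriented by the unit's **preference** — the sign of the mean-count
difference over the 300 ms window, ties broken toward target — so values
≥ 0.5 mean informative. Significance is a two-sided rank-sum test on the
raw counts (always the tie-corrected normal approximation: counts are
heavily tied). The per-unit p-values at 300 ms undergo Benjamini–Hochberg
step-up selection at FDR 0.05; the data-dependent effective cutoff p₍ᵢ₎ is
reported, and the same cutoff is reused when asking whether a
discriminating unit already discriminates at an earlier interval (so the
fraction-discriminating curve ends at 1 by construction). Re-applying BH per
interval would change the question from "when does a discriminating unit
start discriminating" to "what is discriminable at t", and is deliberately
not done; the choice is recorded in the output metadata.

Units firing fewer than one spike per six trials over the initial 300 ms
(mean count < 1/6, strict) are excluded before analysis. The first-spike
variant removes, per trial, everything but the first spike at or after the
onset (baseline spikes included in the removal), then reruns the identical
machinery; counts are then 0/1 by construction.

## First-spike latencies and Poisson counts

First-spike latencies are measured in (onset, onset + 300 ms]; trials
without a spike in the horizon are omitted (not zero-filled) and their
fraction reported. The preferred/non-preferred comparison takes each unit's
mean first-spike latency per stimulus and applies a one-sample two-sided
t-test to the per-unit differences. Median summaries carry bootstrap
standard errors (1000 resamples), the package-wide convention for medians.

The Poisson check fits nothing: λ is the sample mean, the predicted pmf is
evaluated on the observed support 0..max(count), and R² is the variance
explained across those bins by the pmf relative to the empirical bin
proportions. A degenerate support with zero residuals scores R² = 1.

## Tuning and the AUC-vs-Δspikes fit

Orientation statistics live in doubled-angle space (period 180°): with
max-normalized mean rates r_k at orientations θ_k,
x = Σ r_k cos 2θ_k, y = Σ r_k sin 2θ_k, the preferred orientation is
½·atan2(y, x) mapped to [0, 180), and the OSI is √(x² + y²) / Σ r_k. The
two-argument angle is used for both half-planes — the single-branch
arctan(y/x) form is only quadrant-correct for x > 0 — and both statistics
are invariant to uniform rate scaling, so whether raw or normalized rates
enter the sums is immaterial. Receptive-field centers are the center of
mass of the polarity-averaged, channel-averaged, peak-normalized response
map, floored at zero.

The AUC-vs-Δspikes relation is an ordinary least-squares line of the 80 ms
task AUC (oriented toward the target, so distractor-preferring units sit
below 0.5) against the passive-viewing spike-count difference, signed as
(response at 90°) − (response at 45°) so target-preferring units sit at
positive x. Parameter SEs come from the standard OLS covariance (the
inverse information matrix under Gaussian errors); a one-sided p-value for
slope > 0 is reported.

## Pooling

Shuffle augmentation creates, per source unit, `n_copies` (default 6)
surrogate units whose trials are independently permuted **within stimulus
class**, preserving every stimulus-conditioned single-unit statistic while
breaking cross-unit noise correlations — which is the point of pooling
units recorded in different sessions. An unrestricted shuffle (mixing
target and distractor trials) is available behind a flag but destroys the
class-conditional means and is not the default. Distractor-preferring units
have their target and distractor responses swapped (the i-th target trial
exchanges with the i-th distractor trial, requiring equal per-class trial
counts, which the generator guarantees; the preference comes from the
300 ms discrimination table). The pooling neuron for a sample of N units
carries per trial the summed counts of the N units, trials aligned by index
within class; its AUC is averaged over 1000 samples drawn *without
replacement*, and the whole procedure repeats 10 times to attach an SEM.
The smallest N whose mean AUC reaches a supplied behavioral accuracy
(treated as a proportion, mirroring the convention that percent-correct and
AUC share a scale) is the "neurons to explain behavior" readout; the
accuracy threshold is an explicit input, not a default.

For homogeneous pools of independent Poisson units with means (μ₁, μ₂) the
pooled counts are Poisson (Nμ₁, Nμ₂), and the pooled AUC is checked in the
tests against the exact truncated double sum Σᵢⱼ p₁(i)p₂(j)[i>j] + ½[i=j];
at the canonical 0.6/0.22 means this gives 0.6343 at N = 1, rising with
√N-like signal scaling.

## Synthetic-data generator

The generator is the package's stand-in for the recordings and defines the
conditions under which everything is tested.

- **Spike counts.** Response spike counts in `[onset, onset + 80 ms)` are
  Poisson: preferred mean 0.6 and non-preferred mean 0.22 spikes per 80 ms
  for discriminating units (≈7.5 Hz preferred rate); non-discriminating
  units receive the midpoint mean for both stimuli. Per-unit trial counts
  default to 100 per stimulus — roughly half a typical behavioral session
  per condition, and enough for the rank-sum tests to reach the power the
  analyses assume.
- **Spike times.** Response spikes are placed i.i.d. from a gamma latency
  density (shape 3) truncated to the 80 ms window. The scale is re-solved
  numerically so that the **mean first-spike time** — the expectation of
  the minimum of a Poisson-distributed number of draws, conditional on at
  least one — equals the nominal latency (34 ms preferred, +12 ms shift
  non-preferred). Two naive alternatives are biased: sampling an untruncated
  gamma and rejecting overflows shrinks the nominal mean, and matching the
  per-spike mean ignores that the preferred stimulus has more multi-spike
  trials whose first-spike minimum statistic is pulled earlier (~2 ms at
  these means, enough to shift the recovered 12 ms difference to ~14 ms).
- **Baseline.** Spontaneous spikes are homogeneous Poisson (default 1 Hz)
  before the cortical onset only; post-onset activity is the response
  process alone, keeping first-spike statistics unconfounded.
- **Cortical onset.** One per session, Normal(40 ms, 5 ms).
- **Optogenetic truncation.** When enabled, all spikes after LED onset plus
  an 8 ms silencing delay are removed.
- **Behavior.** Hold times are lognormal per stimulus (σ = 0.5), with the
  location calibrated so that P(hold ≥ threshold) equals the spec'd stop
  probability (defaults 0.9 target / 0.1 distractor, threshold 0.9 s) —
  positive support and a heavy right tail, matching the shape of empirical
  hold-time histograms, while making the stop flag re-derivable.
- **Passive viewing.** 12 orientations at 15° steps, 30 repetitions, Poisson
  counts over 330 ms with a circular-Gaussian (von-Mises-shaped, period
  180°) rate profile, κ = 1 (half-width ≈ 35°, typical of mouse V1), peak
  10 Hz over a 0.5 Hz floor.
- **LFP.** Gaussian noise low-pass filtered at 100 Hz (trial-averaged LFP
  noise is smooth; this also keeps the 300 Hz analysis filter from shrinking
  the baseline SD relative to the generated noise SD), rescaled to the
  nominal SD, plus a negative-going alpha-function deflection (τ = 15 ms)
  of amplitude `deflection_amplitude × noise_sd`; the true onset is stored
  in the block metadata.

What the generator does **not** emulate: cross-unit noise correlations
(units are conditionally independent given the stimulus — the very
structure shuffle augmentation imposes), within-session drift or adaptation,
running-speed covariates, sustained post-80 ms responses, eye movements, and
non-Poisson dispersion. Tests passing on this generator therefore validate
the estimators and their contracts, not claims about biological recordings
with correlated or non-stationary activity.

## Problem sizes and determinism

Default analysis problem sizes (100–200 trials per stimulus, tens of units,
hundreds of pooling samples with 5–10 repetitions) were chosen so each
statistical check has ≥ 3-SE resolution against its oracle while a full
pipeline run stays in seconds. Every stochastic stage draws from a child of
one `numpy` seed sequence recorded in the run log; two runs with equal
configuration and seed produce byte-identical outputs. Degenerate inputs
(empty classes, all-zero rates, zero-variance predictors, flat baselines)
raise typed validation errors rather than returning NaNs, except where a
well-defined limit exists (all-zero Poisson counts score R² = 1; a
noiseless flat LFP has no finite threshold and reports "no onset").
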