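# Methods

## The phenomenon being audited

When a recording is segmented and segments are randomly assigned to train
and test sets, any *subject-stable* structure in the data acts as a label
oracle: a model can attach the diagnostic label to each subject's
idiosyncratic pattern and recognise that subject in the test set. The audit
quantifies this by running one identical pipeline under two partitions of
the same segment set and comparing the resulting accuracy estimates. The
only difference between the arms is the partition rule, so the accuracy gap
Δ is attributable to subject-level information crossing the split.

## Synthetic cohort model

Each subject's signal is a sum of four band oscillators plus band-limited
pink noise:

```
x_c(t) = Σ_b sqrt(2 P_bc) · sin(2π f_b t + φ_bc) + σ_noise · (M ε(t))_c
```

* **Bands**: delta (2 Hz), theta (6 Hz), alpha (10 Hz), beta (20 Hz) with
  base band powers 1.0, 0.5, 1.0, 0.2 (squared signal units, arbitrary
  microvolt-like scale). These are typical relative magnitudes for
  eyes-open resting EEG; only ratios matter downstream.
* **Subject fingerprint** (`fingerprint_strength = s`): per subject and per
  band×channel, band *amplitude* is multiplied by `exp(s·Z − s²)` (Z
  standard normal), which makes the expected *power* multiplier exactly 1,
  so group comparisons stay unbiased at any s. Band peak frequency gets an
  additive `N(0, 0.5·s)` Hz shift, shared across channels (as the
  individual alpha peak is). The noise is mixed by a per-subject channel
  matrix `M = I + 0.1·s·G` (rows renormalised), a spatial signature.
  Everything is drawn once per subject and held fixed over the recording —
  this *is* the premise that segments within a subject resemble each other.
* **Disease effect** (`disease_effect = d`): the two diagnostic groups
  receive theta base power `0.5 ± d/2` (clipped at 0), an AD-like slowing
  signal. The group difference in periodogram theta power is an unbiased
  estimate of `d` (verified at n = 50 subjects per group in the tests).
* **Noise**: white noise spectrally shaped to a 1/f power spectrum *above
  1 Hz*, tapered to zero below 0.5 Hz, unit expected variance, scaled by
  `noise_level` (default 1.0). Two deliberate choices keep segments of a
  fingerprint-free subject exchangeable:
  1. the low-frequency cutoff — unbounded 1/f power would give every
     recording a persistent realised slow-wave profile that all of its
     segments share, i.e. an accidental fingerprint that cannot be turned
     off;
  2. normalisation by the *expected* (analytic) variance of the shaping
     filter rather than the realised standard deviation — realised-std
     normalisation couples all segments of a recording through one scale
     factor.
  Without these, the null condition (`fingerprint_strength = 0`) showed
  residual leakage and the paired test over-rejected; with them the
  rejection rate at α = 0.05 is nominal (acceptance suite, 200 replicates).
* **Events**: seizure-like bursts are 3 Hz oscillations under a Hann
  envelope, amplitude `event_strength` shaped per channel by the subject's
  delta-band fingerprint, placed by rejection sampling (10,000-attempt cap)
  into non-overlapping intervals.
* **Randomness**: one root seed feeds a `SeedSequence` tree; subject
  profiles are drawn from child streams before any time-series noise, so
  cohort membership is invariant to the recording duration.

What the generator does *not* emulate: volume conduction from dipolar
sources, artifacts (blinks, EMG, electrode pops), non-stationarity across
the session, realistic seizure morphology and propagation. Passing audits
on this generator therefore demonstrate properties of the *evaluation
machinery* — that the audit detects identity confounding when present and
stays silent when absent — not that any real dataset has fingerprints of a
particular size.

## Pipelines

Raw pipeline: 4th-order Butterworth low-pass applied forward–backward
(zero phase; filter family unspecified in common practice, Butterworth
chosen as the standard default with edge effects negligible relative to
2-s segments), then non-overlapping segments (default 2 s; 500 samples at
250 Hz), stacked as (samples × channels). Segments are not normalised per
channel by default (a config switch exists): the surrogate standardises its
features anyway, and the CNNs see batch normalisation at every block.

Spectrogram pipeline: equal-duration event and non-event pools (non-event
taken from the start of the recording, skipping event spans), segments cut
*within* pools so none straddles an event boundary; magnitude-squared STFT
with a Hann taper (window 256 samples = 0.5 s at 512 Hz, hop 128) without
edge padding, so the time-window count is `floor((n − window)/hop) + 1`;
log power, per-image min–max scaling (scale invariance; a global-scaling
option exists), viridis colormap, bilinear resize to 224 × 224 × 3 with
the full frequency axis up to Nyquist retained. Each channel of a chunk
yields its own image inheriting `y` and `s` (single-channel selection by
config) — a choice that itself introduces channel-level non-independence,
mirroring the surveyed literature.

## Cross-validation constructions

Both schemes shuffle with a seeded generator and deal into k near-equal
chunks (sizes differ by ≤ 1; remainder one per fold, largest first).
Segment-based partitions indices 1..n; subject-based partitions the unique
subject vector and maps chunks back to segment indices, which enforces
`s_i ≠ s_j` across every fold's train/test pair by construction. A
label-stratified variant deals subjects round-robin within each group.
Stratification matters for small cohorts: with unbalanced subject folds the
training majority class is systematically the class under-represented in
that fold's test subjects, which pushes null accuracy *below* chance. The
library default is unstratified (matching the plain construction);
the audit experiments in the acceptance suite use the stratified variant
so that chance means 0.5. Leave-one-subject-out is the subject scheme with
k = |s_u|. No validation partition is carved out by default (no model
selection is performed anywhere); `carve_validation` exists for protocols
that need one.

## Classifiers

The two CNN architectures follow the published block structure they
reproduce: four convolution blocks (convolution → ReLU → max-pool → batch
norm), then dense 20 → 10 → 2 for the raw 1D model and dense 256 → 512 →
dropout(0.5) → 2 for the image model. Exact filter counts are configurable
(defaults 16/32/64/128 kernel 5, and 32/64/128/256 kernel 3×3); training
uses fixed epochs (default 70), batch 32, Adam 1e-4 (raw) or RMSProp 1e-5
(image), no early stopping, per-epoch batch-averaged train accuracy and
monitoring-only test accuracy. The networks are implemented directly on
numpy (im2col convolutions, manual backpropagation) and verified against
numerical gradients; they are deliberately small-scale tools for
direction-of-effect checks, not performance-tuned trainers.

The first-class experiment classifier is the **surrogate**: log band power
per channel in the four canonical bands (periodogram integration),
standardised with statistics fit on the training fold only, then a
logistic model trained by minibatch Adam (learning rate ~0.1 for this
convex problem) with the same online-accuracy bookkeeping as the CNNs.
Leakage through subject fingerprints is a property of the *split*, not of
model capacity, so the cheap model shows the same qualitative effect as
the CNNs (asserted in the tests) while keeping hundreds of audit
replicates affordable on one CPU.

## Inference

Fold accuracies are paired across schemes by fold index (matched k is
required; the pairing choice is recorded in the report's assumptions).
The signed-rank statistic uses midranks for tied |differences|; zero
differences are dropped before ranking (classic treatment; the count is
logged). For n ≤ 20 the two-sided p is exact: the null distribution of the
positive-rank sum over all 2^n sign assignments is built by a
generating-polynomial recursion over doubled ranks (integers even with
midrank ties), and p = min(1, 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w))). Above n = 20 a
tie-corrected normal approximation (no continuity correction) is used.
Scheme means are summarised with percentile-bootstrap 95% CIs over fold
accuracies (10,000 seeded resamples); a Wilson interval over pooled test
segments is available as an option and the report states which was used.

## Problem sizes and numerical choices

The audit experiments in the acceptance suite use cohorts of 20 subjects
per group, 19 channels, 250 Hz, 5 minutes per subject, k = 10, with the
surrogate trained 20 epochs — the full audit runs in well under a minute —
and the null-calibration study uses 200 replicates of a lighter cohort
(10 per group, 1 minute, 5 epochs), chosen so the complete study stays in
the minutes range on a single CPU. The acceptance script averages the
subject-based null accuracy over 40 replicate cohorts to shrink its
Monte-Carlo error (subject-level outcomes are strongly correlated within a
cohort, so a single cohort's mean has a standard deviation of several
percentage points).

Degenerate inputs: constant spectrogram chunks render at the colormap
midpoint with a warning; recordings shorter than one segment yield empty
sets with a warning; all-zero difference vectors give p = 1 flagged;
single-fold summaries return an undefined CI flagged. Event placement
failure reports requested vs available time.

## Known limitations

* Subject-based accuracy on small null cohorts is noisy and often lands
  below 0.5 for a single cohort; this is a real property of subject-level
  cross-validation with few subjects, not a bug, and is why replicate
  averaging is used for point estimates.
* The exact-test enumeration treats accuracies as exchangeable paired
  observations; fold accuracies within a scheme share training data, so
  the test is calibrated for the paired *difference* under the null (shown
  empirically), not a general-purpose independence test.
* EDF export quantises to 16 bits over the recording's amplitude range and
  drops a trailing partial second (fixed-duration data records).
* The survey table is a static snapshot labeled with the documented
  rubric; it is not updated by any automated search.
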