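# Methods

This note documents the modelling and statistical choices behind
`ctxdecode`: what is computed, which knobs matter, what the synthetic
generator does and does not emulate, and where the design was genuinely
open.

## Analysis model

### Features

Epoched EEG (encoding: −1…7 s around movie onset; retrieval: −2…6 s around
the word cue, probe at 2 s) is decomposed with complex Morlet wavelets of
width 5 cycles (`σ_t = 5 / 2πf`, `σ_f = f / 5`), on a 4–45 Hz grid in 1 Hz
steps sampled every 0.05 s.  The convolution is delegated to MNE-Python;
this module owns the grid, the per-frequency gain equalization (L2-
normalized wavelets respond to a unit sinusoid with power ∝ 1/f; power is
rescaled by f so ridge power tracks amplitude² at any frequency — feature
z-scoring and log-baselining are insensitive to this, raw spectra become
comparable across rows), and edge bookkeeping: a bin is invalid for a
frequency when the wavelet's ±2.5 σ_t support overruns the epoch.  The
default retrieval grid (−0.2…4.0 s, 85 bins) sits inside the valid region
of a −2…6 s epoch even at 4 Hz.

Encoding features are the TFR averaged over the 6 s movie window,
`channels × frequencies` wide (2520 at the full 60 × 42 montage/grid).
Retrieval features are single-bin slices in the identical feature order.
Decoding features receive no baseline correction; each feature is z-scored
across trials instead.  Normalization statistics are computed on training
trials only and frozen onto test folds and retrieval bins.  The pooled
(train+test) variant exists behind `pooled_normalization=True` for
comparison; the fold-safe mode is the default and the one used everywhere,
because pooled statistics leak test information into training.

### Decoder

A linear SVM (scikit-learn's liblinear) in a one-against-all arrangement:
one max-margin separator per context, prediction = argmax of the three
decision values, ties resolved to the lowest class index (deterministic).
Regularization defaults to C = 1 and is exposed; the acceptance properties
hold across C ∈ {0.1, 1, 10} (checked in the test suite).  Encoding
performance is assessed by a randomized (unstratified) 10-fold
cross-validation — fold sizes differ by at most one, each trial is predicted
exactly once, normalization is recomputed inside each training fold — and
summarized as a row-normalized confusion matrix whose mean diagonal is the
accuracy (chance 33.3%).

Searchlights re-run the same cross-validation on restricted feature sets:
per channel, the channel plus its Delaunay neighbors on the shipped 2-D
projected 10-20 layout (× all frequencies); per frequency, {f−1, f, f+1}
(two frequencies at the grid ends) × all channels.  Each map cell is tested
against chance with a one-sample t and Bonferroni thresholds 0.05/60 =
0.0008 (channels) and 0.05/42 = 0.0012 (frequencies).

### Cross-phase timecourses

The frozen encoding decoder classifies every retrieval bin.  Per
subject × condition we record accuracy with respect to the target context
and the evidence proportions for target, competitor and the remaining
context (they sum to 1; accuracy equals target evidence).  Series are
smoothed with a centered 0.1 s moving average (shrinking at the edges)
before group statistics.  The headline reinstatement timecourses are
computed over successfully recalled trials; the success/failure contrast
then compares both outcomes inside windows identified from those
timecourses.  Per-bin features are the literal single-bin slice (no local
temporal averaging); the smoothing acts on the accuracy series, not the
features.

### Permutation statistics

Per condition, the null is built by shuffling context labels within
subject and re-running the pipeline: for encoding, the full 10-fold CV (100
iterations); for retrieval, re-training the encoding decoder on shuffled
labels and re-decoding all 85 bins (1000 iterations).  Re-training is the
stricter of the two readings of "shuffled data"; permuting only the
retrieval test labels is available as `mode="permute_test"`.  Each
iteration yields a group one-sample t vs 33.3% (per bin for retrieval);
the 2.5th/97.5th percentiles of the per-bin null t distribution (linear
interpolation) form the two-tailed 0.05 threshold.  Nulls are kept per bin
rather than pooled across bins (the pooled variant would borrow strength
across bins with different variances); per-subject null accuracies are
stored so leave-one-subject-out folds can rebuild their own thresholds.

A percentile threshold interpolated from few null samples is exceeded by
new data noticeably more often than 2.5% per tail (≈4% at 64 samples), so
calibration statements assume the analysis-scale 1000 iterations.

The percentile rule is corroborated by per-bin Monte-Carlo p-values,
p = (1 + #{|t_null| ≥ |t_obs|}) / (1 + n_iter) (the +1 keeps p valid and
nonzero), passed through Benjamini–Hochberg step-up at q = 0.05 across the
85 bins.  Only bins significant under both rules are reported ("joint").
Note an arithmetic consequence: with 1000 iterations the smallest possible
adjusted p for a single extreme bin is 85/1001 ≈ 0.085, so the FDR arm can
only fire when at least two bins reach the minimum permutation p — isolated
single-bin effects are deliberately not reported as joint.

### LOSO window selection and contrasts

Contrasting success vs failure inside windows selected for showing reliable
decoding is circular if the tested subject informed the selection.  For
each left-out subject the remaining subjects' smoothed group t-series is
thresholded by that fold's own null (rebuilt without the subject), and
significant bins within ±0.2 s of the group reference window are selected;
when a fold selects nothing, the window-center bin is used and flagged, so
every subject stays in the contrast.  If a fold shows disjoint significant
sub-intervals inside the margin, their union is used.  Within the selected
bins: paired t between outcomes (subjects with ≤10 trials in either outcome
are excluded), one-sample t vs chance, and repeated-measures ANOVAs (up to
three within-subject factors, statsmodels `AnovaRM`) with partial
η² = F·df₁/(F·df₁+df₂).  All headline factors are 2-level, so no sphericity
correction is needed.  Paired Cohen's d is mean difference / SD of
differences.  The acceptance suite demonstrates the point of the procedure:
on zero-signal cohorts, circular max-|t| selection inflates the
success-contrast type-I error while LOSO selection stays nominal.

### Cluster-based permutation test

Univariate contrasts (log power minus the mean log power in the −1…0 s
pre-cue window) are tested cell-wise with dependent-sample t at
alpha = 0.05; supra-threshold same-sign cells are clustered using channel
adjacency from the montage graph plus ±1 grid step in frequency and in
time — a simultaneous frequency+time step is *not* a neighbor (documented
choice; it makes clusters slightly more conservative).  Cluster mass is the
summed t.  The null is the maximum |mass| over clusters under random
within-subject condition swaps (sign flips of the per-subject difference
maps), 10 000 draws at full scale.  Because the null pools both signs,
comparing a cluster's Monte-Carlo p to 0.05 is a two-tailed test
(0.025 per tail).  The configured contrasts mirror the analysis windows:
success effects in the cue (0.3–1.5 s) and probe (2.3–3.5 s) windows over
4–45 Hz, and theta-band (3–6 Hz) condition contrasts at 0.1–0.6 s and
2.1–2.6 s.

## Synthetic cohorts

The generator emulates the experiment's structure: blocks assign the three
movie contexts to the AB/AC/DE conditions in rotation (each context serves
each condition equally often); each block contributes
`pairs_per_condition_per_block` encoding trials per condition and an
analyzed retrieval set of 4 DE + 2 AB + 2 AC trials (each cue tested once).
At the default 18 blocks × 4 pairs this yields 72 encoding trials per
context and 72/36/36 retrieval trials — the scale of a full session before
artifact rejection.

Signals: per-channel background noise is 1/f-power (α = 1) plus white
sensor noise (ratio 0.5), unit SD, independent across channels with an
optional shared pink source.  Each context's signature is a nonnegative
`channel × frequency` weight map confined to the posterior 40% of channels
and the 4–20 Hz band, built as a random posterior channel profile times a
Gaussian spectral profile with a context-specific peak, rejection-resampled
until all pairwise correlations fall below 0.5.  A trial adds, inside each
event window, a sum of fixed-frequency sinusoids with random phases whose
amplitudes are `snr × event amplitude × weight` (boxcar envelope with
0.05 s cosine ramps).  Encoding trials carry their context's signature
throughout the 6 s movie; retrieval trials only inside scheduled
reinstatement events.  The default schedule encodes the effects the
pipeline is asked to recover: DE target at 0.9–1.0 s (success-gated), AC
competitor at 2.35–2.45 s (both outcomes), AC and AB target at 2.5–2.8 s
(success-gated).  Events can instead be failure-gated, which is how
outcome-dependent band-power differences are programmed for the univariate
contrast (an added oscillation on failed trials is the sign-symmetric
equivalent of a desynchronization on successful ones — the generator is
purely additive and cannot suppress background power).  Success flags are
Bernoulli draws per condition; the defaults (AB 0.70, AC 0.62, DE 0.74)
encode only the expected *ordering* (AC worst — proactive interference),
not values to be reproduced.  Slow context drift is available as a random
walk on signature amplitude (`drift_timescale`) and is off by default; it
is cosmetic for every implemented statistic.

Not emulated: forward-modeled head geometry and realistic channel
covariance, eye/muscle artifacts, raw continuous recordings, and word-level
stimulus identity.  Passing tests therefore show that the *pipeline*
recovers what the generator programs under EEG-plausible noise — they say
nothing about effect sizes in real recordings, where artifacts,
inter-subject variability and weaker signatures dominate.

Determinism: a cohort is a pure function of its `SimConfig` (seeds are
spawned per subject from the config seed); the pipeline derives each
stage's seed from the master seed and the stage name.

## Problem sizes

Tests and the acceptance script run the identical code paths at reduced
size — typically 4–8 subjects, 4–16 channels at 100 Hz, 3–6 blocks, and
5–6 frequency bins inside the signature band; permutation counts follow the
analysis defaults where the property depends on them (1000 retrieval
iterations for calibration/recovery, 100 encoding iterations, 499 cluster
draws for calibration) and are reduced where it does not (50-iteration
fold nulls in the LOSO replicates).  The default pipeline configuration is
a desk-scale run (8 subjects, 32 channels at 200 Hz, 60 encoding trials
per context, 100/200 iterations, 499 draws); experiment-scale constants
(62 channels, 500 Hz, 1000/10 000 iterations) are plain config switches.

## Known limitations

- The empirical chance of label-shuffled cross-validation sits slightly
  below 33.33% (unstratified folds make train/test label proportions
  anti-correlate); the permutation machinery absorbs this, which is one
  reason the analysis uses empirical rather than theoretical nulls.
- With few trials per subject, per-bin accuracies are coarsely quantized
  and the group-t null acquires heavy tails; calibration holds, but power
  at very small trial counts is poor.
- `AnovaRM` requires complete balanced cells; unbalanced designs are
  rejected rather than approximated.
- The montage neighbor graph is a Delaunay triangulation of projected
  standard positions — a reasonable approximation to cap templates, and no
  result here depends on a specific neighbor count.
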