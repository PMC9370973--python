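# Methods

This note documents the models, conventions and parameter choices behind
`ppgqc`, in the order the pipeline runs them.

## Filtering and segmentation

PPG is band-passed with a Butterworth filter, 0.5–12 Hz; the accelerometer
channels with 0.025–10 Hz.  The stated orders ("second"/"fourth") follow
the MATLAB `butter(N, [lo hi])` convention — N poles per band edge, 2N
overall — since that is the convention of the toolchain this style of
pipeline is normally built in.  Filters run forward-only (causal) by
default so every quantity could in principle be produced online by a
device; pass `zero_phase=True` for offline, delay-free analysis.  At these
bands the causal group delay moves detected systolic peaks by ~1 sample at
64 Hz, well inside the ±3-sample tolerance used in the segmentation checks.

Pulse detection is a two-moving-average event detector: the filtered signal
is half-wave rectified and squared; a peak-scale moving average
(W1 = 111 ms) is compared against a beat-scale moving average (W2 = 667 ms)
plus an offset β·(60-s moving average of the squared signal), β = 0.02.
Rectification before squaring is essential — without it the troughs also
produce energy blocks and peaks merge.  The offset is local rather than a
whole-recording constant so that quiet stretches stay detectable in
recordings that also contain very loud motion segments.  Blocks shorter than W1 are rejected; the systolic peak is
the block maximum, the foot the minimum between consecutive peaks.
Foot-to-foot windows outside 0.3–1.5 s (40–200 bpm) are discarded as
implausible.  A foot-to-foot pulse needs a detected peak on both sides, so
the first and last beat of a recording cannot be represented; recovery
statistics therefore count interior beats only.

Each pulse is z-scored with the population (1/N) standard deviation,
matching the 1/N convention used in the epoch-variance formula of the
activity index; a zero-variance window raises a degenerate-pulse error and
is dropped.

## Activity index and ranges

The accelerometer is resampled to the PPG rate (64 Hz, linear
interpolation), each channel band-passed (removing gravity), then combined
into the vector magnitude.  σ is the population standard deviation over 5-s
epochs (N = 320 samples); the minute-wise index is the sum of M = 12
epoch σ values, in g.  Trailing partial epochs and minutes are discarded —
the formulas assume full windows.  Quartile boundaries over the pooled
index values (linear-interpolation percentiles, "type 7") define four
ranges with brackets AR0 = [min, Q1], AR1 = (Q1, Q2], AR2 = (Q2, Q3],
AR3 = (Q3, max]; a pulse belongs to the minute containing its systolic
foot.  Stratified sampling draws 100 pulses per range per recording without
replacement; per-recording RNG substreams are derived from (seed,
CRC32(subject id)) so results do not depend on subject order.

## Signal-quality indices

Seventeen PPG indices and two accelerometer indices are computed per pulse.
Features suffixed `_noZ`, plus `Amplitude`, `Width` and `TroughDepth`, use
the filtered, un-normalized pulse; all others use the z-scored pulse and
are therefore invariant to affine rescaling of the raw signal.  Two
definitions the field leaves open are pinned down here and isolated behind
one function each:

* **Entropy** — Shannon entropy (nats) of a 16-bin amplitude histogram of
  the z-scored pulse over [−4, 4], normalized over non-empty bins.
* **SNR_Moody** — a template-residual SNR: 10·log₁₀ of template power over
  the power of (pulse − template), where the template is an exponentially
  weighted running mean (weight 0.1) of the z-scored pulses resampled to 64
  samples, seeded with the first pulse; zero residual is capped at 60 dB.

Other conventions: `SNR` separates the waveform from high-frequency noise
with a 125 ms moving average; `RelPower` is the periodogram power fraction
in 1–2.25 Hz; zero-crossing rates treat an exact zero as inheriting the
previous sign; local maxima counting uses strict interior maxima with a
flat top counted once at its first sample and no prominence threshold;
`SigSim` resamples the previous pulse to the current length before the
Pearson correlation, and the first pulse of a recording compares against
the following pulse; skewness and kurtosis are population moments (kurtosis
not excess).

## Feature conditioning and NCA selection

Each feature column is shifted to strict positivity (shift = −min + 1e-6,
only when min ≤ 0), Box-Cox transformed at the maximum-likelihood exponent
and z-scored.  By default both partitions are conditioned with their own
fitted parameters — the per-set convention this pipeline standardizes on —
with `boxcox_from_train=True` available as the strictly leakage-free
variant.

NCA learns one weight per feature by maximizing the expected leave-one-out
accuracy of a soft-neighbour classifier under the weighted-L1 metric
d_ij = Σ_r w_r² |x_ir − x_jr|, minus λ Σ_r w_r².  The accuracy term is
normalized per sample (the mean over pulses), which puts λ on the
conventional scale of reference NCA implementations; the tuning grid is 20
log-spaced values in [1e-4, 1].  Optimization is batch gradient ascent from
w = 1 with an adaptive step (halved when a step would lower the objective,
so the accepted objective sequence is non-decreasing), stopping at relative
change < 1e-6 or 200 iterations.  λ is tuned by ten-fold CV of a
1-nearest-neighbour rule in the weighted metric; because that loss curve is
typically flat over small λ, a one-standard-error rule (`rule="1se"`:
largest λ within one SE of the minimum) is available and is what the
planted-recovery demonstrations use, with λ = 0.01 as the operating point.
Stability selection marks features with weight > 20 % of the run maximum
and keeps those marked in ≥ 80 % of ten runs; run-to-run variation comes
from refitting on a 90 % subsample, and an empty stable set falls back to
the full feature set with a warning.

## Classifiers and evaluation

Subjects are split 70/30 (round-half-up on the subject count, so 31
subjects give 22/9); every pulse follows its subject, and no class
rebalancing is applied.  Six families are tuned by sequential model-based
optimization — Gaussian-process surrogate (Matern 5/2) with expected
improvement over random candidate pools, seeded, with pure random search as
a fallback — over these spaces: tree (depth 1–32, min leaf 1–64,
log-scaled); Gaussian vs kernel-density naive Bayes (bandwidth 0.05–2);
SVM (linear/quadratic/cubic/RBF kernel, C 1e-3–1e3, kernel scale 1e-2–1e2,
both log; gamma = 1/scale²); kNN (k 1–64 log, Euclidean/Manhattan,
uniform/distance weights); ensembles (bagging / AdaBoost / gradient
boosting as the gentle-boost analogue, 50–500 learners, learning rate
1e-2–1); a one-hidden-layer MLP (4–128 units, L2 1e-6–1e-1).  The tuning
loss is the mean ten-fold CV misclassification; the winner is refitted on
the full training partition.

The cascade grades a pulse B when the BQ stage rejects it, otherwise F or E
according to the HQ2 stage; HQ2 itself is trained and scored on
ground-truth F/E pulses, with the cascade's error propagation reported
separately.  Metrics derive from the confusion counts (Acc, Sens, Spec,
Prec, F1, MCC, Cohen's κ by their count formulas); AUC uses the rank
statistic with midrank ties over each family's natural score (probability
where available, signed margin for the SVM); a one-class test set yields
AUC = NaN with the other metrics still reported.

Baselines: the similarity-threshold classifier fits the threshold on
training data by scanning all midpoints between consecutive sorted unique
scores (±∞ sentinels), minimizing |Sens − Spec| with ties to the smaller
candidate; the skewness baseline trains an SVM on the single skewness
column through the same tuning harness.

## Synthetic cohort

The generator emulates the study conditions end to end: 31 subjects ×
30 min (a desk-scale stand-in for day-long wear), PPG at 64 Hz, ACC at
32 Hz (±2 g).  Each beat is a sum of two Gaussians — systolic (amplitude 1,
center 30 % of the period, width 12 %) and diastolic (ratio 0.35, center
65 %, width 20 %) — at a subject heart rate ~N(70, 7) bpm with 3 %
beat-to-beat jitter.  The wide diastolic wave keeps the pulse curved
everywhere, so peak counting degrades gracefully with noise instead of
firing on a flat inter-beat segment.

Motion is organized per minute: intensities are drawn by stratified
quantiles from a rest/active mixture (35 % rest ≤ 0.002 g; active
lognormal, median 0.08 g, σ = 1), so every subject traverses the full
activity spectrum and every pooled quartile range is populated for every
recording (≥ 100 pulses per stratum at the default duration).  The
intensity scales independent band-limited noise (2–6 Hz) on each
accelerometer axis — broadband, like real limb motion, which keeps the
coupling between intensity and the gravity-removed vector magnitude the
same for every subject — on top of 1 g gravity and 0.005 g sensor noise.
The same intensity scales
band-limited (0.5–12 Hz) additive PPG noise:
sd = 0.005 + 8 × envelope (signal units per g).

Ground-truth labels derive from the generation parameters, not from
re-detection: a beat is Excellent when its local noise-to-signal ratio is
below 0.03 and its diastolic wave was retained, Bad at ratio ≥ 0.35, Fair
otherwise; diastolic suppression (probability 0.58) models beats whose
morphology degrades independently of motion.  These thresholds were
calibrated once, by Monte-Carlo, to the class mix the labelling conditions
target (≈ 48 % B / 37 % F / 15 % E) and to make the quality grades
meaningful to the features (Excellent pulses are genuinely smooth
two-wave shapes; Bad pulses are noise-dominated).  Simulated raters corrupt
the true label through a row-stochastic confusion matrix (default 93 %
diagonal, errors to adjacent grades), giving realistic but controllable
inter-rater agreement.

What the generator does *not* emulate: arrhythmias or other pathological
morphology, device-specific optical artifacts, skin-tone effects, baseline
wander from respiration, or non-stationary heart rates.  Passing tests on
this corpus demonstrate pipeline correctness (arithmetic, contracts,
recoverability, qualitative class structure), not clinical performance on
real wrist recordings.

## Problem sizes and numerical choices

The benchmark stages are run at sizes chosen to keep a laptop-scale run
comfortable: classifier tuning subsamples the training partition to ≤ 2,500
pulses (stratified by label) with 8 optimizer iterations for the headline
BQ/HQ1 numbers, and ≤ 2,000 pulses with 6 iterations for the cascade; NCA
demonstrations use 400-sample corpora.  Degenerate inputs follow explicit
rules: zero-variance pulses are dropped before feature extraction;
similarity against a zero-variance neighbour returns 0; identical scores
make the baseline threshold degenerate with a warning; ties in λ tuning and
threshold scanning resolve toward the smaller value.  All randomness flows
from a single integer seed through named substreams.
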