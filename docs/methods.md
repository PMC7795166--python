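# Methods

## Problem

Collar-mounted inertial sensors (3-axis accelerometer in g, 3-axis
gyroscope in °/s, nominal 100 Hz) can classify what a dairy calf is doing
— lying quietly or actively, ruminating, self-grooming, suckling at the
milk feeder (nutritive or non-nutritive), or locomotor play. Most of
these behaviours are also worth *counting*: play in particular is a
welfare indicator, but it occupies only a fraction of a percent of the
day. At such prevalences, counting the windows a classifier labels
positive ("classify and count", CC) is biased: with true prevalence `p`,
expected positive fraction is

    p0' = p·tpr + (1 − p)·fpr,

so any false-positive rate inflates the count by `(1 − p)·fpr`, which can
exceed `p` itself. The adjusted-count (AC) estimator inverts the relation,

    p' = (p0' − fpr) / (tpr − fpr),  clipped to [0, 1],

with `tpr`/`fpr` estimated by 5-fold cross-validation on the training
set. The package implements the full pipeline: windowing, feature
extraction, per-individual class balancing, boosted-tree classification
with the standard metric suite, ReliefF feature ranking, a
sampling-frequency degradation study, and AC quantification of play.

## Pipeline conventions

**Windows.** Recordings are discretised into windows of 1–10 s with 50%
overlap (hop = half a window). A window is labelled `b` iff intervals of
behaviour `b` cover strictly more than half of its span; otherwise it is
unlabelled — excluded from classifier training and evaluation, but kept
in the quantification "non-play" pool, as any deployment stream would
keep them. Majority labelling is the tie-break we chose for windows that
straddle bout boundaries; exactly 50% coverage does not label.

**Features.** All features are computed from the magnitude (Euclidean
norm) of the accelerometer and of the gyroscope, never from individual
axes, making them invariant to mounting orientation. Four streams (accel
magnitude, gyro magnitude, and the first difference of each) × 11
statistics = 44 features. Time domain: mean, min, max, excess kurtosis
(defined 0 for zero-variance windows), zero-crossings of the mean-centred
signal (strict sign change; samples exactly on the mean break a
crossing), signal area (Σ|s|/fs, value·seconds). Frequency domain, on the
one-sided rectangular-taper periodogram with the DC bin removed:
normalised spectral entropy (0 for zero-power, 1 for flat), spectrum
minimum, first quartile of the unit-sum spectrum (linear interpolation),
mean-crossings of the spectrum, spectrum area (total power × bin width).
The catalogue is an ordered, name-keyed object, validated to hold exactly
44 uniquely named entries (22 per modality) and replaceable via YAML.

**Balancing.** Free-living class frequencies are wildly skewed. Before
training, each (animal file, behaviour) group is capped at
`floor(s_min/k_b)` windows, where `s_min` defaults to the total count of
the rarest behaviour and `k_b` is the number of files containing
behaviour `b`; groups at or below the cap are kept whole. Flooring keeps
the per-behaviour total within budget; per-group RNG streams are derived
from the master seed and stable group keys, so results do not depend on
iteration order.

**Classifier.** SAMME AdaBoost over CART trees with minimum leaf size 5
and a cap of `max_splits` internal splits (default 20); 100 learners and
unit learning rate by default, all configurable and recorded in reports.
Evaluation is stratified 5-fold cross-validation: the report is the mean
of per-fold metrics; the pooled held-out confusion matrix is returned
alongside. Per-class metrics are one-vs-rest; zero-denominator rates are
reported as 0 and flagged. Cohen's kappa uses marginal-product chance
agreement. Postures (2-class, 4-s windows) and behaviours (7-class, 3-s
windows) are separate models.

**ReliefF.** Hand-implemented (no pre-packaged implementation is
available in this stack): min-max scaling to [0,1], Manhattan diff,
k=10 neighbours, every sample as anchor by default (deterministic),
miss contributions weighted by class priors. Constant features score 0.

**Down-sampling.** 100 Hz → {50, 20, 10, 4} Hz by keeping every d-th
sample from the first (d = 2, 5, 10, 25), deliberately without
anti-alias filtering — it emulates a sensor that records less often, not
a decimation filter. The frequency study recomputes features from the
down-sampled raw signal, re-balances with the same spec, re-evaluates,
and reports per-behaviour percentage decreases; by default these are
relative, `100·(m₁₀₀ − m_f)/m₁₀₀`, with absolute percentage-point
differences behind a flag, since "percentage decrease in performance"
admits both readings.

**Quantification.** Dataset split 50/50, stratified on the play label so
the rare positives appear in both halves. On the training half a sweep of
training conditions (p positives vs NP = 10,000 negatives, p = 10…190 by
default) estimates tpr/fpr per condition via pooled 5-fold CV; the
condition maximising tpr − fpr is selected (ties → smaller p, the
cheapest labelling), a final binary ensemble is trained on that
condition's subsample, CC is computed on the test half and corrected by
the AC formula. The adjusted count is `round(p'·n_test)`. tpr ≤ fpr
raises an "uninformative classifier" error rather than returning a
nonsense estimate. Negatives are resampled per condition under derived
seeds. The sweep varies the *training prevalence* (the reading of the
text we follow); a per-condition score-threshold grid would be a
reasonable alternative and the sweep table is returned so either policy
can be audited.

## Synthetic data

No public labelled calf recordings exist, so the simulator supplies the
study conditions. Per animal it draws a semi-Markov bout sequence: states
without self-transitions, bout lengths log-normal truncated at the 3 s
minimum the observation protocol imposes, and selection weights solved
(via `w(1−w) ∝ prevalence/mean-bout`, accounting for the stationary law
of a self-transition-free chain) so that long-run time fractions match
the configured prevalences exactly — play defaults to 0.27% of time.
Each bout renders as: 1 g gravity on the accelerometer z-axis, a DC
movement intensity plus optional sinusoid on the x-axes (the DC pedestal
keeps the magnitude periodic at the oscillation frequency itself rather
than its double), white noise on all six channels, and Poisson-timed
0.3-s half-sine transients. Signals are float32.

Default regimes (`data/default_regimes.yaml`) were designed once to give
*moderate* separability: self-grooming is deliberately near-play-like
(similar burst amplitude and rate, lower intensity, slower oscillation),
so the binary play classifier has tpr ≈ 0.9 and fpr of a few 10⁻⁴ and
naive CC visibly overestimates — the regime AC is designed to correct.
These parameter values are design choices, not estimates of real calf
signal statistics, and the generator makes no claim to biomechanical
realism (no collar slip, no orientation drift, no inter-animal
variation). Passing tests therefore demonstrate the pipeline's
correctness and the estimator's behaviour under its stated assumptions,
not field performance on real calves.

## Problem sizes and numerical choices

The end-to-end quantification experiments simulate 15 animals × 4 h
(≈144k 3-s windows; the ~72k-window test half matches the scale of the
worked example), with a 3-point condition grid (p = 50, 120, 190),
NP = 8,000 and a 5-round, 9-leaf-tree ensemble — sizes chosen so a
replicate runs in tens of seconds on one core while keeping the fpr
estimate's resolution (1/NP) well below the fpr being estimated. The
deliberately small ensemble makes the binary classifier imperfect; the
adjusted count is the component under test, and its correction is
largest exactly when the classifier is weak. The degradation study
runs four custom regimes (bursty play-like; an 8 Hz-textured state; an
identical-intensity texture-free state; quiet lying) on 6 animals ×
25 min: at 4 Hz the stride-25 subsample maps an 8 Hz sinusoid exactly to
a constant, so the textured state loses its identity while the bursty
class survives — the Nyquist mechanism behind the observed pattern that
play tolerates 4 Hz sampling while fine-textured feeding behaviours do
not.

Other conventions: non-uniform timestamps are rejected, not resampled;
down-sampling requires an exact 100 Hz input; window counts follow
`floor((N − w)/h) + 1`; all stochastic steps (simulation, balancing,
fold shuffling, condition subsampling) derive their streams from a single
master seed, and identical seeds give byte-identical outputs.

## Known limitations

- The 44-feature catalogue reconstructs the published naming scheme
  (time/frequency × raw/difference × accel/gyro); the original exact
  feature list is not public, so the catalogue is config-replaceable.
- AC assumes the training-half rate estimates transfer to the test half;
  boundary (unlabelled) windows make the effective test-time tpr slightly
  lower than the CV estimate, leaving a residual error of roughly ±15%
  on the play count at 0.27% prevalence — still several-fold smaller
  than the CC bias under the same conditions.
- Max-selection of tpr − fpr over a noisy sweep is slightly optimistic
  (selected fpr biased low), a known property of the selection policy.
- Multi-class quantification and concept drift are out of scope.
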