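# Methods

`ethoclass` implements a supervised behaviour-classification pipeline for
animal-borne tri-axial accelerometers, modelled on captive otariid (fur
seal and sea lion) deployments: a back-mounted logger sampling at 25 Hz
over a ±8 g range, a 26-behaviour ethogram grouped into five categories
(foraging, grooming, resting, travelling, other), and a four-family model
comparison evaluated on two animals held out entirely from training.

## Signal model and feature extraction

Raw acceleration on each axis is split into a **static** component — a
centred running mean over `round(3 s × rate)` samples (75 at 25 Hz),
truncated symmetrically at the trace edges so the window stays centred —
and a **dynamic** component, raw minus static. From the dynamic components
come the dynamic body acceleration family:

    PDBA_a = |a_dyn|,  ODBA = |x_dyn| + |y_dyn| + |z_dyn|,
    VeDBA = sqrt(x_dyn² + y_dyn² + z_dyn²)

with the norm inequality `VeDBA ≤ ODBA ≤ √3·VeDBA` holding per sample.
Posture angles come from the static vector: inclination
`arccos(static_z/|static|) ∈ [0, π]` and azimuth
`atan2(static_y, static_x) ∈ (−π, π]`; samples with zero static magnitude
are flagged missing and excluded from epoch means. Whether posture should
be computed from static or raw acceleration is a genuinely open choice;
static is used because the raw vector mixes posture with limb-beat
dynamics at exactly the frequencies the other statistics already capture.

Traces are summarised into **epochs of 13 samples (~0.5 s)**, short enough
to capture the briefest behaviour (a 0.25 s body shake). Epochs are
non-overlapping by default (stride = epoch length, configurable): with
per-sample sliding the epoch count would exceed the sample count by an
order of magnitude relative to the deployment sizes this design targets.
Each epoch carries **52 movement statistics**:

* per raw axis (×3): mean, median, sd, skewness, kurtosis, min, max,
  mean absolute value, inverse coefficient of variation (mean/sd), AR(1)
  coefficient — the OLS slope of each sample on its one-sample lag;
* vector magnitude q: mean, sd, min, max;
* pairwise axis correlations x–y, y–z, x–z;
* mean inclination, circular-mean azimuth;
* mean PDBA per axis; ODBA and VeDBA mean, sd, min, max; trapezoidal AUC
  of ODBA and VeDBA over the epoch with dt = 1/rate.

Conventions: sd uses ddof = 1; skewness and excess kurtosis are the plain
moment estimators m₃/m₂^1.5 and m₄/m₂² − 3. Degenerate epochs
(zero-variance axis) get flagged zeros for sd-derived, correlation and
AR(1) statistics rather than NaNs, so downstream models never see missing
values. The exact 52-statistic inventory is a reconstruction from the
named quantity families; the column list is exposed as
`FEATURE_COLUMNS` and the featurizer is column-order stable.

Each epoch also carries its modal place (surface / underwater / land),
which is always included as a predictor (one-hot), and optionally five
subject covariates: attachment method, age, mass, sex, species.

## Synthetic data generator

No public recordings exist for this kind of deployment, so the generator
is a first-class module. Each behaviour has a signature: a unit gravity
vector set by body pitch/roll, a sum of sinusoidal oscillators (axis,
amplitude, frequency, random-walk phase jitter), and white Gaussian noise;
bouts follow a semi-Markov schedule (category from a row-stochastic
transition matrix, behaviour uniform within category, log-normal duration
truncated to [0.25 s, 210 s]). Sessions default to 400 s per subject —
long enough that, over a 12-subject cohort, at least one training class
exceeds the 3000-epoch balancing cap so the under-sampling path is
genuinely exercised — and 12 subjects, matching the leave-two-out design
(10 train / 2 holdout). Signature parameters are free modelling choices
(no published per-behaviour signal parameters exist); they are set so the
assumed class structure emerges: resting near-static (oscillator
amplitudes below the noise floor), grooming mid-amplitude and fast
(3–5 Hz), travelling and foraging high-amplitude in overlapping 1–4 Hz
bands, giving per-class mean ODBA ordered resting < grooming <
travelling ≈ foraging.

Two knobs shape the learning problem:

* `separability ∈ (0, 1]` interpolates every behaviour's dynamic signal
  power (oscillator power + noise variance, rescaled together) toward the
  cohort grand mean. At 1 the signatures are as specified; toward 0 the
  between-class amplitude contrast collapses. The bout schedule and the
  signal noise use independent seeded streams, so changing separability
  never changes the schedule.
* subject mass scales oscillator frequency by `(mass/60 kg)^(−1/3)` —
  larger animals beat slower — which is what makes the subject covariates
  genuinely informative rather than decorative.

Two variant ethograms support the protocol experiments. The
**covariate-experiment (mass-scaled) variant** gives travelling and
foraging identical orientation, place, axes mix, amplitudes and noise,
differing only in beat frequency, with two subject-level mechanisms on
top: within any animal foraging beats 2.6× faster than travelling, and
fur seals run every beat 2.6× slower than sea lions (otariid lineages
differ in gait and prey processing; the factor is chosen equal to the
within-animal band ratio). A fur seal's foraging band therefore coincides
with a sea lion's travelling band; with the mass scaling and a per-bout
log-normal frequency jitter (sd 0.12) smearing every band into a
continuum, an observed beat is ambiguous between the two categories
unless the subject covariates are available — and with them the decision
rule "faster beat means foraging, with a species-specific threshold" is
expressible by every family, linear ones included. One caveat is itself
informative: because mass and age are continuous and nearly identify
individual training animals, the linear family can convert them into
per-subject prior shifts that extrapolate poorly to held-out animals, so
its covariate gain, while large under the default experiment seed, is the
least stable across cohort draws — an honest reflection of why covariates
help tree and kernel models more reliably. The **overlapping** variant
emulates feeding-trial sessions: foraging is many short, tightly on-band
capture/manipulation bursts (tempo prey-determined, hence exempt from the
allometric mass scaling), while each travelling behaviour shares a
foraging signature centre but wanders broadly around it (wide per-bout
frequency jitter — a noisy, variable gait). Concentrated foraging
examples dominate the shared band everywhere, so classifiers absorb
travelling into foraging while travelling keeps only its off-band tails —
reproducing, as an emergent property, the confusion structure reported
for real seals: travelling the hardest category, mistaken mostly for
foraging. The companion feeding-session transition matrix sets bout
weights so the duration-weighted epoch shares of the two classes come out
roughly equal.

What the generator does **not** emulate: biomechanical waveform realism
(real strokes are not sums of sinusoids), behavioural autocorrelation
beyond first-order category transitions, drift or calibration error in the
logger, wet/dry or depth channels, and within-behaviour variability across
individuals beyond the mass–frequency law. Passing tests therefore show
that the pipeline recovers structure of the kind assumed, not that any
accuracy level would transfer to real deployments.

## Dataset construction

Epochs are labelled by the majority category of their samples; exact ties
break by precedence foraging > grooming > travelling > resting (grooming
and foraging dominate travelling and resting; foraging wins a direct tie
with grooming; the travelling-over-resting edge is this package's choice
since only the pairs are constrained). Epochs labelled 'other' (husbandry,
out of sight) are dropped and counted. The subject-wise split holds out
two animals — by default one female sea lion and one male fur seal when
the cohort contains them, spanning the range of body plans — and training
classes are capped at 3000 epochs by seeded uniform under-sampling;
smaller classes are untouched, and held-out data is never balanced so it
keeps the skewed class mix of a wild deployment.

## Models and selection

Four families: penalised multinomial logistic regression (elastic-net; the
(mixing, strength) pair maps to l1_ratio and C = 1/strength), SVM with
linear/polynomial/radial/sigmoid kernels (one-vs-one with Platt
probability calibration), random forests, and stochastic gradient-boosted
trees (xgboost). Logistic and SVM standardise predictors with constants
stored at fit time; tree families consume raw features. Hyperparameters
are selected by a 70/30 epoch-level split of the training data with
10-fold cross-validation on the 70 % part (epoch-level folds, keyed to
stable epoch identifiers so row order is irrelevant); the winner refits on
the full 70 % and reports accuracy on the 30 % validation part, then on
all training epochs before held-out evaluation. The packaged default grid
file brackets the best published parameter sets per family (e.g. SVM
polynomial degree 4, gamma 0.01, coef0 4, cost 1; GBM learning rate 0.01
with 5000 rounds); `fast_grids()` provides the one-point-per-family grids
used for the small synthetic cohorts, where 5000-round ensembles would add
hours without changing any conclusion.

## Evaluation

`confusion()` tallies predictions against truth in a fixed class order
(foraging, grooming, resting, travelling) with configurable row semantics.
Sensitivity is diagonal over row sum — under the printed-table convention
(rows = true class) this is per-class recall — and a row-sum-weighted mean
of sensitivities equals overall accuracy exactly. Specificity is computed
column-wise as TN/(TN+FP) with a documented caveat: the published
specificity column for these matrices does not match this (or any single
standard) formula, so those values are catalogued as known mismatches
rather than asserted. Two further arithmetic quirks of the published
tables are preserved deliberately: the GBM matrix totals 29 315 cells
against a stated 24 795 held-out epochs (its printed accuracy uses the
matrix's own total), and the SVM matrix's cells total 24 670 while its
printed accuracy divides by the stated 24 795; both denominator paths are
labelled in the fixture report.

## Problem sizes and numerical choices

The protocol experiments run on 12-subject cohorts of 400 s sessions
(~9 200 epochs before 'other' exclusion), one session per subject; this is
the package's default simulation scale and completes a full four-family
protocol (both covariate settings) in a few minutes on one CPU. Logistic
regression uses saga with tol 1e-3 and a bounded iteration count;
probabilities are renormalised to the simplex before argmax; prediction
ties break by the fixed class order. Seeds fan out to per-subject and
per-stage streams by stable hashing (CRC32 of subject id mixed with the
run seed), so cohorts are reproducible subject-by-subject and
bit-identical across runs and platforms.

## Known limitations

* The 52-statistic inventory is one defensible reconstruction; alternates
  (e.g. spectral band power) are out of scope.
* The printed training-side accuracies of the original comparison cannot
  be recomputed from raw data (recordings undeposited); only the held-out
  confusion-matrix arithmetic is reproducible, and is.
* Synthetic cohorts are much smaller than a real multi-session deployment;
  accuracies on them characterise the pipeline, not field performance.
* The published specificity formula remains unrecovered; mismatches are
  reported, not resolved.
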