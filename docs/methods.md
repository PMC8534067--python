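# Methods

`oculoml` implements a complete, testable analogue of a binocular
eye-movement screening study: synthetic recordings of LED-guided vergence
and saccade tests plus reading, velocity-threshold extraction of
physiologic descriptors, per-subject aggregation, and two statistical
analyses — dyslexia classification with permutation significance, and
reading-speed regression with fold-internal feature selection.  This note
records the models, the defaults and why, the numerical choices, and the
limits of what the synthetic experiments demonstrate.

## Stimulus geometry

Targets sit on the subject's median plane at 40 cm (fixation), 20 cm
(convergence target) and 150 cm (divergence target); lateral saccade
targets at 20° eccentricity.  The binocular fixation of a target at
distance *d* requires the vergence angle

    theta(d) = 2 * atan(ipd / (2 d)),

with interocular distance `ipd = 6.0 cm` by default — the value that
reproduces the nominal 9° / 17° / 2° target angles (and the 8°
convergence step) under integer rounding.  Each trial shows the fixation
LED for a uniformly drawn 1400–2000 ms, then the target LED for 2000 ms
with a 200 ms overlap; a vergence test interleaves 20 convergence and 20
divergence trials, a saccade test 20 left and 20 right.

## Movement model

Movements follow a raised-cosine position ramp of amplitude *A* and
duration *D*,

    x(t) = A/2 * (1 - cos(pi t / D)),   0 <= t <= D,

whose velocity is a half-sine with peak `Vp = pi |A| / (2 D)` — smooth,
unimodal, with the closed-form peak a main-sequence parameterization
needs (`main_sequence_slope` fixes `D = pi / (2 slope)` so peak velocity
scales with amplitude).  Defaults: vergence steps of ±7–8° in 450 ms
(peak ≈ 28 °/s), saccades of 20° in 70 ms (peak ≈ 450 °/s), both with
±8 % per-trial duration jitter.  After the ramp each eye drifts
exponentially (`d_e (1 - e^{-t/tau})`, `tau = 80 ms`); the left-minus-
right drift difference is the disconjugate drift.  Saccades additionally
carry a left-minus-right amplitude difference (disconjugacy, default
0.2° ± 0.1°).  White position noise (SD 0.05° per eye) approximates
video-oculography noise; a blink (2 % of trials) replaces 100 ms of both
traces with a large, unequal downward excursion so that aberrant-value
handling is exercised.

Sign conventions: rightward positive per eye; vergence = left − right
(convergence positive); conjugate = (left + right)/2.

**Criterion-referenced ground truth.**  Latency and amplitude are
operational quantities: they are defined by the velocity criterion that
bounds the movement (5 °/s for vergence; 10 % of peak for saccades).
Every generated trial therefore records, in closed form, the values that
an ideal threshold analysis would measure on the noiseless profile — the
criterion crossing times, the amplitude between them
(`A cos(pi t_c / D)`), the post-offset 80/160 ms components including
the residual ramp tail, and the analytic peak.  The generator places the
ramp so the onset criterion is crossed exactly at the drawn latency.
Recovery tests compare the extraction pipeline against these values, so
they measure numerical error, not a definitional mismatch.

## Reading traces

Reading is alternating fixations and small saccades: gamma-distributed
fixations (shape 4, mean 250 ms), one 2° progressive saccade per word,
and a −1.5° regressive saccade inserted before a word with probability
0.15 (defaults; all configurable).  Each fixation carries a small
disconjugate drift.  Reading speed is words divided by trace duration in
minutes.  No return sweeps, vertical components or line structure are
modeled; the trace is what the conjugate-channel segmentation needs, not
a typographically faithful reading record.

## Cohorts

A cohort (default 41 controls + 46 dyslexic subjects, mirroring the
scale of the adolescent cohorts this kind of study uses) draws
subject-level parameters around group means: the dyslexic group's
parameters are the control values plus configurable offsets — by default
+30 ms latency, ×1.25 movement duration (≈ −20 % average velocity), ×2
post-movement drift, ×1.5 disconjugacy, ×1.8 regression rate, +30 ms
fixation duration, directions and rough magnitudes chosen to emulate the
group differences reported for dyslexic adolescents on these tests.
Between-subject spreads (latency SD 25 ms, duration log-SD 0.10, etc.)
make single descriptors informative but not individually diagnostic.
Reading speed is a linear model on the subject's true parameter values
(intercept 365 words/min; negative weights on saccade/vergence latency,
movement duration, regression rate and drift; noise SD 15 words/min),
calibrated so control and dyslexic means land near ~175 and ~135
words/min.  Randomness is counter-based: subject *i* draws from
`default_rng([master_seed, i])`, so enlarging a cohort never perturbs
existing subjects.

A second, descriptor-level generator (`generate_feature_cohort`) draws
per-subject feature rows directly (iid standard normal, optional group
mean shifts, speed from a planted linear model).  It exists for
calibration-scale Monte Carlo — hundreds of cohorts for permutation-test
uniformity, planted-model recovery — where trace synthesis adds cost but
no information.  Pipeline-level claims are always exercised on the
trace-level generator.

## Event extraction

Channels: vergence = left − right, conjugate = mean.  Velocity is a
central difference after a 5-sample (25 ms) moving average.  Detection
and measurement are deliberately separated:

* **Vergence movements** are bounded by the first rise above and the
  subsequent drop below 5 °/s.  Bursts shorter than 20 ms or moving less
  than 0.5° are treated as noise blips and skipped, so the first *real*
  movement in the window is returned.
* **Saccades** are located by a practical 40 °/s floor (for reading,
  30 °/s, since reading saccades are small), then bounded at 10 % of the
  movement's peak velocity; for a 400 °/s peak the two rules coincide.
  Peak velocity and the threshold crossings are refined on the *raw*
  central difference: the moving average attenuates a 70 ms saccade's
  ~14 Hz fundamental by a few percent, which is exactly the scale of the
  quantities of interest.
* **Sub-sample refinement.**  At 200 Hz a sample is 5 ms and a 20°
  saccade moves ≈ 0.2° per sample at its 10 % bound, so sample-grid
  event bounds are too coarse.  Crossing times are linearly interpolated
  on the velocity trace and positions at crossing times are read off a
  local 4-point cubic; the sampled peak is parabola-refined.  On
  noiseless recordings this keeps worst-case errors near 1 ms latency,
  0.07° amplitude and 1 % peak velocity (the acceptance suite bounds
  them at 5 ms / 0.1° / 2 %).

Per-trial descriptors: latency (onset − target onset), phasic amplitude,
the amplitude changes over the 80 ms and 160 ms after offset, total
amplitude (phasic + 160 ms component — an exact sum by construction),
phasic and total duration (phasic + 160 ms), peak and average velocity
(|total amplitude| / total duration), and for saccades the disconjugacy
(left − right amplitude over the conjugate-defined interval) and the
disconjugate drift over both windows.  Trials are aberrant when no
movement is detected in the 2000 ms window, latency falls outside it, or
kinematics are implausible (amplitude outside 0.5–30°, peak velocity
above 1000 °/s conjugate / 300 °/s vergence — blinks trip these bounds).
The drift windows are measured from each channel's own detected offset.
Reading fixation durations are the intervals between consecutive
detected saccades (the conventional reading, adopted deliberately; a
literal "interval between fixations" reading would measure saccade
durations instead), and the regressive percentage is
100 × leftward / rightward saccade counts.

## Feature tables and cleaning

Per subject and per (test, trial kind, descriptor) the table holds mean,
sample (n−1) standard deviation, coefficient of variation
(SD/mean × 100) and valid-trial count, named
`test.descriptor.statistic`.  Cells that cannot be computed (no valid
trials, CoV at zero mean, single-trial SD) are flagged aberrant, not
silently zeroed.  Two cleaning rules:

* classification — aberrant cells become 0 (treating artifacts as
  informative of recording quality rather than imputable);
* regression — within each diagnostic class and column, values strictly
  outside the 3rd–97th percentile band (linear interpolation between
  order statistics) are replaced by the within-class pre-replacement
  mean; aberrant cells get the same mean, since a zero placeholder would
  distort the percentile band itself.

Row order is then shuffled deterministically.

## Analysis 1 — classification

Eleven classifier families, four linear (L1-penalized logistic
regression, linear SVM, LDA, Gaussian naive Bayes) and seven non-linear
(RBF SVM with gamma = 0.01, QDA, k-NN, Gaussian process, a small MLP,
random forest, decision tree), all with every hyperparameter written
explicitly into the roster and no tuning anywhere.  Because the
descriptor tables are wide (≈ 230 features for fewer than 100 subjects),
the two discriminant models use shrinkage-regularized covariances
(LDA: lsqr + Ledoit–Wolf shrinkage; QDA: eigen solver + Ledoit–Wolf),
and the two neural models use the lbfgs solver, which is the appropriate
optimizer at this sample size.  Evaluation is stratified shuffled 5-fold
CV (stratified because an ~46/41 split makes unstratified folds
occasionally degenerate); at each fold both blocks are standardized with
the training mean and SD only (constant columns divide by
max(SD, 1e−12)), and accuracy/sensitivity/specificity are averaged over
folds.  The positive class is *dyslexic*.  The best model is the
lexicographic maximum on (accuracy, sensitivity, specificity), residual
ties broken by fixed roster order.

Significance: R label permutations of the entire dataset (default
1000), each re-running the full CV (fold construction included; a
fixed-folds variant sits behind a flag), with
p = #(permuted ≥ observed)/R.  The plain estimator is the default so a
score above all replicates reports exactly 0.000; the bias-corrected
(1+#)/(1+R) variant is available.  With small cohorts CV accuracies tie
frequently, which makes the plain estimator mildly conservative — the
calibration suite checks uniformity at cohort sizes where the
discretization is unimportant.

## Analysis 2 — regression

Reading speed is predicted from the cleaned features by linear
regression, an RBF SVR (gamma = 0.01), and a two-layer neural network
sized to ≈ 60 trainable parameters (hidden width 5 on 10 inputs:
10·5 + 5 + 5 + 1 = 61, recorded as approximate).  At each fold the 10
features with the largest |Pearson r| against speed *on the training
rows* are selected (absolute value deliberately, so strongly negative
descriptors survive; signed ranking sits behind a flag; constant columns
are excluded; ties break by name).  Out-of-fold predictions are pooled
before computing MAPE = 100·mean(|y−ŷ|/y) and the Pearson correlation
between prediction and truth — one pooled scatter, not a per-fold
average.  The best model is the lowest-MAPE one.  Stability reporting
lists features selected in ≥ 4 of 5 folds with their full-dataset
correlation and the two-sided p-value from the standard t-transform of
r.  The percentile cleaning runs before the CV split (its class-wise
means see all rows); this mirrors a pre-modeling preprocessing stage but
is a potential, documented, leakage path — the fold-internal selection
and standardization are the guarded steps.

## What the synthetic experiments do and do not show

The generator reproduces the statistical *structure* the analyses
assume — criterion-defined kinematics, between-subject variability,
group offsets, artifact cells, a descriptor-linked reading speed — so
passing tests demonstrate that the extraction is numerically faithful,
that the CV and permutation machinery are unbiased and leak-free, and
that planted effects of realistic size are found.  They do not show that
real dyslexic and control adolescents separate at any particular
accuracy: real main sequences, drift shapes, tracker noise spectra and
descriptor covariances differ from the raised-cosine/white-noise
idealization, and the clinical cohort behind the published accuracies is
not public.  Problem sizes in the test-and-acceptance suite (200
noiseless trials for recovery; 200 exchangeable cohorts of 30 subjects
at R = 99 for calibration; one 100 + 100 strong-effect cohort; n = 200
with 5 planted descriptors at R² = 0.5 for regression) were chosen as
the smallest scales at which the corresponding statistical statements
are stable across seeds.

## Known limitations

* Raised-cosine kinematics have symmetric velocity profiles; real
  saccades are mildly asymmetric and vergence often shows a slow
  late component beyond the single exponential drift.
* Blinks are the only artifact class; no pupil-size coupling, no
  tracker dropouts, no head motion.
* The reading model has no line sweeps and a single saccade amplitude
  per direction.
* The study-scale permutation p-values are granular at 1/R and the
  plain estimator is conservative under heavy score ties.
* Fixed extraction thresholds (5 °/s, 40 °/s, 10 %) are not adapted per
  subject; very slow vergence (peak < 5 °/s) would be invisible by
  construction.
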