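# Methods

This note documents the models, algorithms and numerical choices behind
`jointgaze`, in the spirit of a statistical package's methods appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Paradigm and geometry

A session consists of 16 trials of 11 s (attention grabber at 0 s, intro
at 1 s, target cueing at 3 s, outro at 9 s), sampled at 300 Hz on a
27-inch 1920×1080 screen. The full cross of four cueing conditions
(neutral, mild, intense, neutral+pointing) and four object stimuli gives
the 16 trials; target side is counterbalanced 8/8 and the presentation
order is a seeded permutation within two blocks of eight. All time
windows are half-open `[t0, t1)` and trial-local time zero is the
attention-grabber onset.

Pixel displacements convert to visual angle per axis as
`atan(pitch · d / distance)`, combined across axes as a Euclidean norm.
The physical pixel pitch follows from the 27-inch diagonal and the 16:9
pixel grid (597.9 × 336.3 mm). **Viewing distance is a mandatory,
explicit parameter** (default 650 mm, typical for a remote tracker in a
child lab); it is not a property of the hardware and silently assuming
it would bias every velocity.

## Gaze cleaning chain

Order: segment → blink correction → plausibility filter → smoothing →
velocity → adaptive threshold → saccades → fixations → trial quality.
Cleaning is monotone (a non-valid sample never becomes valid again), and
per-sample status is one of `valid / missing / blink / excluded /
implausible`.

- **Blink correction.** Tracking-loss runs of 75–250 ms (inclusive) are
  blinks; valid samples within 25 ms (8 samples) before/after are
  excluded as eyelid-motion artefacts. Shorter or longer gaps are left
  as generic missingness.
- **Plausibility filter.** The velocity rule (> 1000 °/s) runs on *raw*
  combined coordinates as an anchored forward scan: a sample that
  implies an implausible velocity relative to the last accepted sample
  is dropped without advancing the anchor, so isolated spikes do not
  contaminate their neighbours. The acceleration rule (> 10 000 °/s²)
  is evaluated on a Savitzky–Golay (70 ms) estimate of the velocity
  series instead of raw sample-to-sample differences: at 300 Hz, raw
  acceleration noise from ordinary tracker jitter (≈ 0.3° RMS) is tens
  of thousands of °/s², so a raw rule would discard large fractions of
  perfectly valid data; genuine spike artefacts are already caught by
  the velocity rule.
- **Smoothing.** Savitzky–Golay, 70 ms window (21 samples, forced odd),
  polynomial order 3, applied within contiguous valid runs only — never
  across blinks or gaps. Runs shorter than the window are passed
  through unsmoothed and logged.
- **Velocity.** Central differences of the smoothed angular position;
  undefined (NaN, never interpolated) at run edges.

## Saccade and fixation detection

The saccade threshold is estimated **once per session** (noise level is
a property of a recording, not a trial): starting from PT₀ = 100 °/s,
iterate PTₙ = mean + 6 SD of samples below PTₙ₋₁ until the change is
below 1 °/s (max 50 iterations); onset/offset extension uses mean + 3 SD
of the final sub-threshold samples. Degenerate inputs (noise-free
synthetic data) floor the threshold at 10 °/s; fewer than 1 s of defined
velocity falls back to the fixed initial threshold. All constants sit in
`CleaningConfig`.

A saccade is a maximal run at/above the peak threshold, extended both
ways to the onset threshold, with duration ≥ 10 ms and amplitude ≥ 1°.
Two detection guards reflect how adaptive thresholds behave on smoothed
noisy data: candidates separated by < 30 ms are merged (a single dropped
sample otherwise splits one movement in two; 30 ms is well below any
real inter-saccadic fixation), and the 1° amplitude floor discards
micro-excursions where correlated noise rides over the threshold for a
few samples without any gaze shift.

Fixations are maximal valid runs outside saccades that satisfy a
stability criterion and last ≥ 100 ms; the centroid is the mean smoothed
position. Two stability modes exist because the criterion "position
change smaller than 1 °/s" mixes units: the default `velocity` mode
(smoothed angular velocity < 1 °/s, the literal reading — appropriate
for clean or low-noise data) and a `dispersion` mode (position range
< 1° within a centred 100 ms window). With realistic positional noise
the literal 1 °/s bound is unattainable (smoothed velocity noise alone
is an order of magnitude larger), so noise-robustness experiments use
the dispersion mode; the choice is logged.

A trial is dropped when less than 50 % of its samples remain valid;
exactly half retained is kept.

## RJA scoring

A trial is RJA-positive iff some fixation on the cued target AOI starts
in the cueing phase or later (onset ≥ 3 s) and a head-AOI fixation ends
within the 500 ms before that onset (gap ∈ [0, 0.5] s, offset-to-onset
by default; onset-to-onset is available). Latency is the first
qualifying target-fixation onset minus cueing onset; RJA duration is
that fixation's dwell (or the sum over qualifying fixations, by config).
AOI membership is by fixation centroid with half-open boxes; the
distractor-side object neither qualifies nor disqualifies; the pointing
condition uses the same regions (no hand AOI), so scoring has no
condition-dependent branches. The scorer is deterministic,
order-invariant, and is tested against a brute-force all-pairs oracle.

## Pupil features

Per eye: values outside (2, 8) mm dropped; samples deviating more than
3 × MAD from a 150 ms rolling median dropped (a constant trace has
MAD 0, so any spike on it is removed); gaps up to 150 ms (counted as
missing-samples × sample interval) linearly interpolated between
flanking valid samples — valid samples are never altered and longer gaps
stay missing. Eyes are cleaned first, then combined (mean where both
valid, single eye otherwise). BPS = mean diameter over [0, 0.5) s (the
pre-transient half of the attention grabber); the trace is normalized by
subtracting BPS; SEPR = mean normalized diameter over [4.5, 5.5) s,
which may be negative. Each window requires ≥ 50 % valid coverage,
echoing the trial-level rule; otherwise the feature is absent (never
imputed). BPS and SEPR inherit shift-equivariance: adding a constant to
the trace moves BPS one-to-one and leaves SEPR unchanged.

## Synthetic sessions

The generator exists so that every downstream stage can be validated
against known ground truth; it emulates the paradigm's structure rather
than any individual child.

- **Gaze.** A behaviour plan lists fixation targets and dwells; saccades
  between them follow the main-sequence law Vp = 500(1 − e^(−A/15)) °/s
  with a symmetric raised-cosine velocity profile (duration 2A/Vp).
  Peak acceleration is additionally capped at 9000 °/s² — slightly
  slowing saccades above ~13° — so generated movements stay inside the
  plausibility envelope the cleaning chain enforces; a generator whose
  output its own filters would shred is not a usable oracle. Blinks are
  tracking-loss gaps in both gaze and pupil channels; per-eye white
  positional noise is configurable in degrees.
- **Pupil.** Piecewise-linear diameter profiles: flat baseline, a
  luminance-adaptation bump after 0.6 s, a cueing-locked ramp whose
  plateau spans 4.4–5.6 s at `bps + sepr`, and a slow return. Both
  feature windows lie on exactly flat segments, so BPS and SEPR recovery
  is exact at zero noise by construction.
- **Cohorts.** Per-trial RJA outcomes are Bernoulli with
  `logit p = fe(group, timepoint) + u_participant + v_trial +
  slope · (BPS − BPS_ref)`; groups may shift BPS (the mediation path)
  and SEPR is inversely coupled to BPS. Defaults follow the study
  design: groups A-FFIP (n = 32) and EIAU (n = 28) at baseline /
  end-of-treatment / follow-up plus non-autistic (n = 52) at baseline /
  follow-up, 16 trials, participant intercept SD 1.0 and trial intercept
  SD 0.3 on the log-odds scale, BPS 4.3 ± 0.4 mm between participants
  with a −0.5 log-odds/mm slope — magnitudes on the scale typical of
  preschool pupillometry and per-trial gaze-following rates. Identical
  spec + seed yields byte-identical files. `simulate_feature_table` draws the
  outcome table directly for statistical experiments;
  `simulate_cohort` renders full sample files.

What the generator does **not** emulate: smooth pursuit, head movement,
calibration drift, temporally correlated tracker noise, luminance-driven
pupil dynamics beyond the stylized bump, or condition effects on RJA
(none are modelled, matching the screen of task-condition factors).
Passing tests therefore certify the pipeline's correctness on signals
with these idealizations, not its field accuracy on any particular
tracker.

## Mixed models

Both families share one penalized decomposition with crossed random
intercepts for participant and trial index. For the binomial-logit
family the marginal likelihood is approximated by a Laplace expansion
around the joint (β, u, v) mode, found by damped Newton iterations on
the penalized log-likelihood; the two log-SDs are profiled by
Nelder–Mead (deterministic start log 0.5, box [−8, 3] with a quadratic
pull outside the box and one restart from the clipped solution so
boundary fits terminate cleanly). β is estimated at the joint penalized
mode (the conditional-mode convention); this differs from software that
re-optimizes β against the full Laplace objective by a few percent
attenuation on strong effects, which the recovery experiments quantify —
coverage of the 95 % Wald CI at the study design size is the acceptance
standard. For the Gaussian family the same decomposition is exact ML
with the residual variance profiled in closed form; it agrees with
lme4's `lmer(..., REML=FALSE)` to ~1e-4 in the cross-check test.
Fixed-effect covariance is the top-left block of the inverse joint
Hessian. Fits report convergence and singularity (a variance at the
boundary) honestly; contrasts refuse to run on non-converged fits.

**R².** Marginal R² = σ²_f / (σ²_f + Σσ²_random + σ²_resid) with σ²_f
the variance of the fixed-effect predictor over the data and σ²_resid =
π²/3 for binomial-logit (the fitted residual variance for Gaussian);
conditional R² adds the random-intercept variances to the numerator.

**Contrasts.** Marginalized cell means are inverse-link fixed-effect
predictions with random effects at zero and covariates at their means;
pairwise contrasts are odds ratios (binomial) or mean differences
(Gaussian) with Wald z/p and percentile [2.5 %, 97.5 %] intervals over a
nonparametric cluster bootstrap that resamples participants with
replacement (resampled clusters get fresh ids so the random-effect
grouping stays honest; k = 1000 by default, seed-controlled).

**Condition screen.** Each task-condition factor (cueing, stimulus,
target side) is added alone to the base model and tested by a
likelihood-ratio χ²; single-level factors are skipped with a log line.

**Cascade models.** OLS on standardized change scores (later minus
baseline), optionally covariate-adjusted (e.g. controlling the baseline
level); reported as standardized β with 95 % CI, t, p and R².

**Dropout ANOVA and power.** Two-way Type-II ANOVA
(group × retention) with interaction via statsmodels, η² per term, and
empty cells rejected by name. Analytic power converts η² to
f² = η²/(1−η²) with noncentrality λ = f²·N. The default reference
distribution is the large-sample noncentral χ² (`method="chi2"`), the
convention under which the 2×2 design with η² = 0.12 and N = 60 has
power 0.816 ≈ 0.82; the exact noncentral-F with df2 = N − cells
(`method="ncf"`, 0.803 for the same design) is available. At these
sample sizes the two conventions differ by about one percentage point;
the default follows the large-sample convention common in applied
power reporting for this design.

## Causal mediation

Quasi-Bayesian Monte-Carlo mediation of a binary treatment: a linear
mediator model at participant level (mediator ~ treatment + baseline
mediator) and a logistic outcome model on per-trial rows (outcome ~
treatment + mediator + baseline mediator). k draws (default 1000) of
both coefficient vectors from their asymptotic normal distributions —
plus a scaled-inverse-χ² draw of the mediator residual variance and
fresh mediator errors per unit — propagate estimation uncertainty into
potential outcomes Y(t, M(t′)) averaged over the sample. ACME and ADE
are averaged over both treatment arms, so ACME + ADE equals the total
effect *exactly in every draw*; effects are on the probability scale.
Point estimates are means over draws, intervals percentile
[2.5 %, 97.5 %], p two-sided tail proportions; the proportion mediated
is ACME/total (point) with a percentile interval over per-draw ratios.
Controlling for the baseline mediator makes the design a moderated
mediation: the mediated path reflects mediator *change*. Signs of
separation in the outcome model flag the result unreliable. On a
linear-Gaussian toy the estimator recovers the closed form
ACME = a·b, which the acceptance script recomputes.

## Validation problem sizes

The validation experiments use: 50 zero-noise trials for the exact
round trip; 200 trials at 0.3° noise (plus 3 × 20 trials for the
threshold-vs-noise curve); 100 simulated cohorts of 60 participants ×
16 trials for GLMM recovery (group log-odds 0.9, participant SD 1.0);
n = 2000 units and k = 1000 draws for the mediation toy; and 1000
random fixation configurations for the scorer/oracle equivalence.
These sizes make the whole validation run in well under a minute while
keeping Monte-Carlo error far from every decision boundary.

## Known limitations

- No smooth-pursuit or microsaccade classification; head movement and
  calibration error are out of scope.
- The literal 1 °/s fixation-stability bound is only usable on
  near-noiseless data; realistic analyses should use the dispersion
  mode (both are exposed and logged).
- Binomial fixed effects carry the mild attenuation of joint-mode
  profiling relative to full-Laplace ML; variance components and
  Gaussian fits are convention-free.
- The cluster bootstrap refits the mixed model k times; contrast
  intervals at k = 1000 are compute-heavy on large cohorts.
- Real-data effect estimates from any particular cohort are not
  reproducible here without that cohort's data; all empirical claims in
  this package concern synthetic ground truth.
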