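# Methods

This note documents the models behind `ppaudit`, the defaults it ships,
the design decisions that were genuinely open, and what the simulations
do and do not establish about real data.

## The battery

Twelve tasks, four per auditory domain. Ten are adaptive forced-choice
tasks whose outcome is a discrimination threshold; the two pitch-sequence
tasks (p3 local change, p4 global/contour change) run 40 same/different
trials at a fixed difficulty (20 "same", 20 "different", each reference
sequence used once per condition) and score the number correct.

Stimulus parameters follow the published task descriptions where stated:
500 Hz, 100 ms pure tones for the rhythm tasks; 250 ms tones for the
pitch tasks; reference inter-onset intervals (IOI) drawn from 300–600 ms;
1000 ms stimuli for the modulation tasks with FM rates of 2 Hz (prosodic
time scale) and 40 Hz (phonemic time scale). Where the original stimulus
inventories are not public the package reconstructs them parametrically
and exposes the parameters:

- **Pitch difficulty** is expressed in semitones around a reference near
  500 Hz, for comparability with the relative (%) rhythm dimensions.
- **p3/p4 sequences** are random four-tone melodies with inter-tone steps
  of 1–3 semitones; "different" trials move the 3rd or 4th tone on the
  semitone grid so that the up/down contour is preserved (p3) or broken
  (p4). This guarantees the local/global distinction by construction and
  is verified property-style over thousands of generated trials.
- **Metrical sequences (r3/r4)** are seven onsets on a 16-unit grid (unit
  = half a beat): a strongly metrical pattern aligned to the 4-beat
  accent structure and a syncopated, weakly metrical variant. The
  distortion displaces one mid-sequence onset by a percentage of the
  beat.
- **Dynamic ripples (m3/m4)** sum 48 log-spaced carriers (250–4000 Hz)
  under a spectral envelope drifting at `ripple_rate` Hz with
  `ripple_density` cycles/octave; m4 varies density between intervals.

Waveform synthesis exists for inspection and WAV export; every analysis
operates on parametric trial descriptors, so rendering fidelity never
affects statistics.

## Virtual observers

Adaptive-task responses come from a logistic psychometric function in
log-difficulty, ψ(x) = γ + (1 − γ − λ)·F with
F = 1/(1 + exp(−β(ln x − ln α))): guess rate γ (0.5 for 2AFC, 1/3 for the
XAB/AXB tasks), lapse rate λ (default 0.02), threshold α in task units,
slope β (default 6 for adaptive tasks).

The fixed same/different tasks use a high-threshold detection variant:
the observer *detects* the change with probability max(0, 2F − 1) and
responds "different" exactly when it detects (lapses flip the response).
This choice makes the two boundary observers behave correctly — a
non-perceiving observer answers "same" throughout and scores 20/40 (the
guessing level of a balanced design), a perfect observer scores 40/40 —
which the plain forced-choice ψ cannot do (it would give a β = 0 guesser
75% correct). Slope default for these tasks is 3, putting control scores
mid-range (~30/40) rather than at ceiling.

## Adaptive engine

Two-down one-up staircase with multiplicative steps: factor 2 until the
second reversal, √2 afterwards; levels clipped to per-task floors and
ceilings. The threshold estimate is the geometric mean of the last six
reversal levels; tracks with fewer than six reversals are flagged
unconverged, their outcome propagates as missing and they are excluded
from group statistics. This estimator targets the level where
ψ = √0.5 ≈ 70.7% correct (Levitt's convergence point); simulation puts
the geometric-mean estimate within ~10% of the closed-form target at 50
trials (the residual bias comes from the coarse early steps and the
easy starting level).

The practice phase mirrors the clinical protocol: a fixed, identical
starting level, repetition until five consecutive correct responses, with
the level eased (doubled) after errors so that poor performers enter the
test at an individually easier level; the test then starts at the level
where practice ended.

One root seed drives everything through named substreams
(`SeedSequence(seed, spawn_key=...)`), so cohorts, tracks and analyses
are exactly reproducible and independent of execution order.

## Single-case statistics

The modified t-test treats the control mean and SD as estimates from a
small sample; its type-I error at α = 0.05 with n = 28 controls is the
nominal 5% (checked by 10⁴-simulation calibration — this is the property
that distinguishes it from a naive z-score). One-tailed p-values in the
task's deficit direction (thresholds: higher worse; p3/p4 scores: lower
worse — a registry the analyses share) are mapped to Z = Φ⁻¹(1 − p), and
the battery-wide criterion is Z > 2.64 (one-tailed 0.05, Bonferroni over
12 tasks, kept at 12 even when a patient misses tasks).

Covariate adjustment follows the regression-norms construction: fit
controls' outcome on covariates, compare the patient with their predicted
value scaled by the prediction SE at their covariate position (leverage
h\*), df = n − k − 1. Covariates are screened in controls only: age and
fluid intelligence (CPM) are candidates, and any candidate significant
(two-tailed p < 0.05) for at least one task is used for all twelve. The
frequentist form is implemented; Bayesian variants are out of scope.

## Group-level policy

Every task outcome is Lilliefors-tested in controls and in patients
(α = 0.05); a task deviating in either group is log-transformed for both.
Two consequences worth knowing:

- Each genuinely normal task false-positives at 1 − 0.95² ≈ 9.75% (two
  screens), so across seven normal tasks a perfectly clean selection
  happens in less than half of cohorts even with ideal power. Exact-set
  recovery of the five log-normal tasks is therefore not a stable event;
  per-task recovery is (each log task is flagged in a large majority of
  simulated cohorts, detection ≥ 85%).
- Implanted subtype deficits make the pooled patient sample a *mixture*,
  which is itself non-normal when shifts are large; patient-side
  flags on deficit tasks are expected behaviour, not a defect. (The
  discrete binomial scores of p3/p4 inflate patient-side rejection
  further.)

Group comparisons are pooled-variance one-sided t-tests (patients worse),
Bonferroni-corrected by 12; a Welch option exists
(`group_compare(..., equal_var=False)`). Subtype comparisons use
tie-corrected Kruskal–Wallis at uncorrected p < 0.05 — matching the
original analysis convention — followed by Tukey–Kramer contrasts on rank
means with the studentized-range criterion and unequal-n correction.
Correlation families (symptom duration, hearing level: Pearson; digit
span: Spearman; factor scores: Pearson, one-tailed) are Bonferroni
corrected within each family (×12, or ×12·k for k factors).

`headline_findings()` collects the cohort-level Bonferroni-corrected
claims — the group patient-vs-control deficits. Subtype KW tests and the
SVM permutation p are uncorrected by convention, and single-case flags
form per-patient families, so none of those enter the corrected headline
set; this is what makes the end-to-end null control meaningful (~95% of
no-deficit cohorts produce no headline finding).

## Classifier

`PairwiseSubtypeSVM` fits a linear SVM at C = 10⁶ (hard margin on
separable data; a warning is raised if training data are not separable at
that C). Accuracy is leave-one-out with fold-wise z-scoring; significance
is a label-permutation test with add-one smoothing,
p = (1 + #{perm ≥ obs})/(1 + n_perm). Reported weights come from the
full-sample fit on standardized features. A caution the simulations make
explicit: with ~10 cases and several correlated deficit features, the
max-margin weight *ordering* is unstable run-to-run even when the mean
ordering is clear — single-study weight rankings should be read
accordingly.

## Factor model

Principal-component extraction on the correlation matrix (eigenvalues of
which sum to the number of variables; variance explained per factor is
100·λ/p), eigenvalue > 1 retention, varimax rotation (communalities
preserved to 1e−8), regression-method factor scores (zero mean over the
fitting sample). The model is fitted on controls and patients together
and patient scores are read off afterwards. Extraction, rotation and
retention are all constructor options; whether published solutions of
this kind are rotated is usually unstated — near-simple structure
suggests rotation, which is the default here.

## Synthetic cohorts

Defaults encode the study conditions: 28 controls, 8 SV / 6 NFV / 4 LV.
Per-task control ability models: log-normal for {p1, r1, r2, m2, m3}
(log-SD 0.70–0.85, a realistic half-decade threshold spread which is
also what gives the pre-log normality screen its power), truncated-normal
for the other thresholds (mean/SD ratios ≈ 4), and log-normal underlying
thresholds for p3/p4 from which scores are drawn binomially through the
fixed-task observer model (controls ≈ 30/40, spanning > 10 distinct
values so score discreteness stays modest).

Structure implanted beyond the margins:

- **CPM–p2 coupling.** CPM loads 0.80 on the repetition latent f₂; the
  p2 threshold takes a −0.45/0.80 share of f₂, giving a population
  control-side CPM–p2 correlation of −0.45 (better fluid intelligence,
  lower threshold). Recovered sample correlations average ≈ −0.42 after
  integer rounding/clipping of CPM.
- **Neuropsychology.** Fourteen variables from two orthogonal latents
  (semantic/naming and repetition) with a 10 + 4 block loading structure
  (0.72–0.88 dominant loadings, two sentence-comprehension variables
  deliberately mixed), unit residual variance. SV shifts the semantic
  latent (−2.5 SD), NFV the repetition latent (−2.0), LV mildly (−1.0);
  digit span derives from f₂.
- **Deficit profiles** (control-SD units, positive = worse): NFV
  {p3 3.0, r4 2.6, p4 1.0, r2 1.2, r3 1.2, m4 1.2}; SV {r3 1.3}; LV none.
  The magnitudes encode the reported qualitative ordering — sequence
  tasks (p3, r4) about twice the secondary tasks *in measured-outcome
  units*; p3's measured contrast is capped near 2 SD by the same/
  different guessing floor, which is why its implanted shift is larger.
  The repetition latent additionally couples into p3/p4 (coefficient
  0.3), so patient factor-2 scores correlate with sequence performance.
- **Age** is generated but carries no true effect (matching the reported
  absence of an age correlation), so covariate screening should usually
  select CPM and not age.

`generate_cohort` returns the outcome table plus a ground-truth record
(true thresholds, latents); `generate_trial_level` replaces outcomes with
staircase/fixed-run measurements. The analysis stages never read the
truth record.

What the generator does **not** emulate: floor/ceiling effects of real
clinical scales, non-stationary attention or fatigue across a session,
hearing-threshold interactions with stimulus audibility, correlated
residuals between tasks beyond the latent couplings, and dropout/aborted
tasks. Passing pipeline tests therefore demonstrates statistical
correctness and internal consistency of the methodology, not clinical
validity on real cohorts.

## Problem sizes and numerical choices

Simulation-based checks use sizes chosen to keep the full suite
comfortably reproducible on a single CPU: 200 staircases for the
convergence check, 10⁴ draws for single-case calibration, 100 cohorts for
transform-policy recovery, 100 pipeline runs for the null control (50
SVM permutations each), 20 for deficit-pattern recovery (100
permutations each); the worked example uses 1000 permutations. Degenerate
inputs fail loudly: constant samples (normality test, correlations),
all-tied ranks, rank-deficient or singular designs, non-positive values
scheduled for log transform, singleton classifier classes. p-values are
clipped away from {0, 1} only at the float boundary (1e−300) before the
Z transform.

## Known limitations

- Staircase step sizes, floors/ceilings and the six-reversal threshold
  rule are reconstructions of common practice, configurable but not
  validated against the original tool chain.
- The fixed-task observer is a high-threshold model; criterion-setting
  (bias) and sensory-noise (SDT) accounts would give different
  same/different score distributions near the floor.
- The covariate-adjusted single-case test assumes control residual
  normality; no small-sample correction beyond the t reference is
  applied.
- Tukey–Kramer on rank means approximates the rank-variance with the
  large-sample N(N+1)/12 form; with 18 patients in three small groups
  the contrast is approximate, as is standard for this post hoc.
- With four LV cases, any statement about LV sparing has very low power;
  the simulations reproduce this honestly (LV shows spurious corrected
  flags in roughly a third of runs at these sample sizes).
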