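# Methods

`dmnstab` re-implements, as a testable pipeline on synthetic data, an
analysis that asks whether *stability* of default-mode-network (DMN)
activation — the autoregressive self-prediction of each region's
time series — predicts trial-level feedback learning on the Balloon
Analogue Risk Task (BART) over and above mean *deactivation* of the same
regions. This note describes each model, the choices made where the
design was genuinely open, and what the synthetic studies do and do not
establish about real data.

## Task and trial-level learning model

Each subject plays 24 balloons. Every pump earns a point but risks an
explosion; balloons pop after 4–10 pumps, with the explosion points in
one fixed pseudo-random order shared by all subjects (the published
order is not available; ours is generated once from a dedicated seed).
Events are separated by uniform 0.5–4.0 s jitter and the task is
self-paced.

Feedback learning is modeled at the trial level:

    pumps_ij = γ0 + γ1·trial_ij + γ2·outcome_ij + γ3·prevValence_ij
               + γ4·prevValue_ij + u0j + u3j·prevValence_ij
               + u4j·prevValue_ij + ε_ij

with `u0j ~ N(0, τ00)`, `u3j ~ N(0, τ33)`, `u4j ~ N(0, τ44)`,
`ε ~ N(0, σ²)`. Coding rules:

* current outcome: cash-out = 0, explosion = 1;
* previous valence: cash-out = 1, explosion = 0. The source analysis
  plan prints an internally inconsistent coding (both levels zero); we
  chose the orientation under which a positive γ3 reads "more pumps
  after positive feedback", which is the construct the index measures;
* previous value: 1 iff the previous balloon's final pumps strictly
  exceed the subject's own 75th percentile of pumps over all 24 trials
  (ties are low-value);
* the first balloon has no previous outcome and emits no design row.

Estimation is REML (ML by flag) with a diagonal random-effects
covariance — 24 trials per subject cannot identify an unstructured 3×3.
The three relative variance components are optimized by bounded
quasi-Newton with the scale and the fixed effects profiled out
analytically; convergence is declared at a relative objective change
below 1e-12 or 500 iterations. Per-subject empirical-Bayes (EB) slopes
are the closed-form BLUPs at the estimated components.

Two numerical choices deserve emphasis:

* **Variance floor.** Relative variance components are floored at 1e-8
  instead of exactly 0. At the floor the fit is numerically identical to
  the boundary (and is flagged as a boundary estimate), but the EB
  slopes retain each subject's ranking information instead of collapsing
  to a single constant. The downstream regression t-tests are invariant
  to the outcome's scale, so this choice only prevents a degenerate
  constant outcome; it does not move any estimate. Without it, boundary
  estimates — common when the true slope variance is small — produced a
  constant learning index and numerically meaningless regression
  p-values.
* **Degenerate outcome guard.** If a learning index is still numerically
  constant, the regression stage reports zero coefficients with p = 1
  and a `degenerate_outcome` flag rather than dividing by a zero
  residual variance.

**Shrinkage caveat.** With three jointly estimated random effects whose
design columns are correlated, the BLUP is a *multivariate* contraction:
the exact scalar theorem u_i = k·(conditional unpooled estimate) with
k ∈ (0, 1) holds componentwise (and is verified in the tests), but the
popular statement "each EB slope lies between the subject's own OLS
slope and the fixed effect" is not a theorem and fails for roughly 4% of
subjects in study-scale simulations. The package treats the latter as a
diagnostic, not an invariant.

## Synthetic behavior generator

Each trial draws a latent intended pump count from the linear predictor
(subject deviations included) plus Gaussian noise, rounded and floored
at one. The balloon pops at its explosion point, so observed pumps are
`min(intended, explosion point)` and the outcome is an explosion exactly
when the intent reaches that point. Two consequences:

* the current-outcome coefficient γ2 cannot act generatively (the
  outcome is mechanically determined); `simulate_learning_rows` draws
  the design exogenously and the response directly from the trial-level
  equation, and is the generator used to validate the fitter, where all
  five fixed effects must be recoverable;
* explosion trials carry no slope information (their pumps equal the
  scheduled explosion point), so refits of BART-generated data estimate
  an attenuated valence slope — about γ3·(1 − explosion share). At the
  study defaults (γ0 = 5, explosion points 4–10, explosion rate ≈ 0.36)
  the large-simulation limit of the refitted γ3 is 1.167 for a planted
  1.5. Attenuation rescales slopes roughly uniformly and therefore
  preserves the between-subject ordering the downstream analysis needs.

The generative high-value threshold is the 75th percentile of the
subject's latent intended-pump distribution (γ0 + u0 + 0.674·σ); the
fitted design recomputes it from observed pumps, as the analysis
prescribes.

## Network model and estimation

The 10 DMN regions (mPFC, PCC, bilateral dSFG, TP, hippocampus, AG)
follow a unified SEM / structural VAR:

    η(t) = A η(t) + Φ η(t−1) + ζ(t),   ζ ~ N(0, diag)

A holds contemporaneous directed paths (zero diagonal); Φ holds lag-1
paths, and its diagonal — always estimated — is the per-ROI
autoregressive "stability" measure. Estimation maximizes the Gaussian
conditional likelihood over all (t−1, t) volume pairs in which both
volumes are observed; series are centered per ROI over observed volumes;
missing volumes (NaN) remove exactly the pairs that touch them.

When the contemporaneous graph is acyclic, `det(I − A) = 1` for every
parameter value, the likelihood separates by equation, and the exact ML
solution is per-equation OLS; the whole search then runs in closed form
from one 20×20 Gram matrix per subject. Cyclic structures couple the
equations through the `log|det(I − A)|` term and are fitted by
quasi-Newton ascent on the variance-profiled likelihood with an analytic
gradient, warm-started from the acyclic solution; a candidate is
rejected when it drives `cond(I − A)` above 1e8.

### Path search

Group stage: starting from the AR-only null model, every absent path
(contemporaneous and, by default, lagged cross-ROI) is scored per
subject with a one-path likelihood-ratio refit; the candidate
significant for the largest fraction of subjects is added while that
fraction is at least 70%; ties break on the larger mean |statistic|,
then lexicographic path order. Group paths are then re-tested and pruned
(weakest first) to a fixed point. Individual stage: greedy forward
addition and backward pruning per subject; group paths are never pruned
there.

P-values use the exact finite-sample F tail of the one-path test
(`F = (n−k)(e^{LR/n} − 1)` with k the unrestricted equation's regressor
count): for the acyclic route this is the exact added-regressor test
under Gaussian innovations, and it corrects the χ²(1) approximation's
anticonservative far tail at fMRI-scale series lengths — which matters
because the individual stage tests ~180 candidates at once. The
per-test level is α = 0.05 at the group stage (the 70%-of-subjects
criterion supplies family-wise control there); the individual stage
Bonferroni-corrects α over its candidate set, without which a null
subject accumulates about α·180 spurious paths.

## ROI GLM (deactivation)

Pump, cash-out, and explosion events are convolved with the canonical
double-gamma HRF (SPM default parameters: response delay 6, undershoot
16, ratio 6; unit-peak normalized) on a TR/16 microtime grid and sampled
at volume times; events are zero-duration sticks. A pump-number
parametric modulator (mean-centered within the pump condition, no
further orthogonalization) controls for balloon size. Discrete-cosine
drift regressors implement the 128 s high-pass with the conventional
order `floor(2·duration/cutoff) + 1`; the truncated basis absorbs slow
drifts well (beta shift < 3% for a 300 s sinusoid) but leaks near the
cutoff (up to ~10–15% for 150–200 s periods) — a known property of DCT
high-pass filtering. Eight nuisance columns (six motion parameters plus
white-matter and CSF signals) are appended when supplied; volumes with
frame displacement above 2 mm are censored, which is implemented — and
tested — as exact row deletion. The per-ROI OLS beta of the pump
condition is the deactivation estimate (negative = suppression below the
implicit jittered-baseline).

## Coupled studies and the planted association

`make_coupled_study` generates the full joint structure the analysis
tests for. Per subject: a mean AR coefficient is drawn as
`N(0.6, 0.12²)` (clipped to [0.05, 0.90]), with per-ROI scatter of SD
0.05; the true valence/value slope deviations are
`coupling_b · z(AR) + N(0, slope_noise_sd²)` where z(AR) standardizes
the AR deviation by its generative SD (so `coupling_b` is in pump units
per SD of stability; defaults 0.5 and 0.1); the deactivation amplitude
is `N(−0.5, 0.3²)`, drawn independently of the AR process so the two
feature sets are uncorrelated in truth. The group contemporaneous
template has three shared paths (mPFC→PCC, PCC→left AG, PCC→right AG,
each 0.3). Pump events carry an HRF-shaped response scaled by the
subject's amplitude and a fixed per-ROI weight profile, added onto the
uSEM series; outcome volumes are NaN-censored, so the network stage
analyzes decision-period volumes only. Scan length is drawn per subject
from the configured range (default 180–300 volumes at TR = 2 s — the
self-paced scan lengths are not published, so this range is a
configuration default, not a reported quantity) and extended if the
task ran longer.

## Dimension reduction and regressions

Each subject's 10 deactivation betas and 10 AR estimates are reduced to
one score each: the first principal component of the column covariance
matrix (varimax rotation of a single retained component is the identity
and is applied as such). The sign is fixed so the loading sum is
positive. Loadings are also reported rescaled to the correlation metric
(loading · √eigenvalue / column SD), which is the interpretation we
adopt for "rescaled" factor loadings; the original analysis does not
define its rescaling. Both learning indices are then regressed on the
two scores (OLS with intercept) in separate models, thresholded at
p = 0.025 to correct for the two outcomes; the stability × deactivation
interaction model and the Pearson correlation between the two scores are
computed as checks. Subjects failing any stage are excluded listwise
with a logged manifest.

## What the synthetic studies establish — and what they do not

The generator reproduces the study's design parameters (24 balloons,
explosion points 4–10 in a fixed order, 0.5–4 s jitter, TR = 2 s,
self-paced variable scan lengths, NaN-censored outcome volumes) and a
controllable stability→learning coupling with an independent
deactivation pathway. Passing tests therefore establish that every
estimator recovers its own generative truth at study scale, that the
search and the final regressions are calibrated under the null, and that
the planted association is detected with high power at n = 65. They do
not establish anything about real BOLD data: the generator has no
physiological noise, no motion beyond a censoring mask, no spatial
structure, linear HRF coupling, and Gaussian innovations; and the real
study's coefficients are not reproducible because its data are not
deposited.

## Problem sizes and determinism

All randomness flows from `numpy` Generators seeded per run; identical
seeds give byte-identical outputs (tested). The acceptance script sizes
its replications as: oracle equivalence at T = 500; recovery at
T = 2000; group-search rates over 10 replicates of 20 subjects at
T = 200; promotion rates over 3 replicates of 30 subjects; mixed-model
recovery at n = 100 subjects; GLM calibration over 100 null series;
end-to-end power over 25 and type-I over 300 full-pipeline replicates at
n = 65. The test suite uses the same or larger sizes (500 type-I
replicates).
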