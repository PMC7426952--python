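# Methods

`crossarea` analyzes simultaneously recorded spiking activity from two
cortical regions (canonically premotor "M2" and primary motor "M1" cortex of
a rat performing a cued reach-to-grasp task) and separates what the two
populations do *together* from what each does *on its own*. This note
documents the models and procedures, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Cross-area subspace

Spike counts are binned at 100 ms (half-open bins `[t, t+dt)`), aligned to
grasp onset in a −1…+1 s window, concatenated across trials and
mean-centered per unit. Canonical correlation analysis (CCA) between the two
region matrices X_A (T × n_A) and X_B (T × n_B) yields paired weight vectors
(a_j, b_j) maximizing corr(X_A a_j, X_B b_j) subject to unit variance and
mutual uncorrelatedness of projections within a region; the projections are
the *cross-area dynamics* and their correlations are the canonical
correlations ρ_1 ≥ … ≥ ρ_k, k = min(rank_A, rank_B).

The implementation is the classical SVD form (whiten each block through its
thin SVD, read the canonical structure off the SVD of the whitened
cross-product), which matches MATLAB's `canoncorr` conventions: training
projections have unit sample variance (n−1). Rank-deficient blocks are
projected onto their numerical rank with a warning. CCA leaves each CV's
sign arbitrary; we orient every CV so that its mean projection over
reach-initiation bins (−0.1…+0.3 s around reach start) is nonnegative, and
all sign-sensitive comparisons align signs first.

**Generalization.** Per-CV R² is the squared Pearson correlation of paired
held-out projections under tenfold cross-validation with random row
partitioning (trial structure deliberately ignored); folds are matched by CV
index. R² here is sign-invariant by construction.

**Significance (trial-shuffle null).** One region's trials are randomly
permuted before concatenation, preserving within-trial temporal structure
(hence coarse movement-locked modulation) while destroying moment-to-moment
inter-area correspondence; CCA is refit and the top CV's R² recorded
(10⁴ shuffles nominally; identity permutations are re-drawn). A CV is
significant when its R² exceeds the null's 95th percentile; a dataset with
no significant CV is flagged for exclusion. Implementation note: permuting
whole trials only permutes rows of the concatenation, so the shuffled top
correlation is the top singular value of Q_Aᵀ P Q_B with the whitened blocks
fixed — refitting from scratch is never needed, and the fast path is tested
to equal brute-force refits to 1e-10.

By default the statistic compared against this null is the *training* top-CV
R², the same quantity the null records. The comparison is then exchangeable
under the permutation and calibrated (≈5% of no-shared-signal sessions show
a false positive). Comparing the cross-validated R² against a training-fit
null (`observed="cv"`) is supported but conservative, since training R² is
optimistically biased; both numbers are always reported.

**Bin/lag sweep.** The fit is repeated for bin widths {100, 75, 50} ms and
inter-region lags −500…+500 ms (stepped by one bin, region B's window
shifted); the cross-validated top-CV R² per cell identifies the best
operating point. On synthetic sessions the argmax recovers a planted
inter-region lag to within one bin.

## Local dynamics and inter-area timing

The cross-area subspace (CS) of a region is the span of its significant CV
weight vectors (all significant CVs, per the exclusion rule above; the top
CV when none are flagged). For each bin the centered population vector is
decomposed into its orthogonal projection onto the CS (shared component)
and the residual (local component); magnitudes of the two are the shared
and local activity. The CS basis is orthonormalized (QR) first, so
shared² + local² = total² holds to machine precision — this identity is
asserted on every synthetic session in the test suite.

Per-trial timing of local activity is the magnitude-weighted median of bin
centers (smallest t whose cumulative magnitude reaches half the total) on
the −1…+1 s peri-grasp window; trajectories are z-scored per session and
clipped at zero before weighting (window and weighting are configurable).
The median-timing rule is our choice — robust and parameter-free — since
"median timing" admits several operationalizations.

The M2-leads-M1 hypothesis is tested by permutation: region labels are
swapped independently within each trial (negating that trial's timing
difference), 10⁵ permutations nominally, one-sided p with the +1 correction
(floor below 1e-5 at the nominal permutation count). The early-vs-late
coupling change reassigns timing differences to the two stages at random
(group sizes preserved), statistic = difference of means.

**Calibration caveat.** The sign-flip null is exact when per-trial
differences are exchangeable within trials and independent across trials
(verified: 5.4% rejections at nominal 5% on iid input). In the end-to-end
pipeline, session-level randomness that differs between regions — fitted-CS
estimation error, region-specific noise-floor shape from the particular
draw of baseline rates and loadings — shifts *all* of a session's timing
differences coherently, which the within-trial flip group does not null
out. In small, heterogeneous sessions this inflates the single-session
type-I rate to roughly 8–13%; with 30+ units per region the residual
asymmetry is small (≈4–6% measured). Group-level inference across animals
(hierarchical bootstrap) is the appropriate remedy on real data; single-
session timing p-values from small populations should be read with this
caveat.

## Behavioral coupling

**CA-modulation (d′).** For each trial the reach window is
[reach_start − 0.1 s, grasp_onset + 0.1 s] and the baseline window has equal
length ending 1 s before the reach window. After subtracting the baseline
median from both segments,

    d' = (mu_reach − mu_baseline) / ( (1/2) * sqrt(sigma_reach + sigma_baseline) )

with σ a sample standard deviation. The denominator is implemented exactly
in this form — summing standard deviations under the root — although it
differs from the textbook pooled form; as a consequence d′ scales as √c when
the signal is scaled by c, and the test suite asserts this behavior as a
faithfulness check. `dprime_variant="pooled"` provides the conventional
sqrt((σ_r² + σ_b²)/2) for sensitivity analysis. Records with both σ's zero
are flagged invalid rather than raising.

**Duration coupling.** log d′ is regressed on log reach-duration with the
learning stage as an additive covariate (and animal, when several are
present); only trials with positive d′ enter and the excluded count is
reported. Note that because the printed d′ denominator is itself
amplitude-dependent, a latent amplitude scaling ∝ duration^β does not map
onto a d′ log-log slope of exactly β; slope-recovery checks therefore plant
the power law on d′ directly.

**Reach-start detection.** Bins in the pre-reach window (−2…−0.1 s before
reach start, truncated at the door-open cue when the reaction time is under
2 s — the truncation is counted) are labeled 0 and bins in the initiation
window (−0.1…+0.3 s) are labeled 1. A logistic regression on the session's
z-scored CS signals (both regions' top CVs by default; any channel subset is
supported) yields per-bin initiation probabilities; performance is
summarized by the in-sample ROC/AUC (a cross-validated variant exists and is
off by default), the difference of median CS activity between the two
windows, and the per-trial mean probability difference between windows.
Perfect separation (where unpenalized maximum likelihood diverges) falls
back to an L2-penalized fit and is flagged.

## Population statistics

**Hierarchical bootstrap.** Two-level resampling — animals with
replacement, then each sampled animal's values with replacement — with a
pluggable statistic (difference of condition grand means by default).
One-sided p is the fraction of resamples on the non-hypothesized side,
floored at 1/n (two-sided: doubled smaller tail, floored at 2/n); at 10⁴
resamples the floors are 1e-4 and 2e-4 exactly.

**Shared-over-total variance.** A k = 3 factor analysis (EM; backed by
scikit-learn's `FactorAnalysis` with the exact LAPACK SVD path so the
log-likelihood is monotone) models counts as mean + U·factors + diagonal
private noise. Per-unit shared variance is diag(UUᵀ) and the contract-
bearing quantity is the rotation-invariant ratio shared/(shared+private);
private variances are floored at 1e-6 of the unit variance for EM
stability. Leave-one-out selection of k is out of scope; k is fixed at 3
and overridable.

## Synthetic sessions

The generator emulates the recording the pipeline assumes, with known
ground truth. Per unit u in region r, the rate is log-linear in the
latents:

    lambda_u(t) = baseline_u * exp( w_shared,u * a_trial * z(t) + w_local,u * l_r(t) )

* `z(t)`: Gaussian bump at reach start, width 0.5 s × (duration/0.25 s) —
  movement-locked shared activation whose width tracks the reach.
* `a_trial = a_stage × (duration/0.25)^β × lognormal jitter`, β = −0.25:
  short reaches carry larger shared amplitude, the planted duration
  coupling. Stage amplitudes: 0.5 (early), 3.0 (late/baseline).
* Local latents: Gaussian bumps (σ 0.2 s) with the M2 bump leading the M1
  bump by 100 ms, amplitude 2.5 with lognormal jitter and an independent
  **random sign per trial and region**, center-jittered per region
  (sd 0.1 s).
* Spikes: inhomogeneous Poisson on a 5 ms grid inside a ±~2 s peri-reach
  window, homogeneous baseline elsewhere; 1 ms dead time; rates clipped at
  200 Hz (warned).
* Behavior: log-normal reach durations with stage means 0.30 s (early) and
  0.20 s (late); shifted-exponential reaction times, mean 3.0 s early and
  0.89 s late; success rates 27%/58%. Early reaction times in the emulated
  task are reported much longer still (tens of seconds); we use a shorter
  heavy-tailed early distribution since the inter-trial dead time carries
  no analyzable signal.
* Baseline rates uniform 20–50 Hz per unit (multi-unit-inclusive motor
  cortex scale, mean ≈ the ~25 Hz reported for M1).

Two structural choices matter and were arrived at deliberately. First,
local loadings are orthogonalized against the shared loadings *in the
rate-weighted (Poisson noise) metric* and spread densely (equal magnitude,
random sign) over units, so the planted local axis carries no first-order
count-space projection onto the shared axis and no extreme per-unit
exponents. Second, the local bump takes a random sign each trial: an
event-locked local latent with a deterministic trial mean is itself
cross-region correlated (both regions bump at the reach), and CCA —
correctly — absorbs such a component into the shared subspace. Sign
randomization removes the local latents' trial mean and their
moment-to-moment cross-region correlation while leaving every
magnitude-based local analysis (timing, peak-to-trough) unchanged. Without
these two choices "shared-axis recovery" is ill-posed: the population-
optimal top CV genuinely mixes the planted axes.

What the generator does **not** emulate: biophysics (conductances,
refractoriness beyond the fixed dead time), correlated private noise,
behavioral kinematics, electrode drift, non-stationarity across a session,
and muscimol pharmacokinetics (the "perturbed" stage simply scales M2
latent drive by 0.05). Passing recovery tests on these synthetics therefore
demonstrates correctness of the estimators under the stated model, not
robustness to every property of real recordings.

A further caveat on log-link generators and CCA: because the count-space
response to a latent is base_u·(e^{w_u c} − 1) and CCA weights are
noise-metric weighted, the population-optimal weight vector only aligns
with the planted loading when per-unit exponents are modest and per-unit
SNR is low-to-moderate. The default amplitudes keep peak per-unit exponents
near 0.5 for this reason; at much larger amplitudes axis recovery degrades
through curvature even as detection gets easier.

## Numerical conventions

* Seconds everywhere inside the API; bin widths in milliseconds at the
  boundary. Half-open bins; spikes on the right window edge excluded.
* z-scores use the n−1 standard deviation; zero-variance units map to
  zeros, never NaN.
* All resampling (shuffles, permutations, bootstrap, cross-validation
  folds) is driven by explicit integer seeds; identical seeds give
  byte-identical results. Generator output is deterministic per
  (seed, stage).
* p-values from shuffles/permutations carry the +1 correction and can
  never be zero; bootstrap p-values are floored at 1/n (2/n two-sided).
* Trials missing required events, exceeding the recorded span, or with
  degenerate (all-zero) trajectories are dropped and counted, never
  imputed.

## Problem sizes in the shipped experiments

The test suite and the reproduction script run scaled-down versions of the
nominal resampling counts: 500 trial shuffles (nominal 10⁴), 10³–10⁴
permutations (nominal 10⁵), sessions of 12–40 units and 30–300 trials.
These sizes were chosen so the full suite completes in minutes while every
statistical conclusion (calibration bands, recovery tolerances) is stated
with the matching binomial/precision allowance.
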