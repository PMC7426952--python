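# crossarea

Shared versus local neural population dynamics for paired two-region spike
recordings.

When two cortical areas — say premotor (M2) and primary motor (M1) cortex
of a rat learning a reach-to-grasp task — are recorded simultaneously, part
of each population's activity is coordinated with the partner region and
part is specific to the region itself. `crossarea` separates the two and
quantifies, trial by trial, how each couples to behavior:

* **Cross-area dynamics** — canonical correlation analysis (CCA) between
  the binned population matrices finds paired weight vectors (a_j, b_j)
  maximizing corr(X_A a_j, X_B b_j); the projections are the shared
  signals, and their significance is assessed against a trial-shuffle null
  that preserves within-trial structure while breaking moment-to-moment
  inter-area correspondence.
* **Local dynamics** — the magnitude of each population vector's residual
  after orthogonal projection onto the significant-CV subspace; per-trial
  median timing of local activity and permutation tests for the
  M2-leads-M1 timing hypothesis.
* **Behavioral coupling** — a single-trial d′ modulation index of the
  cross-area signal (reach window vs an equal baseline window), its
  log-log regression on reach duration, and logistic-regression detection
  of reach initiation with ROC/AUC.
* **Population statistics** — hierarchical (animal → trial) bootstrap,
  circular-shuffle PETH modulation tests, normalized pairwise
  cross-correlations, and factor-analysis shared-over-total variance.
* **Synthetic sessions** — an inhomogeneous-Poisson generator with a
  planted shared latent, lagged local latents, and duration-coupled
  amplitudes, so every estimator can be validated against ground truth.

See `docs/methods.md` for the models, conventions and caveats.

## Worked example

```python
import numpy as np
import crossarea as ca

# a late-learning synthetic session: 20 units per region, 120 trials
cfg = ca.SyntheticConfig(n_units={"M2": 20, "M1": 20}, n_trials=120, seed=42)
session, truth = ca.generate_session(cfg, stage="late")

# CCA on the peri-grasp window + trial-shuffle significance
fit = ca.pipeline.fit_session(session, n_shuffles=500, seed=0)
print(f"canonical correlations (top 3): {np.round(fit.model.rho[:3], 3)}")
print(f"significant CVs: {fit.significance.n_significant} "
      f"(top-CV cross-validated R^2 = {fit.significance.crossval_r2[0]:.3f}, "
      f"null 95th pct = {fit.significance.null_threshold:.3f})")
print(f"planted-axis angle, M1: "
      f"{ca.planted_axis_angle(truth, fit.model, 'M1'):.1f} deg")

# local-activity timing: does M2 lead M1?
t_m2, t_m1 = ca.pipeline.session_timing_difference(session, fit)
res = ca.timing_permutation_test(t_m2, t_m1, n_perm=10_000, seed=0)
print(f"median timing difference (M2 - M1): {1000*res.statistic_s:.0f} ms, "
      f"p = {res.p_value:.4f}")

# single-trial reach modulation of the M1 cross-area signal
mods = ca.pipeline.session_modulation(session, fit.model, "M1")
print(f"mean M1 CA-modulation (d'): {mods['d_prime'].mean():.2f}")
```

Output:

```text
canonical correlations (top 3): [0.836 0.174 0.166]
significant CVs: 1 (top-CV cross-validated R^2 = 0.686, null 95th pct = 0.426)
planted-axis angle, M1: 14.1 deg
median timing difference (M2 - M1): -91 ms, p = 0.0001
mean M1 CA-modulation (d'): 5.29
```

Reading it: exactly one canonical variable rises above the trial-shuffle
null — the planted one-dimensional shared latent — and its fitted axis sits
14° from the planted loading vector. Local M2 activity precedes local M1
activity by ~91 ms (the generator plants a 100 ms lead), significant at the
permutation floor. The late-stage cross-area signal is strongly
reach-modulated (d′ ≈ 5), and on an early-learning session the same numbers
come out much weaker — the learning contrast the pipeline is built to
measure.

A thin CLI mirrors the common steps on TSV session directories:

```sh
crossarea simulate --stage late --seed 3 --out session_dir/
crossarea fit-cca session_dir/ --shuffles 500 --seed 0
crossarea local session_dir/ --perms 100000 --seed 0
crossarea modulation session_dir/ --seed 0
crossarea detect session_dir/ --channels m2,m1 --seed 0
```

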