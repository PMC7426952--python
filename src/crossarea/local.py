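"""Local (non-shared) population dynamics and inter-area timing tests.

The cross-area subspace (CS) of a region is the span of its significant CV
weight vectors.  For each time bin the centered population vector is split
into its projection onto the CS (shared component) and the residual in the
orthogonal complement (local component); the magnitudes of these two
vectors are the shared and local activity values.  With an orthonormalized
CS basis the split is an exact orthogonal decomposition, so
shared^2 + local^2 equals the squared norm of the population vector.

Timing of local activity within a trial is summarized by the
magnitude-weighted median of bin-center times (smallest t at which the
cumulative magnitude reaches half the total).  The M2-leads-M1 hypothesis
is tested by permutation: region labels are swapped independently within
trials, which negates that trial's timing difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("crossarea")


@dataclass
class LocalSignal:
    """Per-bin shared/local magnitudes of one region's population activity."""

    local_mag: np.ndarray     # (n_bins,)
    shared_mag: np.ndarray    # (n_bins,)
    total_mag: np.ndarray     # (n_bins,)
    region: str
    basis_dim: int


@dataclass
class TimingResult:
    m2_timing_s: np.ndarray       # per-trial median timing
    m1_timing_s: np.ndarray
    diff_s: np.ndarray            # M2 - M1 per trial
    p_value: float
    n_permutations: int
    statistic_s: float            # mean(M2 - M1)
    side: str
    n_excluded: int = 0


def local_projection(X: np.ndarray, weights: np.ndarray,
                     region: str = "") -> LocalSignal:
    """Split centered population vectors into shared and local components.

    ``X``: (n_bins, n_units) centered activity; ``weights``: (n_units, m)
    significant-CV weight matrix (m >= 1, m < n_units).  The weight columns
    are orthonormalized (QR) before projection, so the Pythagorean identity
    ``shared^2 + local^2 = total^2`` holds exactly up to round-off.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    W = np.atleast_2d(np.asarray(weights, dtype=float))
    if W.shape[0] == 1:
        W = W.T
    if W.shape[0] != X.shape[1]:
        raise ValueError("weight rows must match unit count")
    if W.shape[1] >= W.shape[0]:
        raise ValueError("shared span covers full unit space; no complement")
    Q, _ = np.linalg.qr(W)
    shared = X @ Q @ Q.T
    local = X - shared
    return LocalSignal(local_mag=np.linalg.norm(local, axis=1),
                       shared_mag=np.linalg.norm(shared, axis=1),
                       total_mag=np.linalg.norm(X, axis=1),
                       region=region, basis_dim=W.shape[1])


def trial_median_timing(magnitude: np.ndarray, time_s: np.ndarray) -> float:
    """Magnitude-weighted median time of a nonnegative trajectory.

    Returns the smallest bin-center time at which the cumulative magnitude
    reaches half the total.  Raises ``ValueError`` on an all-zero (or
    negative) trajectory so callers can exclude and count the trial.
    """
    w = np.asarray(magnitude, dtype=float)
    t = np.asarray(time_s, dtype=float)
    if w.shape != t.shape:
        raise ValueError("magnitude and time axes differ in length")
    if np.any(w < 0):
        raise ValueError("magnitudes must be nonnegative")
    total = w.sum()
    if total == 0:
        raise ValueError("all-zero trajectory has no median timing")
    idx = int(np.searchsorted(np.cumsum(w), total / 2.0))
    return float(t[idx])


def per_trial_timings(trajectories: list[np.ndarray],
                      time_s: np.ndarray,
                      zscore: bool = True) -> tuple[np.ndarray, int]:
    """Median timing per trial; trajectories are z-scored across the session
    (pooled bins) and clipped at 0 before weighting, then excluded (and
    counted) if degenerate."""
    mats = np.asarray(trajectories, dtype=float)
    if zscore:
        mu, sd = mats.mean(), mats.std(ddof=1)
        mats = (mats - mu) / sd if sd > 0 else mats - mu
    mats = np.clip(mats, 0.0, None)
    out, excluded = [], 0
    for row in mats:
        try:
            out.append(trial_median_timing(row, time_s))
        except ValueError:
            excluded += 1
            out.append(np.nan)
    return np.asarray(out), excluded


def timing_permutation_test(m2_timing_s: np.ndarray,
                            m1_timing_s: np.ndarray,
                            n_perm: int = 100_000, seed: int = 0,
                            side: str = "less") -> TimingResult:
    """Permutation test of mean(M2 - M1) median-timing difference.

    The null swaps region labels independently within each trial (negating
    that trial's difference).  ``side="less"`` tests the M2-leads
    hypothesis (negative mean difference); p-values carry the +1 correction.
    Trials with a missing timing in either region are excluded and counted.
    """
    m2 = np.asarray(m2_timing_s, dtype=float)
    m1 = np.asarray(m1_timing_s, dtype=float)
    if m2.shape != m1.shape:
        raise ValueError("unequal trial counts")
    ok = np.isfinite(m2) & np.isfinite(m1)
    n_excluded = int((~ok).sum())
    d = (m2 - m1)[ok]
    if len(d) < 2:
        raise ValueError("need at least 2 complete trial pairs")
    obs = float(d.mean())
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, len(d)))
    null = (signs * d).mean(axis=1)
    if side == "less":
        exceed = int(np.sum(null <= obs))
    elif side == "greater":
        exceed = int(np.sum(null >= obs))
    else:
        raise ValueError("side must be 'less' or 'greater'")
    p = (1 + exceed) / (1 + n_perm)
    return TimingResult(m2_timing_s=m2, m1_timing_s=m1, diff_s=d,
                        p_value=float(p), n_permutations=n_perm,
                        statistic_s=obs, side=side, n_excluded=n_excluded)


def coupling_change_test(early_diffs_s: np.ndarray,
                         late_diffs_s: np.ndarray,
                         n_perm: int = 100_000, seed: int = 0,
                         side: str = "greater") -> float:
    """Permutation test for a change in M2-M1 temporal coupling with
    learning.

    Statistic: mean(late) - mean(early) timing difference.  The null
    reassigns differences at random to the two stages (group sizes kept).
    With M2 leading (negative differences), tighter late coupling moves the
    statistic positive, hence the default ``side="greater"``; the side is
    configurable.
    """
    early = np.asarray(early_diffs_s, dtype=float)
    late = np.asarray(late_diffs_s, dtype=float)
    early, late = early[np.isfinite(early)], late[np.isfinite(late)]
    if len(early) == 0 or len(late) == 0:
        raise ValueError("both stages need at least one difference")
    obs = late.mean() - early.mean()
    pooled = np.concatenate([early, late])
    n_e = len(early)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(pooled)
        null[i] = perm[n_e:].mean() - perm[:n_e].mean()
    if side == "greater":
        exceed = int(np.sum(null >= obs))
    elif side == "less":
        exceed = int(np.sum(null <= obs))
    else:
        raise ValueError("side must be 'less' or 'greater'")
    return float((1 + exceed) / (1 + n_perm))
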