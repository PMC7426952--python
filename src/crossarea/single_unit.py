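"""Single-unit metrics: PETHs, circular-shuffle modulation tests, and
pairwise normalized cross-correlations.

The modulation test asks whether a unit's trial-averaged peri-event time
histogram deviates from a flat profile more than expected from its own
within-trial statistics: each shuffle circularly rotates every trial's bin
vector by an independent uniform offset, which preserves per-trial count
distributions and autocorrelation up to wraparound while destroying event
locking.  The test statistic is the peak absolute deviation of the PETH
from its mean (a standard choice; pluggable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

DEFAULT_ALPHA = 0.000125   # per-neuron significance level used throughout


@dataclass
class PethResult:
    peth: np.ndarray          # spikes/bin, trial-averaged
    time_s: np.ndarray
    peak_time_s: float
    p_value: float
    significant: bool
    alpha: float = DEFAULT_ALPHA


@dataclass
class PairXcorr:
    unit_a: int
    unit_b: int
    value: float              # peak r minus mean r over the lag range
    peak_lag_ms: float


def compute_peth(trial_counts: np.ndarray) -> np.ndarray:
    """Trial-averaged PETH from a (n_trials, n_bins) count array.

    Units are spikes/bin; divide by the bin width for a rate.
    """
    trial_counts = np.atleast_2d(np.asarray(trial_counts, dtype=float))
    if trial_counts.shape[0] < 1:
        raise ValueError("need at least one trial")
    return trial_counts.mean(axis=0)


def _peak_deviation(trial_counts: np.ndarray) -> float:
    peth = trial_counts.mean(axis=0)
    return float(np.max(np.abs(peth - peth.mean())))


def circular_shuffle_test(trial_counts: np.ndarray,
                          n_shuffles: int = 10_000,
                          alpha: float = DEFAULT_ALPHA,
                          seed: int = 0,
                          statistic: Callable[[np.ndarray], float] | None = None,
                          ) -> tuple[float, bool]:
    """Circular-shuffle test for event-locked modulation of one unit.

    ``trial_counts``: (n_trials, n_bins) binned counts aligned to the event.
    Returns ``(p, significant)`` with the +1-corrected p-value
    ``(1 + #{S_null >= S_obs}) / (1 + n_shuffles)`` (never exactly 0).  A
    constant-zero unit returns p = 1.
    """
    trial_counts = np.atleast_2d(np.asarray(trial_counts, dtype=float))
    n_trials, n_bins = trial_counts.shape
    if n_bins < 2:
        raise ValueError("need at least 2 bins per trial")
    stat = statistic or _peak_deviation
    s_obs = stat(trial_counts)
    if not np.any(trial_counts):
        return 1.0, False
    rng = np.random.default_rng(seed)
    col = np.arange(n_bins)
    exceed = 0
    for _ in range(n_shuffles):
        shifts = rng.integers(0, n_bins, size=n_trials)
        rolled = trial_counts[np.arange(n_trials)[:, None],
                              (col[None, :] - shifts[:, None]) % n_bins]
        if stat(rolled) >= s_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_shuffles)
    return float(p), bool(p < alpha)


def peth_with_significance(trial_counts: np.ndarray, time_s: np.ndarray,
                           n_shuffles: int = 10_000,
                           alpha: float = DEFAULT_ALPHA,
                           seed: int = 0) -> PethResult:
    """Convenience wrapper combining the PETH and its modulation test."""
    peth = compute_peth(trial_counts)
    p, sig = circular_shuffle_test(trial_counts, n_shuffles=n_shuffles,
                                   alpha=alpha, seed=seed)
    return PethResult(peth=peth, time_s=np.asarray(time_s),
                      peak_time_s=float(time_s[int(np.argmax(peth))]),
                      p_value=p, significant=sig, alpha=alpha)


def normalized_xcorr(counts_a: np.ndarray, counts_b: np.ndarray,
                     binwidth_ms: float, max_lag_ms: float = 200.0,
                     unit_a: int = 0, unit_b: int = 0) -> PairXcorr:
    """Normalized cross-correlation of two binned count series.

    The value is the peak Pearson correlation over lags in
    [-max_lag, +max_lag] (stepped by one bin) minus the mean correlation
    over all lags in that range; positive lag means B follows A.  Series
    are mean-subtracted by the Pearson formula itself; zero-variance
    overlap segments contribute r = 0.
    """
    a = np.asarray(counts_a, dtype=float).ravel()
    b = np.asarray(counts_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    max_shift = int(round(max_lag_ms / binwidth_ms))
    if max_shift < 1 or len(a) <= max_shift:
        raise ValueError("series too short for the requested lag range")
    rs = []
    lags = np.arange(-max_shift, max_shift + 1)
    for s in lags:
        if s >= 0:
            x, y = a[:len(a) - s], b[s:]
        else:
            x, y = a[-s:], b[:len(b) + s]
        if x.std() == 0 or y.std() == 0:
            rs.append(0.0)
        else:
            rs.append(float(np.corrcoef(x, y)[0, 1]))
    rs = np.asarray(rs)
    peak = int(np.argmax(rs))
    return PairXcorr(unit_a=unit_a, unit_b=unit_b,
                     value=float(rs[peak] - rs.mean()),
                     peak_lag_ms=float(lags[peak] * binwidth_ms))


def xcorr_vs_weight_regression(xcorr_values: Sequence[float],
                               mean_weight_mags: Sequence[float],
                               ) -> tuple[float, float, float, float]:
    """OLS of pairwise cross-correlation on mean |CCA weight| of the pair.

    Returns (slope, R^2, t, p) with a two-sided t-test on the slope.
    """
    from .stats import group_summary_regression
    import pandas as pd

    y = np.asarray(xcorr_values, dtype=float)
    x = np.asarray(mean_weight_mags, dtype=float)
    if len(y) < 3 or len(x) != len(y):
        raise ValueError("need at least 3 paired observations")
    res = group_summary_regression(
        pd.DataFrame({"y": y, "x": x}), "y", ["x"])
    return (res.params["x"], res.rsquared, res.tvalues["x"],
            res.pvalues["x"])
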