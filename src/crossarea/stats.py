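"""Population-level inference: hierarchical bootstrap, factor-analysis
shared variance, and a shared OLS utility.

The hierarchical bootstrap resamples animals with replacement and then
values within each sampled animal, respecting the nesting of trials within
subjects.  With n resamples the smallest attainable one-sided p is 1/n
(2/n two-sided), matching the floor conventions used when reporting
"p < 0.0001" at 10^4 resamples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from sklearn.decomposition import FactorAnalysis

logger = logging.getLogger("crossarea")


# ---------------------------------------------------------------------------
# hierarchical bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    mean: float
    sd: float
    p_value: float
    n_resamples: int
    sided: str
    grouping: str
    resamples: np.ndarray


def _resample_group(rng: np.random.Generator,
                    groups: Mapping[str, np.ndarray]) -> float:
    animals = list(groups)
    picked = rng.choice(len(animals), size=len(animals), replace=True)
    vals = [groups[animals[i]][rng.integers(0, len(groups[animals[i]]),
                                            len(groups[animals[i]]))]
            for i in picked]
    return float(np.mean([v.mean() for v in vals]))


def hierarchical_bootstrap(values: Mapping[str, Sequence[float]],
                           values_b: Mapping[str, Sequence[float]] | None = None,
                           statistic: Callable[..., float] | None = None,
                           n: int = 10_000, sided: str = "one",
                           side: str = "greater",
                           seed: int = 0) -> BootstrapResult:
    """Two-level (animal -> trial) bootstrap inference.

    ``values`` maps animal id -> per-trial values for one condition; with
    ``values_b`` given, the default statistic is the difference of grand
    means (condition A - condition B), otherwise the grand mean itself.
    Each resample draws animals with replacement and then trials within
    each sampled animal with replacement.

    ``side="greater"`` tests statistic > 0: the one-sided p is the fraction
    of resamples on the non-hypothesized side (<= 0), floored at 1/n;
    two-sided doubles the smaller tail and floors at 2/n.
    """
    groups_a = {k: np.asarray(v, dtype=float) for k, v in values.items()}
    if not groups_a or any(len(v) == 0 for v in groups_a.values()):
        raise ValueError("every animal needs at least one value")
    groups_b = None
    if values_b is not None:
        groups_b = {k: np.asarray(v, dtype=float) for k, v in values_b.items()}
        if not groups_b or any(len(v) == 0 for v in groups_b.values()):
            raise ValueError("every animal needs at least one value")

    rng = np.random.default_rng(seed)
    stats = np.empty(n)
    for i in range(n):
        a = _resample_group(rng, groups_a)
        if groups_b is not None:
            b = _resample_group(rng, groups_b)
            stats[i] = statistic(a, b) if statistic else a - b
        else:
            stats[i] = statistic(a) if statistic else a

    if side == "greater":
        wrong = np.mean(stats <= 0)
    elif side == "less":
        wrong = np.mean(stats >= 0)
    else:
        raise ValueError("side must be 'greater' or 'less'")
    if sided == "one":
        p = max(float(wrong), 1.0 / n)
    elif sided == "two":
        tail = min(float(np.mean(stats <= 0)), float(np.mean(stats >= 0)))
        p = min(1.0, max(2.0 * tail, 2.0 / n))
    else:
        raise ValueError("sided must be 'one' or 'two'")
    grouping = "animal" if groups_b is None else "animal,condition"
    return BootstrapResult(mean=float(stats.mean()),
                           sd=float(stats.std(ddof=1)), p_value=p,
                           n_resamples=n, sided=sided, grouping=grouping,
                           resamples=stats)


# ---------------------------------------------------------------------------
# factor-analysis shared variance
# ---------------------------------------------------------------------------

@dataclass
class SharedVarianceResult:
    loading: np.ndarray          # U, (n_units, k)
    private_var: np.ndarray      # diag of Sigma_private
    shared_var: np.ndarray       # diag of U U^T
    ratio: np.ndarray            # shared / (shared + private), per unit
    mean: np.ndarray
    k: int
    loglike_path: np.ndarray     # per-EM-iteration log-likelihood
    converged: bool
    dropped_units: np.ndarray    # indices of zero-variance units removed


def fa_shared_variance(X: np.ndarray, k: int = 3, max_iter: int = 1000,
                       tol: float = 1e-3, seed: int = 0,
                       ) -> SharedVarianceResult:
    """Shared-over-total variance per unit from a k-factor model.

    Fits observed ~ mu + U f + eps (diagonal private noise) by EM; the
    shared covariance is U U^T and each unit's ratio is
    shared_ii / (shared_ii + private_ii).  Zero-variance units are dropped
    (their rows are NaN in the outputs) and reported; non-convergence
    within ``max_iter`` returns a result flagged ``converged=False``.
    Private variances are floored at 1e-6 times the unit variance.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more time bins than units")
    var = X.var(axis=0, ddof=1)
    keep = var > 1e-12 * max(1.0, float(var.max()))
    dropped = np.nonzero(~keep)[0]
    if dropped.size:
        logger.warning("fa_shared_variance: dropped %d zero-variance unit(s)",
                       dropped.size)
    Xk = X[:, keep]
    if k >= Xk.shape[1]:
        raise ValueError("k must be smaller than the number of active units")
    fa = FactorAnalysis(n_components=k, max_iter=max_iter, tol=tol,
                        svd_method="lapack", random_state=seed)
    fa.fit(Xk)
    U = fa.components_.T                       # (units, k)
    priv = np.maximum(fa.noise_variance_, 1e-6 * var[keep])
    shared = np.sum(U ** 2, axis=1)
    ratio = shared / (shared + priv)

    def expand(v: np.ndarray, width: int = 0) -> np.ndarray:
        if width:
            out = np.full((p, width), np.nan)
            out[keep] = v
        else:
            out = np.full(p, np.nan)
            out[keep] = v
        return out

    loglike = np.asarray(fa.loglike_)
    return SharedVarianceResult(
        loading=expand(U, k), private_var=expand(priv),
        shared_var=expand(shared), ratio=expand(ratio),
        mean=expand(fa.mean_), k=k, loglike_path=loglike,
        converged=fa.n_iter_ < max_iter, dropped_units=dropped)


# ---------------------------------------------------------------------------
# OLS utility
# ---------------------------------------------------------------------------

def group_summary_regression(df: pd.DataFrame, outcome: str,
                             covariates: Sequence[str]):
    """OLS with two-sided t-tests, shared by the pairwise-correlation and
    modulation-change regressions.

    ``covariates`` are patsy terms (e.g. ``["x", "C(stage)"]``).  A
    rank-deficient design raises ``ValueError`` naming the offending
    columns.
    """
    formula = f"{outcome} ~ " + " + ".join(covariates)
    model = smf.ols(formula, data=df)
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        # identify collinear columns by QR pivoting
        _, r = np.linalg.qr(model.exog)
        diag = np.abs(np.diag(r))
        bad = [model.exog_names[i] for i in np.nonzero(
            diag < 1e-10 * diag.max())[0]]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return model.fit()
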