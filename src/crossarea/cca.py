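"""Cross-area subspace identification with canonical correlation analysis.

CCA finds paired linear combinations of the two populations' activity
(canonical variables, CVs) whose time courses are maximally correlated.  The
implementation is the classical SVD form: each centered data block is
whitened through its thin SVD and the canonical structure is read off the
SVD of the cross-product of the whitened blocks, which matches the textbook
solution of the generalized eigenproblem and is numerically robust to
rank-deficient populations (zero-variance or collinear units are projected
out and the corresponding weights set to zero-pattern via the pseudoinverse
mapping).

Significance of CVs is assessed against a trial-shuffle null: one region's
trials are randomly permuted before concatenation, which preserves each
region's within-trial temporal structure (and hence coarse event-locked
modulation) while destroying moment-to-moment inter-area correspondence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg as sla

from .core import BinnedPopulation, concat_and_center

logger = logging.getLogger("crossarea")

_RCOND = 1e-10


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

@dataclass
class CCAModel:
    """Fitted canonical correlation model for a pair of regions.

    ``weights[region]`` is (n_units, k); projections of the *training* data
    onto CV j of the two regions have Pearson r equal to ``rho[j]``.
    ``orientation[j]`` records the sign flip applied to make the CV's mean
    projection over the orientation rows (e.g. reach-initiation bins)
    nonnegative.
    """

    regions: tuple[str, str]
    weights: Mapping[str, np.ndarray]
    rho: np.ndarray
    means: Mapping[str, np.ndarray]
    binwidth_ms: float = 100.0
    lag_ms: float = 0.0
    orientation: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def k(self) -> int:
        return len(self.rho)

    def project(self, X: np.ndarray, region: str,
                cv: int | None = None) -> np.ndarray:
        """Project data onto the region's CV weight(s), after centering with
        the stored training means."""
        if region not in self.weights:
            raise ValueError(f"unknown region {region!r}")
        W = self.weights[region]
        X = np.asarray(X, dtype=float)
        if X.shape[1] != W.shape[0]:
            raise ValueError("unit count does not match model")
        Z = (X - self.means[region]) @ W
        return Z if cv is None else Z[:, cv]


def _whiten(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Thin SVD whitening; returns (Q, back-map, rank) with Q orthonormal."""
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > _RCOND * s[0])) if s.size else 0
    U, s, Vt = U[:, :rank], s[:rank], Vt[:rank]
    back = Vt.T / s           # maps whitened coords to unit-space weights
    return U, back, rank


def fit_cca(X_a: np.ndarray, X_b: np.ndarray,
            regions: tuple[str, str] = ("M2", "M1"),
            binwidth_ms: float = 100.0, lag_ms: float = 0.0,
            orient_rows: np.ndarray | None = None) -> CCAModel:
    """Fit CCA between two time x unit matrices.

    Inputs are centered internally (the fitted column means are stored so
    held-out data can be projected consistently).  Rows must outnumber
    columns in each block.  Weights are scaled so training projections have
    unit variance (n-1 normalization), matching the convention of MATLAB's
    ``canoncorr``.

    ``orient_rows``: optional boolean mask of rows (e.g. reach-initiation
    bins); each CV is sign-flipped so region A's mean projection over those
    rows is >= 0.  Without a mask the largest-magnitude weight coefficient
    of region A is made positive.
    """
    X_a = np.asarray(X_a, dtype=float)
    X_b = np.asarray(X_b, dtype=float)
    if X_a.shape[0] != X_b.shape[0]:
        raise ValueError("row counts differ between regions")
    n = X_a.shape[0]
    if n <= X_a.shape[1] or n <= X_b.shape[1]:
        raise ValueError("need more rows than columns in each region")
    mean_a, mean_b = X_a.mean(axis=0), X_b.mean(axis=0)
    Xa, Xb = X_a - mean_a, X_b - mean_b

    Qa, back_a, ra = _whiten(Xa)
    Qb, back_b, rb = _whiten(Xb)
    if ra < Xa.shape[1] or rb < Xb.shape[1]:
        warnings.warn("rank-deficient input: dropped "
                      f"{Xa.shape[1] - ra + Xb.shape[1] - rb} dimension(s)",
                      RuntimeWarning)
    k = min(ra, rb)
    if k == 0:
        raise ValueError("zero-rank input")
    U, s, Vt = np.linalg.svd(Qa.T @ Qb)
    rho = np.clip(s[:k], 0.0, 1.0)
    scale = np.sqrt(n - 1)
    Wa = back_a @ U[:, :k] * scale
    Wb = back_b @ Vt.T[:, :k] * scale

    # sign orientation (CCA leaves per-CV sign arbitrary)
    Za = Xa @ Wa
    if orient_rows is not None:
        ref = Za[np.asarray(orient_rows, dtype=bool)].mean(axis=0)
    else:
        ref = np.array([Wa[np.argmax(np.abs(Wa[:, j])), j]
                        for j in range(k)])
    flips = np.where(ref < 0, -1.0, 1.0)
    Wa *= flips
    Wb *= flips

    return CCAModel(regions=regions,
                    weights={regions[0]: Wa, regions[1]: Wb},
                    rho=rho, means={regions[0]: mean_a, regions[1]: mean_b},
                    binwidth_ms=binwidth_ms, lag_ms=lag_ms,
                    orientation=flips)


def project(model: CCAModel, X: np.ndarray, region: str,
            cv: int = 0) -> np.ndarray:
    """Functional alias for :meth:`CCAModel.project` on a single CV."""
    return model.project(X, region, cv)


# ---------------------------------------------------------------------------
# cross-validated generalization
# ---------------------------------------------------------------------------

def _squared_pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def crossval_r2(X_a: np.ndarray, X_b: np.ndarray, folds: int = 10,
                seed: int = 0) -> np.ndarray:
    """Tenfold cross-validated R^2 (squared Pearson r of paired held-out
    projections) per CV, averaged over folds.

    Rows are partitioned at random, ignoring trial structure.  CVs are
    matched across folds by index (correlation-sorted within each fit).
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    n = X_a.shape[0]
    if n < folds:
        raise ValueError("fewer rows than folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_ids = np.array_split(order, folds)
    r2_per_fold = []
    for test_idx in fold_ids:
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        model = fit_cca(X_a[mask], X_b[mask])
        Za = model.project(X_a[test_idx], model.regions[0])
        Zb = model.project(X_b[test_idx], model.regions[1])
        r2_per_fold.append([_squared_pearson(Za[:, j], Zb[:, j])
                            for j in range(model.k)])
    k = min(len(r) for r in r2_per_fold)
    return np.array([[r[j] for j in range(k)] for r in r2_per_fold]).mean(axis=0)


# ---------------------------------------------------------------------------
# trial-shuffle significance
# ---------------------------------------------------------------------------

@dataclass
class CvSignificance:
    """Per-CV significance of the fitted model against a trial-shuffle null."""

    observed_r2: np.ndarray        # statistic compared to the null, per CV
    crossval_r2: np.ndarray        # tenfold cross-validated R^2, per CV
    null_percentile: float
    null_threshold: float
    null_r2: np.ndarray            # top-CV statistic per shuffle
    n_shuffles: int
    significant: np.ndarray        # bool per CV
    observed_kind: str = "train"

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())

    @property
    def exclude(self) -> bool:
        """Dataset exclusion rule: no significant CV at all."""
        return self.n_significant == 0


def _permute_non_identity(rng: np.random.Generator, n: int) -> np.ndarray:
    while True:
        p = rng.permutation(n)
        if n == 1 or np.any(p != np.arange(n)):
            return p


def trial_shuffle_significance(tensors_a: Sequence[BinnedPopulation],
                               tensors_b: Sequence[BinnedPopulation],
                               n_shuffles: int = 10_000,
                               percentile: float = 95.0,
                               seed: int = 0,
                               folds: int = 10,
                               observed: str = "train") -> CvSignificance:
    """Assess CV significance against a trial-shuffle null.

    Region A's trials stay in order; region B's trials are permuted
    (identity permutations re-drawn) before concatenation, centering and
    CCA refit; the null statistic is the top CV's training R^2 (= rho_1^2).
    Each true CV is flagged significant when its statistic exceeds the
    null's ``percentile``-th percentile.

    ``observed`` selects the statistic for the true model: ``"train"``
    (default) uses training-fit R^2, the same quantity the null records, so
    the comparison is exchangeable under the permutation and hence
    calibrated; ``"cv"`` uses the tenfold cross-validated R^2, a
    conservative variant.  Both are stored on the result.
    """
    if len(tensors_a) < 2:
        raise ValueError("need at least 2 trials to shuffle")
    if len(tensors_a) != len(tensors_b):
        raise ValueError("regions must have equal trial counts")
    rng = np.random.default_rng(seed)

    Xa, _, _ = concat_and_center(tensors_a)
    Xb, _, _ = concat_and_center(tensors_b)
    model = fit_cca(Xa, Xb)
    train_r2 = model.rho ** 2
    cv_r2 = crossval_r2(Xa, Xb, folds=folds,
                        seed=int(rng.integers(2 ** 31)))

    # Permuting whole trials only permutes rows of the concatenation, so
    # column means and the whitening of each block are unchanged; the
    # shuffled top canonical correlation is the top singular value of
    # Qa^T P Qb, which avoids refitting from scratch on every shuffle.
    n_trials = len(tensors_b)
    Qa, _, _ = _whiten(Xa)
    Qb, _, _ = _whiten(Xb)
    block_sizes = [t.counts.shape[0] for t in tensors_b]
    offsets = np.concatenate([[0], np.cumsum(block_sizes)])
    blocks = [np.arange(offsets[i], offsets[i + 1])
              for i in range(n_trials)]
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = _permute_non_identity(rng, n_trials)
        idx = np.concatenate([blocks[i] for i in perm])
        M = Qa.T @ Qb[idx]
        null[s] = sla.svdvals(M)[0] ** 2
    thr = float(np.percentile(null, percentile))

    if observed == "train":
        obs = train_r2
    elif observed == "cv":
        obs = np.pad(cv_r2, (0, max(0, len(train_r2) - len(cv_r2))))
    else:
        raise ValueError("observed must be 'train' or 'cv'")
    significant = obs > thr
    if not significant.any():
        logger.info("no significant CVs: dataset flagged for exclusion")
    return CvSignificance(observed_r2=obs, crossval_r2=cv_r2,
                          null_percentile=percentile, null_threshold=thr,
                          null_r2=null, n_shuffles=n_shuffles,
                          significant=significant, observed_kind=observed)


# ---------------------------------------------------------------------------
# weight stability, subspace geometry, parameter sweep
# ---------------------------------------------------------------------------

def weight_stability(X_a: np.ndarray, X_b: np.ndarray, n_subsets: int = 10,
                     frac: float = 0.9, seed: int = 0,
                     ) -> dict[str, np.ndarray]:
    """Refit CCA on random subsets of time bins and report weight deltas.

    Each subset keeps ``frac`` of the rows (without replacement).  Subset
    CVs are sign-aligned to the full-data model (maximizing the
    weight-vector dot product) and rescaled to unit projection variance on
    the full data — the same normalization the full model carries — before
    deltas (subset - full) are taken, so deltas reflect changes in the
    weight *pattern* rather than sampling scale.
    Returns ``{region: (n_subsets, n_units, k) deltas}``.
    """
    full = fit_cca(X_a, X_b)
    rng = np.random.default_rng(seed)
    n = X_a.shape[0]
    m = int(round(frac * n))
    ra, rb = full.regions
    centered = {ra: X_a - X_a.mean(axis=0), rb: X_b - X_b.mean(axis=0)}
    out = {r: np.empty((n_subsets, full.weights[r].shape[0], full.k))
           for r in full.regions}
    for s in range(n_subsets):
        idx = rng.choice(n, size=m, replace=False)
        sub = fit_cca(X_a[idx], X_b[idx])
        k = min(full.k, sub.k)
        signs = np.sign(np.sum(sub.weights[ra][:, :k]
                               * full.weights[ra][:, :k], axis=0))
        signs[signs == 0] = 1.0
        for r in full.regions:
            W = sub.weights[r][:, :k] * signs
            scale = centered[r] @ W
            W = W / scale.std(axis=0, ddof=1)
            aligned = np.full_like(out[r][s], np.nan)
            aligned[:, :k] = W
            out[r][s] = aligned - full.weights[r]
    return out


def pca_axes(X: np.ndarray, k: int = 3) -> np.ndarray:
    """Top-k principal axes (n_units x k) of a centered activity matrix.

    Used to compare axes of maximal local covariance against the CCA axes
    of maximal cross-area correlation (via :func:`subspace_angle`).
    """
    from sklearn.decomposition import PCA
    X = np.asarray(X, dtype=float)
    return PCA(n_components=k).fit(X).components_.T


def subspace_angle(U: np.ndarray, V: np.ndarray) -> float:
    """Largest principal angle (degrees) between the spans of U and V.

    For two vectors this is the folded vector angle in [0, 90]; for a vector
    against a p-dimensional basis it is the angle between the vector and the
    subspace (MATLAB ``subspace`` convention).
    """
    U = np.atleast_2d(np.asarray(U, dtype=float))
    V = np.atleast_2d(np.asarray(V, dtype=float))
    if U.shape[0] == 1:
        U = U.T
    if V.shape[0] == 1:
        V = V.T
    if U.shape[0] != V.shape[0]:
        raise ValueError("bases must share ambient dimension")
    for M in (U, V):
        if np.linalg.matrix_rank(M) < M.shape[1]:
            raise ValueError("basis columns must be linearly independent")
    angles = sla.subspace_angles(U, V)
    return float(np.degrees(angles.max()))


@dataclass
class SweepResult:
    """Cross-validated top-CV R^2 over a binwidth x lag grid."""

    grid: "np.ndarray"          # structured per-cell results via pandas
    table: "object"             # DataFrame: binwidth_ms, lag_ms, r2, n_trials
    best_binwidth_ms: float
    best_lag_ms: float
    best_r2: float


def lag_binwidth_sweep(session, window: tuple[float, float] = (-1.0, 1.0),
                       event: str = "grasp_onset",
                       binwidths_ms: Sequence[float] = (100.0, 75.0, 50.0),
                       lag_range_ms: tuple[float, float] = (-500.0, 500.0),
                       folds: int = 10, seed: int = 0) -> SweepResult:
    """Sweep CCA generalization over bin widths and inter-region lags.

    For each cell, region B's (second region's) windows are shifted by the
    lag before binning; lags step by one bin.  Trials whose shifted window
    leaves the recorded span are dropped per cell; a cell with no valid
    trials is marked missing (NaN).
    """
    import pandas as pd
    from .core import align_trials

    rows = []
    reg_a, reg_b = session.regions
    for bw in binwidths_ms:
        lag_step = bw
        lags = np.arange(lag_range_ms[0], lag_range_ms[1] + lag_step / 2,
                         lag_step)
        for lag in lags:
            try:
                ta, _ = align_trials(session, reg_a, event, window, bw)
                shift = lag / 1000.0
                tb, _ = align_trials(session, reg_b, event,
                                     (window[0] + shift, window[1] + shift), bw)
                ids_a = {int(t.trial_index[0]) for t in ta}
                ids_b = {int(t.trial_index[0]) for t in tb}
                keep = sorted(ids_a & ids_b)
                ta = [t for t in ta if int(t.trial_index[0]) in keep]
                tb = [t for t in tb if int(t.trial_index[0]) in keep]
                Xa, _, _ = concat_and_center(ta)
                Xb, _, _ = concat_and_center(tb)
                r2 = float(crossval_r2(Xa, Xb, folds=folds, seed=seed)[0])
                rows.append((bw, float(lag), r2, len(keep)))
            except ValueError:
                rows.append((bw, float(lag), np.nan, 0))
    table = pd.DataFrame(rows, columns=["binwidth_ms", "lag_ms", "r2",
                                        "n_trials"])
    valid = table.dropna(subset=["r2"])
    if valid.empty:
        raise ValueError("sweep produced no valid cells")
    best = valid.loc[valid["r2"].idxmax()]
    return SweepResult(grid=table.to_numpy(), table=table,
                       best_binwidth_ms=float(best["binwidth_ms"]),
                       best_lag_ms=float(best["lag_ms"]),
                       best_r2=float(best["r2"]))
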