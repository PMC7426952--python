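"""Single-trial coupling of cross-area activity to reach behavior.

Implements the d-prime modulation index on the top-CV cross-area signal
(reach window vs an equal-length baseline window), its log-log relationship
with reach duration, and the reach-initiation analyses: median separability
of pre-reach vs initiation activity, logistic-regression detection of reach
start with ROC/AUC, and single-trial prediction time courses.

Window conventions (seconds, relative to trial events):

* reach window      : [reach_start - 0.1, grasp_onset + 0.1]
* baseline window   : equal length, ending at reach_start - 1.1
* pre-reach window  : [reach_start - 2.0, reach_start - 0.1), truncated at
                      door_open when the reaction time is short
* initiation window : [reach_start - 0.1, reach_start + 0.3)

The d' denominator is (1/2) * sqrt(sigma_reach + sigma_baseline) with sigma
a standard deviation — a non-standard pooled form that is implemented as
stated; ``variant="pooled"`` provides the conventional
sqrt((sigma_r^2 + sigma_b^2)/2) for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve as _sk_roc_curve, roc_auc_score

logger = logging.getLogger("crossarea")

PRE_REACH_WINDOW = (-2.0, -0.1)      # s, relative to reach start
INIT_WINDOW = (-0.1, 0.3)            # s, relative to reach start


# ---------------------------------------------------------------------------
# modulation (d') and its duration coupling
# ---------------------------------------------------------------------------

@dataclass
class ModulationRecord:
    trial_id: int
    d_prime: float
    mu_reach: float
    mu_baseline: float
    sigma_reach: float
    sigma_baseline: float
    reach_window: tuple[float, float]
    baseline_window: tuple[float, float]
    reach_duration_s: float = np.nan
    stage: str = ""
    animal_id: str = ""
    valid: bool = True


def reach_windows(reach_start_s: float, grasp_onset_s: float,
                  data_start_s: float = -np.inf,
                  ) -> tuple[tuple[float, float], tuple[float, float]]:
    """Reach and equal-length baseline windows for one trial.

    reach = [reach_start - 0.1, grasp_onset + 0.1]; the baseline has the
    same length and ends 1 s before the reach window starts.  Raises
    ``ValueError`` when the baseline would precede the available data so
    callers can drop and count the trial.
    """
    if not (np.isfinite(reach_start_s) and np.isfinite(grasp_onset_s)):
        raise ValueError("reach_start and grasp_onset required")
    reach = (reach_start_s - 0.1, grasp_onset_s + 0.1)
    length = reach[1] - reach[0]
    base_end = reach[0] - 1.0
    baseline = (base_end - length, base_end)
    if baseline[0] < data_start_s:
        raise ValueError("baseline window precedes available data")
    return reach, baseline


def ca_modulation(signal: np.ndarray, time_s: np.ndarray,
                  reach_window: tuple[float, float],
                  baseline_window: tuple[float, float],
                  variant: str = "printed",
                  trial_id: int = -1, **meta) -> ModulationRecord:
    """Single-trial cross-area modulation d' of a CS signal trajectory.

    The baseline median is subtracted from both segments before computing
    means and standard deviations.  ``variant="printed"`` uses the
    denominator (1/2)sqrt(sigma_r + sigma_b); ``"pooled"`` the textbook
    sqrt((sigma_r^2 + sigma_b^2)/2).  A record with both sigmas zero is
    flagged invalid (d' undefined) rather than raising.
    """
    signal = np.asarray(signal, dtype=float)
    time_s = np.asarray(time_s, dtype=float)
    in_reach = (time_s >= reach_window[0]) & (time_s < reach_window[1])
    in_base = (time_s >= baseline_window[0]) & (time_s < baseline_window[1])
    if in_reach.sum() < 2 or in_base.sum() < 2:
        raise ValueError("both windows need at least 2 bins")
    base_med = float(np.median(signal[in_base]))
    reach_seg = signal[in_reach] - base_med
    base_seg = signal[in_base] - base_med
    mu_r, mu_b = float(reach_seg.mean()), float(base_seg.mean())
    sd_r, sd_b = float(reach_seg.std(ddof=1)), float(base_seg.std(ddof=1))
    if sd_r + sd_b == 0:
        return ModulationRecord(trial_id, np.nan, mu_r, mu_b, sd_r, sd_b,
                                reach_window, baseline_window,
                                valid=False, **meta)
    if variant == "printed":
        denom = 0.5 * np.sqrt(sd_r + sd_b)
    elif variant == "pooled":
        denom = np.sqrt((sd_r ** 2 + sd_b ** 2) / 2.0)
    else:
        raise ValueError("variant must be 'printed' or 'pooled'")
    return ModulationRecord(trial_id, (mu_r - mu_b) / denom, mu_r, mu_b,
                            sd_r, sd_b, reach_window, baseline_window, **meta)


def modulation_table(records: list[ModulationRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "trial_id": r.trial_id, "d_prime": r.d_prime,
        "reach_duration_s": r.reach_duration_s, "stage": r.stage,
        "animal_id": r.animal_id, "valid": r.valid} for r in records])


def duration_modulation_slope(records: pd.DataFrame,
                              ) -> tuple[float, float, float, int]:
    """Log-log regression of d' on reach duration with stage covariate.

    Only trials with positive d' enter (the excluded count is returned);
    the learning stage is an additive covariate, and the animal is added
    as a further additive term when more than one animal is present.
    Returns (slope, t, p, n_excluded).
    """
    from .stats import group_summary_regression

    df = records.copy()
    if "valid" in df:
        df = df[df["valid"]]
    n_all = len(df)
    df = df[df["d_prime"] > 0].copy()
    n_excluded = n_all - len(df)
    if len(df) == 0:
        raise ValueError("no trials with positive modulation")
    if len(df) < 10:
        raise ValueError("need at least 10 positively modulated trials")
    df["log_d"] = np.log(df["d_prime"])
    df["log_dur"] = np.log(df["reach_duration_s"])
    covs = ["log_dur"]
    if df["stage"].nunique() > 1:
        covs.append("C(stage)")
    if "animal_id" in df and df["animal_id"].nunique() > 1:
        covs.append("C(animal_id)")
    res = group_summary_regression(df, "log_d", covs)
    return (float(res.params["log_dur"]), float(res.tvalues["log_dur"]),
            float(res.pvalues["log_dur"]), n_excluded)


# ---------------------------------------------------------------------------
# reach-initiation detection
# ---------------------------------------------------------------------------

@dataclass
class DetectorModel:
    coef: np.ndarray            # (n_channels,)
    intercept: float
    channels: tuple[str, ...]
    ridge_fallback: bool = False

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        z = X @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-z))


@dataclass
class DetectionEval:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def label_detection_samples(trials: pd.DataFrame,
                            trajectories: dict[int, tuple[np.ndarray, np.ndarray]],
                            ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Label CS-activity bins as pre-reach (0) or reach initiation (1).

    ``trajectories`` maps trial_id to ``(time_s, values)`` where ``values``
    is (n_bins,) or (n_bins, n_channels) CS activity and times are absolute.
    The pre-reach window truncates at door_open when the reaction time is
    under 2 s (truncations are counted); trials providing no initiation
    bins are dropped and counted.  Returns (X, y, report).
    """
    X_rows, y_rows = [], []
    report = {"n_trials": 0, "n_dropped": 0, "n_truncated": 0}
    for _, trial in trials.iterrows():
        tid = int(trial["trial_id"])
        if tid not in trajectories:
            report["n_dropped"] += 1
            continue
        time_s, values = trajectories[tid]
        values = np.asarray(values, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        rs = trial["reach_start_s"]
        pre_lo = rs + PRE_REACH_WINDOW[0]
        if np.isfinite(trial.get("door_open_s", np.nan)) \
                and trial["door_open_s"] > pre_lo:
            pre_lo = trial["door_open_s"]
            report["n_truncated"] += 1
        pre = (time_s >= pre_lo) & (time_s < rs + PRE_REACH_WINDOW[1])
        init = (time_s >= rs + INIT_WINDOW[0]) & (time_s < rs + INIT_WINDOW[1])
        if init.sum() == 0 or pre.sum() == 0:
            report["n_dropped"] += 1
            continue
        X_rows.append(values[pre])
        y_rows.append(np.zeros(int(pre.sum())))
        X_rows.append(values[init])
        y_rows.append(np.ones(int(init.sum())))
        report["n_trials"] += 1
    if not X_rows:
        raise ValueError("no valid trials for detection labeling")
    X = np.vstack(X_rows)
    y = np.concatenate(y_rows)
    report["class_counts"] = (int((y == 0).sum()), int((y == 1).sum()))
    return X, y, report


def fit_reach_detector(X: np.ndarray, y: np.ndarray,
                       channels: tuple[str, ...] = ("M2", "M1"),
                       ) -> tuple[DetectorModel, np.ndarray]:
    """Maximum-likelihood logistic regression of initiation labels on CS
    activity; returns the model and in-sample predicted probabilities.

    Perfect separation (divergent unpenalized fit) falls back to an L2
    ridge fit with the ``ridge_fallback`` flag set.
    """
    y = np.asarray(y, dtype=int)
    X = np.asarray(X, dtype=float).reshape(len(y), -1)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    ridge = False
    clf = LogisticRegression(C=np.inf, max_iter=2000)
    with np.errstate(over="ignore"):
        clf.fit(X, y)
    z = X @ clf.coef_.ravel() + clf.intercept_[0]
    separated = (np.isfinite(z).all()
                 and z[y == 0].max() < z[y == 1].min())
    if separated or not np.all(np.isfinite(clf.coef_)):
        # unpenalized ML diverges under perfect separation; cap with ridge
        clf = LogisticRegression(C=1.0, max_iter=2000)
        clf.fit(X, y)
        ridge = True
        logger.warning("perfect separation: ridge fallback used")
    model = DetectorModel(coef=clf.coef_.ravel(),
                          intercept=float(clf.intercept_[0]),
                          channels=tuple(channels), ridge_fallback=ridge)
    return model, model.predict_proba(X)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> DetectionEval:
    """ROC curve and trapezoidal AUC; ties handled by rank averaging
    (the AUC equals the concordant-pair statistic)."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = _sk_roc_curve(labels, scores)
    return DetectionEval(fpr=fpr, tpr=tpr,
                         auc=float(roc_auc_score(labels, scores)))


def prediction_timecourse(model: DetectorModel, trials: pd.DataFrame,
                          trajectories: dict[int, tuple[np.ndarray, np.ndarray]],
                          ) -> tuple[dict[int, np.ndarray], float]:
    """Per-trial predicted initiation probability and the session summary.

    The per-trial summary is the mean predicted probability over the
    initiation window minus the mean over the pre-reach window; the session
    summary is the mean of trial summaries.
    """
    probs: dict[int, np.ndarray] = {}
    summaries = []
    for _, trial in trials.iterrows():
        tid = int(trial["trial_id"])
        if tid not in trajectories:
            continue
        time_s, values = trajectories[tid]
        values = np.asarray(values, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        p = model.predict_proba(values)
        probs[tid] = p
        rs = trial["reach_start_s"]
        pre = (time_s >= rs + PRE_REACH_WINDOW[0]) \
            & (time_s < rs + PRE_REACH_WINDOW[1])
        init = (time_s >= rs + INIT_WINDOW[0]) & (time_s < rs + INIT_WINDOW[1])
        if pre.any() and init.any():
            summaries.append(p[init].mean() - p[pre].mean())
    return probs, float(np.mean(summaries)) if summaries else np.nan


def median_separability(pre_values: np.ndarray,
                        init_values: np.ndarray) -> float:
    """Difference of medians, initiation minus pre-reach, on the (session
    z-scored) CS signal."""
    pre = np.asarray(pre_values, dtype=float)
    init = np.asarray(init_values, dtype=float)
    if pre.size == 0 or init.size == 0:
        raise ValueError("both sets must be nonempty")
    return float(np.median(init) - np.median(pre))
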