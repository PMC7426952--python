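"""Convenience glue running the full analysis on a session.

These helpers chain the module-level operations in the order the method
runs: peri-grasp binning and concatenation -> CCA fit and trial-shuffle
significance -> top-CV cross-area trajectories -> local residual magnitudes
-> behavioral coupling.  They exist so the CLI, the tests and the
reproduction script share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SessionData, align_trials, concat_and_center
from .cca import CCAModel, CvSignificance, fit_cca, trial_shuffle_significance
from .local import local_projection, per_trial_timings
from .behavior import ca_modulation, modulation_table, reach_windows

PERI_GRASP = (-1.0, 1.0)          # s, CCA fitting window around grasp onset
TRAJ_WINDOW = (-2.6, 2.0)         # s around reach start for trajectories
BINWIDTH_MS = 100.0


def peri_grasp_matrices(session: SessionData,
                        binwidth_ms: float = BINWIDTH_MS,
                        window: tuple[float, float] = PERI_GRASP):
    """Per-trial tensors and centered concatenations for both regions,
    restricted to trials valid in both."""
    out = {}
    kept = None
    for region in session.regions:
        tensors, dropped = align_trials(session, region, "grasp_onset",
                                        window, binwidth_ms)
        ids = [int(t.trial_index[0]) for t in tensors]
        kept = set(ids) if kept is None else kept & set(ids)
        out[region] = dict(zip(ids, tensors))
    durations = session.trials.set_index("trial_id")["reach_duration_s"]
    result = {}
    for region in session.regions:
        tensors = [out[region][i] for i in sorted(kept)]
        X, trial_map, means = concat_and_center(tensors)
        # reach-initiation rows (used to orient CV signs): bins within
        # [-0.1, +0.3] s of reach start, i.e. [-dur-0.1, -dur+0.3] rel grasp
        orient = np.concatenate([
            (t.time_s >= -durations.loc[int(t.trial_index[0])] - 0.1)
            & (t.time_s < -durations.loc[int(t.trial_index[0])] + 0.3)
            for t in tensors])
        result[region] = {"tensors": tensors, "X": X,
                          "trial_map": trial_map, "means": means,
                          "orient_rows": orient}
    return result


@dataclass
class SessionFit:
    model: CCAModel
    significance: CvSignificance
    mats: dict


def fit_session(session: SessionData, n_shuffles: int = 500,
                seed: int = 0, binwidth_ms: float = BINWIDTH_MS) -> SessionFit:
    """Fit CCA on the peri-grasp window and assess CV significance."""
    mats = peri_grasp_matrices(session, binwidth_ms)
    ra, rb = session.regions
    sig = trial_shuffle_significance(mats[ra]["tensors"], mats[rb]["tensors"],
                                     n_shuffles=n_shuffles, seed=seed)
    model = fit_cca(mats[ra]["X"], mats[rb]["X"], regions=(ra, rb),
                    binwidth_ms=binwidth_ms,
                    orient_rows=mats[ra]["orient_rows"])
    return SessionFit(model=model, significance=sig, mats=mats)


def cs_trajectories(session: SessionData, model: CCAModel,
                    regions: tuple[str, ...] | None = None,
                    window: tuple[float, float] = TRAJ_WINDOW,
                    binwidth_ms: float = BINWIDTH_MS,
                    ) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Top-CV cross-area activity per trial, on a window around reach start.

    Returns trial_id -> (absolute bin centers, values) with one column per
    requested region.  Values are z-scored per region across all analyzed
    bins of the session.
    """
    regions = regions or session.regions
    per_region = {}
    kept = None
    for region in regions:
        tensors, _ = align_trials(session, region, "reach_start",
                                  window, binwidth_ms)
        ids = [int(t.trial_index[0]) for t in tensors]
        kept = set(ids) if kept is None else kept & set(ids)
        per_region[region] = dict(zip(ids, tensors))
    trial_ids = sorted(kept)
    # project and z-score per region over all analyzed bins
    projected: dict[str, dict[int, np.ndarray]] = {}
    for region in regions:
        vals = {i: model.project(per_region[region][i].counts, region, 0)
                for i in trial_ids}
        pooled = np.concatenate(list(vals.values()))
        mu, sd = pooled.mean(), pooled.std(ddof=1)
        projected[region] = {i: (v - mu) / sd if sd > 0 else v - mu
                             for i, v in vals.items()}
    out = {}
    starts = session.trials.set_index("trial_id")["reach_start_s"]
    for i in trial_ids:
        times = per_region[regions[0]][i].time_s + starts.loc[i]
        out[i] = (times, np.column_stack([projected[r][i] for r in regions]))
    return out


def local_magnitudes(session: SessionData, fit: SessionFit,
                     use_significant: bool = True,
                     ) -> dict[str, tuple[np.ndarray, list[np.ndarray]]]:
    """Per-trial local-activity magnitude trajectories for both regions.

    The cross-area subspace uses all significant CVs (falling back to the
    top CV when ``use_significant`` is False or none are flagged).
    Returns region -> (bin centers rel. grasp, list of per-trial series).
    """
    n_sig = fit.significance.n_significant
    m = max(1, n_sig) if use_significant else 1
    out = {}
    for region in session.regions:
        info = fit.mats[region]
        W = fit.model.weights[region][:, :m]
        mags = []
        time_s = info["tensors"][0].time_s
        n_bins = len(time_s)
        X = info["X"]
        for t in range(len(info["tensors"])):
            rows = X[t * n_bins:(t + 1) * n_bins]
            mags.append(local_projection(rows, W, region).local_mag)
        out[region] = (time_s, mags)
    return out


def session_timing_difference(session: SessionData, fit: SessionFit,
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial median timings (s, rel. grasp) of M2 and M1 local activity."""
    mags = local_magnitudes(session, fit)
    ra, rb = session.regions
    t_a, m_a = mags[ra]
    t_b, m_b = mags[rb]
    tim_a, _ = per_trial_timings(m_a, t_a)
    tim_b, _ = per_trial_timings(m_b, t_b)
    return tim_a, tim_b


def session_modulation(session: SessionData, model: CCAModel, region: str,
                       variant: str = "printed") -> pd.DataFrame:
    """CA-modulation (d') records for every analyzable trial of a session."""
    traj = cs_trajectories(session, model, regions=(region,))
    records = []
    for _, trial in session.trials.iterrows():
        tid = int(trial["trial_id"])
        if tid not in traj:
            continue
        time_s, values = traj[tid]
        try:
            rw, bw = reach_windows(trial["reach_start_s"],
                                   trial["grasp_onset_s"],
                                   data_start_s=time_s[0])
            rec = ca_modulation(values[:, 0], time_s, rw, bw,
                                variant=variant, trial_id=tid,
                                reach_duration_s=trial["reach_duration_s"],
                                stage=session.stage,
                                animal_id=session.animal_id)
        except ValueError:
            continue
        records.append(rec)
    return modulation_table(records)
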