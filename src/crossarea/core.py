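"""Core data model for paired-region spike recordings.

A session holds spike timestamps for units in exactly two simultaneously
recorded regions (canonically premotor "M2" and motor "M1" cortex) together
with a per-trial event table for a cued reach-to-grasp task.  Everything
downstream (PETHs, canonical correlation, local-dynamics timing, behavioral
coupling) consumes the binned representations built here.

Conventions
-----------
* All event and spike times are in **seconds** from the start of the
  recording; bin widths cross the API boundary in **milliseconds**.
* Bins are half-open ``[t, t + dt)``: a spike exactly on the right edge of
  the analysis window is excluded.
* z-scoring uses the sample (n-1) standard deviation; zero-variance units
  become all-zero columns rather than NaN.
* Trials missing a required alignment event, or whose window falls outside
  the recorded span, are dropped (never imputed) and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("crossarea")

#: trial-table columns required on ingestion
TRIAL_COLUMNS = ("trial_id", "door_open_s", "reach_start_s", "grasp_onset_s",
                 "reach_end_s", "success")

#: events a trial alignment may target
ALIGN_EVENTS = ("door_open", "reach_start", "grasp_onset")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

def make_trial_table(door_open: Sequence[float],
                     reach_start: Sequence[float],
                     grasp_onset: Sequence[float],
                     reach_end: Sequence[float] | None = None,
                     success: Sequence[bool] | None = None) -> pd.DataFrame:
    """Assemble a validated trial table with derived behavioral columns.

    ``reaction_time_s = reach_start - door_open`` and
    ``reach_duration_s = grasp_onset - reach_start`` are added.  Raises
    ``ValueError`` on event-order violations or overlapping trials.
    """
    n = len(door_open)
    df = pd.DataFrame({
        "trial_id": np.arange(n, dtype=int),
        "door_open_s": np.asarray(door_open, dtype=float),
        "reach_start_s": np.asarray(reach_start, dtype=float),
        "grasp_onset_s": np.asarray(grasp_onset, dtype=float),
        "reach_end_s": (np.asarray(reach_end, dtype=float)
                        if reach_end is not None else np.full(n, np.nan)),
        "success": (np.asarray(success, dtype=bool)
                    if success is not None else np.zeros(n, dtype=bool)),
    })
    df["reaction_time_s"] = df["reach_start_s"] - df["door_open_s"]
    df["reach_duration_s"] = df["grasp_onset_s"] - df["reach_start_s"]
    _validate_trials(df)
    return df


def _validate_trials(df: pd.DataFrame) -> None:
    ok = df.dropna(subset=["door_open_s", "reach_start_s", "grasp_onset_s"])
    if (ok["door_open_s"] > ok["reach_start_s"]).any():
        raise ValueError("door_open after reach_start")
    if (ok["reach_start_s"] > ok["grasp_onset_s"]).any():
        raise ValueError("reach_start after grasp_onset")
    if (ok["reach_duration_s"] <= 0).any():
        raise ValueError("non-positive reach duration")
    starts = ok["door_open_s"].to_numpy()
    ends = ok["grasp_onset_s"].to_numpy()
    if len(ok) > 1 and (starts[1:] < ends[:-1]).any():
        raise ValueError("trials overlap in time")


@dataclass
class SessionData:
    """Spike timestamps for two regions plus the trial event table.

    Parameters
    ----------
    regions : exactly two region labels, e.g. ``("M2", "M1")``.
    units : mapping region -> list of per-unit sorted spike-time arrays (s).
    trials : trial table (see :func:`make_trial_table`).
    animal_id : subject identifier used by hierarchical statistics.
    stage : one of ``early``, ``late``, ``baseline``, ``perturbed``.
    """

    regions: tuple[str, str]
    units: Mapping[str, list[np.ndarray]]
    trials: pd.DataFrame
    animal_id: str = "rat0"
    stage: str = "late"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.regions) != 2:
            raise ValueError("exactly two regions required")
        for r in self.regions:
            if r not in self.units or len(self.units[r]) == 0:
                raise ValueError(f"region {r!r} needs at least one unit")
            clean = []
            for st in self.units[r]:
                st = np.asarray(st, dtype=float)
                if st.size and (np.any(st < 0) or np.any(np.diff(st) < 0)):
                    raise ValueError("spike times must be nonnegative and sorted")
                clean.append(st)
            self.units[r] = clean  # type: ignore[index]
        _validate_trials(self.trials)

    def n_units(self, region: str) -> int:
        return len(self.units[region])

    @property
    def span(self) -> tuple[float, float]:
        """Recorded span: zero to the last spike or event, whichever is later."""
        if "t_end" in self.meta:
            return (0.0, float(self.meta["t_end"]))
        last_spike = max((st[-1] for r in self.regions for st in self.units[r]
                          if st.size), default=0.0)
        last_event = float(np.nanmax(self.trials[["grasp_onset_s",
                                                  "reach_end_s"]].to_numpy()))
        return (0.0, max(last_spike, last_event))


@dataclass
class BinnedPopulation:
    """Time-bin x unit spike-count matrix.

    ``time_s`` holds bin centers relative to ``event`` (or absolute time for
    continuous binning, ``event="continuous"``).  ``trial_index`` maps each
    row to its source trial, or is None for continuous data.
    """

    counts: np.ndarray                  # (n_bins, n_units)
    binwidth_ms: float
    time_s: np.ndarray                  # (n_bins,) bin centers
    event: str
    trial_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (bins x units)")
        if self.counts.shape[0] != len(self.time_s):
            raise ValueError("row count must match time axis length")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_units(self) -> int:
        return self.counts.shape[1]


# ---------------------------------------------------------------------------
# binning and alignment
# ---------------------------------------------------------------------------

def bin_spikes(unit_spikes: Sequence[np.ndarray],
               window: tuple[float, float],
               binwidth_ms: float,
               event: str = "continuous") -> BinnedPopulation:
    """Bin spike times of several units into half-open [t, t+dt) bins.

    Any trailing partial bin (window length not a multiple of the bin width)
    is dropped.  Spikes on the right window edge fall outside the last bin.
    """
    if len(unit_spikes) == 0:
        raise ValueError("empty unit list")
    start, end = float(window[0]), float(window[1])
    if end <= start:
        raise ValueError("window end must exceed start")
    dt = binwidth_ms / 1000.0
    n_bins = int(np.floor((end - start) / dt + 1e-9))
    if n_bins < 1:
        raise ValueError("window shorter than one bin")
    edges = start + dt * np.arange(n_bins + 1)
    cols = []
    for st in unit_spikes:
        st = np.asarray(st, dtype=float)
        if st.size and np.any(np.diff(st) < 0):
            raise ValueError("spike times must be sorted")
        # restrict to [start, end) first: keeps the analysis window (and its
        # right edge) half-open regardless of floating-point edge placement
        st = st[(st >= start) & (st < min(end, edges[-1]))]
        counts = np.histogram(st, bins=edges)[0].astype(float)
        cols.append(counts)
    centers = edges[:-1] + dt / 2.0
    return BinnedPopulation(np.column_stack(cols), binwidth_ms, centers, event)


def align_trials(session: SessionData, region: str, event: str,
                 window: tuple[float, float], binwidth_ms: float,
                 ) -> tuple[list[BinnedPopulation], int]:
    """Bin one region's spikes in a window around ``event`` on every trial.

    Trials lacking the event or whose window exceeds the recorded span are
    dropped; the drop count is returned alongside the per-trial tensors.
    Raises ``ValueError`` if no trial survives.
    """
    if event not in ALIGN_EVENTS:
        raise ValueError(f"unknown alignment event {event!r}")
    col = event + "_s"
    t0, t1 = session.span
    ev = session.trials[col].to_numpy(dtype=float)
    tids = session.trials["trial_id"].to_numpy(dtype=int)
    ok = np.isfinite(ev) & (ev + window[0] >= t0) & (ev + window[1] <= t1)
    dropped = int((~ok).sum())
    ev, tids = ev[ok], tids[ok]
    if ev.size == 0:
        raise ValueError("no trials retained after alignment")

    dt = binwidth_ms / 1000.0
    n_bins = int(np.floor((window[1] - window[0]) / dt + 1e-9))
    if n_bins < 1:
        raise ValueError("window shorter than one bin")
    rel_edges = window[0] + dt * np.arange(n_bins + 1)
    centers = rel_edges[:-1] + dt / 2.0
    # (n_trials, n_bins+1) absolute edges; half-open bins via searchsorted-left
    edges = ev[:, None] + rel_edges[None, :]
    counts = np.empty((ev.size, n_bins, session.n_units(region)))
    for u, st in enumerate(session.units[region]):
        pos = np.searchsorted(st, edges.ravel(), side="left")
        counts[:, :, u] = np.diff(pos.reshape(edges.shape), axis=1)
    tensors = [BinnedPopulation(counts[i], binwidth_ms, centers.copy(), event,
                                trial_index=np.full(n_bins, tids[i]))
               for i in range(ev.size)]
    if dropped:
        logger.info("align_trials(%s, %s): dropped %d trial(s)",
                    region, event, dropped)
    return tensors, dropped


def concat_and_center(tensors: Sequence[BinnedPopulation],
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack per-trial tensors in trial order and subtract column means.

    Returns ``(matrix, trial_map, column_means)``; ``trial_map[i]`` is the
    trial id of row ``i`` so the concatenation can be split back apart.
    """
    n_units = {t.counts.shape[1] for t in tensors}
    if len(n_units) != 1:
        raise ValueError("mismatched unit counts across trials")
    mat = np.vstack([t.counts for t in tensors]).astype(float)
    trial_map = np.concatenate([
        t.trial_index if t.trial_index is not None
        else np.full(t.counts.shape[0], i)
        for i, t in enumerate(tensors)])
    means = mat.mean(axis=0)
    return mat - means, trial_map, means


def split_by_trial(matrix: np.ndarray, trial_map: np.ndarray,
                   ) -> dict[int, np.ndarray]:
    """Invert :func:`concat_and_center`'s stacking (centering offset aside)."""
    return {int(t): matrix[trial_map == t] for t in np.unique(trial_map)}


def zscore_per_unit(matrix: np.ndarray) -> np.ndarray:
    """Column-wise z-score with n-1 sd; zero-variance columns map to zeros."""
    matrix = np.asarray(matrix, dtype=float)
    mu = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1) if matrix.shape[0] > 1 else np.zeros(matrix.shape[1])
    out = matrix - mu
    nz = sd > 0
    out[:, nz] /= sd[nz]
    out[:, ~nz] = 0.0
    return out


# ---------------------------------------------------------------------------
# TSV / YAML external interfaces
# ---------------------------------------------------------------------------

def write_session(session: SessionData, out_dir: str | Path) -> None:
    """Write ``spikes.tsv`` (region, unit_id, spike_time_s) and ``trials.tsv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for region in session.regions:
        for uid, st in enumerate(session.units[region]):
            rows.append(pd.DataFrame({"region": region, "unit_id": uid,
                                      "spike_time_s": st}))
    pd.concat(rows, ignore_index=True).to_csv(out / "spikes.tsv", sep="\t",
                                              index=False, float_format="%.6f")
    session.trials.to_csv(out / "trials.tsv", sep="\t", index=False,
                          float_format="%.6f")
    with open(out / "session.yaml", "w") as fh:
        yaml.safe_dump({"regions": list(session.regions),
                        "animal_id": session.animal_id,
                        "stage": session.stage,
                        "t_end": float(session.span[1])}, fh)


def read_session(in_dir: str | Path) -> SessionData:
    """Read a session directory written by :func:`write_session`."""
    src = Path(in_dir)
    spikes = pd.read_csv(src / "spikes.tsv", sep="\t")
    trials = pd.read_csv(src / "trials.tsv", sep="\t")
    meta_path = src / "session.yaml"
    meta = yaml.safe_load(meta_path.read_text()) if meta_path.exists() else {}
    regions = tuple(meta.get("regions") or
                    pd.unique(spikes["region"]).tolist())
    units: dict[str, list[np.ndarray]] = {}
    for region in regions:
        sub = spikes[spikes["region"] == region]
        n = int(sub["unit_id"].max()) + 1 if len(sub) else 0
        units[region] = [np.sort(sub.loc[sub["unit_id"] == u,
                                         "spike_time_s"].to_numpy())
                         for u in range(n)]
    if "reaction_time_s" not in trials:
        trials["reaction_time_s"] = trials["reach_start_s"] - trials["door_open_s"]
    if "reach_duration_s" not in trials:
        trials["reach_duration_s"] = trials["grasp_onset_s"] - trials["reach_start_s"]
    extra = {"t_end": meta["t_end"]} if "t_end" in meta else {}
    return SessionData(regions=regions, units=units, trials=trials,
                       animal_id=str(meta.get("animal_id", "rat0")),
                       stage=str(meta.get("stage", "late")), meta=extra)


def load_config(path: str | Path) -> dict:
    """Load a YAML config with sections {data, windows, cca, nulls, seeds}."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg
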