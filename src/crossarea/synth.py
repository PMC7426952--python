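"""Two-region synthetic spiking sessions with planted shared/local structure.

The generator emulates the recording geometry the analysis pipeline assumes:
two populations ("M2", "M1") whose firing is driven by a single shared
low-dimensional latent plus region-local latents, wrapped in a reach-to-grasp
trial structure.  Every session comes with its ground truth (planted loading
vectors, per-trial shared amplitude, local lead/lag, duration-coupling
exponent) so downstream estimators can be scored against known answers.

Rate model (log link, per unit u in region r, trial-local time t):

    lambda_u(t) = baseline_u * exp( w_shared,u * a_trial * z(t)
                                    + w_local,u * l_r(t) )

with ``z`` a Gaussian bump peaking at reach start whose width scales with
reach duration, ``a_trial = a_stage * (duration/ref)**beta`` (beta < 0: short
reaches carry larger shared amplitude) times a log-normal trial jitter, and
the local latents ``l_M2`` leading ``l_M1`` by a planted lag.  Spikes are
drawn as an inhomogeneous Poisson process (discretized on a 5 ms grid inside
the peri-reach modulation window, homogeneous at baseline elsewhere) with a
fixed 1 ms dead time.  Rates are clipped at ``lambda_max``.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .core import SessionData, make_trial_table

logger = logging.getLogger("crossarea")

_FINE_DT = 0.005          # s, discretization of the inhomogeneous rate
_MOD_PAD = (-1.8, 2.2)    # s around reach start where latents are evaluated


@dataclass
class SyntheticConfig:
    """Study conditions for one simulated animal.

    Behavioral defaults follow the printed early/late statistics of the task
    (mean reach duration 0.30 s early vs 0.20 s late; late reaction time
    ~0.9 s; success 27%/58%); neural amplitude scales are free parameters of
    the emulation, chosen so that the late stage is a clearly detectable
    ("high-SNR") regime and the early stage a weak one.
    """

    n_units: Mapping[str, int] = field(
        default_factory=lambda: {"M2": 30, "M1": 30})
    n_trials: int = 200
    seed: int = 0
    baseline_rate_hz: tuple[float, float] = (20.0, 50.0)
    # shared-latent amplitude by stage (a_stage)
    shared_amplitude: Mapping[str, float] = field(
        default_factory=lambda: {"early": 0.5, "late": 3.0,
                                 "baseline": 3.0, "perturbed": 3.0})
    shared_dim: int = 1
    shared_amp_jitter_sigma: float = 0.25   # log-normal sigma on a_trial
    shared_lag_ms: float = 0.0              # M1 shared latent delay vs M2
    # local latents
    local_amplitude: Mapping[str, float] = field(
        default_factory=lambda: {"M2": 2.5, "M1": 2.5})
    local_lag_ms: float = 100.0             # M2 local leads M1 local
    local_amp_jitter_sigma: float = 0.3
    center_jitter_sd_s: float = 0.10
    # behavioral distributions by stage
    duration_mean_s: Mapping[str, float] = field(
        default_factory=lambda: {"early": 0.30, "late": 0.20,
                                 "baseline": 0.20, "perturbed": 0.29})
    duration_lognorm_sigma: float = 0.25
    # reaction time: shifted exponential (shift, exponential mean), seconds
    reaction_time_s: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"early": (0.5, 2.5), "late": (0.3, 0.6),
                                 "baseline": (0.3, 0.6),
                                 "perturbed": (0.5, 2.5)})
    success_rate: Mapping[str, float] = field(
        default_factory=lambda: {"early": 0.273, "late": 0.576,
                                 "baseline": 0.576, "perturbed": 0.374})
    # coupling of shared amplitude to duration: a ~ (duration/ref)**beta
    beta: float = -0.25
    ref_duration_s: float = 0.25
    kernel_width_s: float = 0.5         # shared-bump sigma at ref duration
    local_kernel_width_s: float = 0.20
    iti_s: float = 4.0
    lambda_max_hz: float = 200.0
    dead_time_ms: float = 1.0
    # multiplier on M2 latent drive when stage == "perturbed" (muscimol-like)
    m2_suppression: float = 0.05

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if any(a < 0 for a in self.shared_amplitude.values()):
            raise ValueError("shared amplitudes must be >= 0")
        if any(d <= 0 for d in self.duration_mean_s.values()):
            raise ValueError("duration means must be positive")


@dataclass
class SyntheticGroundTruth:
    """Planted structure of one generated session."""

    w_shared: Mapping[str, np.ndarray]       # unit-norm, (n_units, shared_dim)
    w_local: Mapping[str, np.ndarray]        # unit-norm, (n_units,)
    baseline_hz: Mapping[str, np.ndarray]
    shared_amp_per_trial: np.ndarray         # a_trial, (n_trials,)
    local_lag_ms: float
    shared_lag_ms: float
    beta: float
    latent_centers_s: pd.DataFrame           # per-trial latent bump centers


def _unit_vectors(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    v = rng.standard_normal((n, k))
    q, _ = np.linalg.qr(v)
    return q[:, :k]


def _draw_trial_schedule(cfg: SyntheticConfig, stage: str,
                         rng: np.random.Generator) -> pd.DataFrame:
    shift, mean_exp = cfg.reaction_time_s[stage]
    rts = shift + rng.exponential(mean_exp, cfg.n_trials)
    mean_d = cfg.duration_mean_s[stage]
    sig = cfg.duration_lognorm_sigma
    mu = np.log(mean_d) - sig ** 2 / 2.0       # log-normal with given mean
    durations = rng.lognormal(mu, sig, cfg.n_trials)
    success = rng.random(cfg.n_trials) < cfg.success_rate[stage]

    door, reach, grasp, reach_end = [], [], [], []
    t = 3.0                                     # head room for baselines
    for i in range(cfg.n_trials):
        d_open = t
        r_start = d_open + rts[i]
        g_on = r_start + durations[i]
        door.append(d_open)
        reach.append(r_start)
        grasp.append(g_on)
        reach_end.append(g_on + 0.15)
        t = g_on + 2.5 + cfg.iti_s
    return make_trial_table(door, reach, grasp, reach_end, success)


def generate_session(cfg: SyntheticConfig, stage: str = "late",
                     ) -> tuple[SessionData, SyntheticGroundTruth]:
    """Generate one session at the given learning stage.

    Deterministic given ``cfg.seed`` and ``stage``.  Returns the session and
    its planted ground truth.
    """
    if stage not in cfg.shared_amplitude:
        raise ValueError(f"unknown stage {stage!r}")
    stage_key = zlib.crc32(stage.encode()) & 0x7FFFFFFF
    seed = np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, stage_key])
    rng = np.random.default_rng(seed)

    regions = ("M2", "M1")
    trials = _draw_trial_schedule(cfg, stage, rng)
    durations = trials["reach_duration_s"].to_numpy()
    reach_starts = trials["reach_start_s"].to_numpy()

    baseline = {r: rng.uniform(*cfg.baseline_rate_hz, cfg.n_units[r])
                for r in regions}
    w_shared = {r: _unit_vectors(rng, cfg.n_units[r], cfg.shared_dim)
                for r in regions}
    # Local loadings are orthogonalized against the shared loadings in the
    # rate-weighted (Poisson noise) metric, so the planted "local" axis
    # carries no first-order projection onto the shared axis in count space
    # and the two kinds of dynamics are genuinely separable.
    w_local = {}
    for r in regions:
        # dense, equal-magnitude loading: local drive is distributed evenly
        # so no single unit carries an extreme exponent
        v = rng.choice([-1.0, 1.0], cfg.n_units[r])
        b = baseline[r]
        for j in range(cfg.shared_dim):
            ws = w_shared[r][:, j]
            v = v - ws * (b * v * ws).sum() / (b * ws * ws).sum()
        w_local[r] = v / np.linalg.norm(v)

    a_stage = cfg.shared_amplitude[stage]
    a_trial = (a_stage * (durations / cfg.ref_duration_s) ** cfg.beta
               * rng.lognormal(0.0, cfg.shared_amp_jitter_sigma, cfg.n_trials))
    # Local bump amplitude carries a random per-trial sign (independent per
    # region): local activity is movement-locked in time but its population
    # pattern varies trial to trial, so it has no event-locked trial mean
    # and no cross-region moment-to-moment correlation for CCA to absorb.
    # Magnitude-based local analyses are sign-invariant.
    local_amp_jit = {r: (rng.choice([-1.0, 1.0], cfg.n_trials)
                         * rng.lognormal(0.0, cfg.local_amp_jitter_sigma,
                                         cfg.n_trials)) for r in regions}
    # center jitter is independent per region so the "local" latents carry
    # little moment-to-moment cross-region correlation beyond event locking
    region_jit = {r: rng.normal(0.0, cfg.center_jitter_sd_s, cfg.n_trials)
                  for r in regions}
    local_lag = {"M2": 0.0, "M1": cfg.local_lag_ms / 1000.0}
    shared_lag = {"M2": 0.0, "M1": cfg.shared_lag_ms / 1000.0}
    suppress = {"M2": cfg.m2_suppression if stage == "perturbed" else 1.0,
                "M1": 1.0}

    centers = pd.DataFrame({
        "trial_id": trials["trial_id"],
        "shared_center_M2_s": reach_starts,
        "shared_center_M1_s": reach_starts + shared_lag["M1"],
        "local_center_M2_s": reach_starts + region_jit["M2"],
        "local_center_M1_s": reach_starts + local_lag["M1"] + region_jit["M1"],
    })

    t_end = float(trials["grasp_onset_s"].iloc[-1]) + 3.0 + cfg.iti_s
    dead = cfg.dead_time_ms / 1000.0
    clipped = False

    units: dict[str, list[np.ndarray]] = {}
    for r in regions:
        n_u = cfg.n_units[r]
        base = baseline[r]
        per_unit: list[list[np.ndarray]] = [[] for _ in range(n_u)]

        # homogeneous baseline spikes outside the per-trial modulation windows
        windows = np.column_stack([reach_starts + _MOD_PAD[0],
                                   reach_starts + _MOD_PAD[1]])
        for u in range(n_u):
            n_sp = rng.poisson(base[u] * t_end)
            sp = np.sort(rng.uniform(0.0, t_end, n_sp))
            inside = np.zeros(len(sp), dtype=bool)
            for lo, hi in windows:
                inside |= (sp >= lo) & (sp < hi)
            per_unit[u].append(sp[~inside])

        # inhomogeneous spikes inside each trial's modulation window
        for i in range(cfg.n_trials):
            lo = reach_starts[i] + _MOD_PAD[0]
            hi = reach_starts[i] + _MOD_PAD[1]
            grid = np.arange(lo, hi, _FINE_DT)
            sig_z = cfg.kernel_width_s * durations[i] / cfg.ref_duration_s
            cz = centers[f"shared_center_{r}_s"].iloc[i]
            z = np.exp(-0.5 * ((grid - cz) / sig_z) ** 2)
            cl = centers[f"local_center_{r}_s"].iloc[i]
            l_r = (cfg.local_amplitude[r] * local_amp_jit[r][i]
                   * np.exp(-0.5 * ((grid - cl) / cfg.local_kernel_width_s) ** 2))
            drive = suppress[r] * (
                np.outer(a_trial[i] * z, w_shared[r][:, 0])
                + np.outer(l_r, w_local[r]))
            if cfg.shared_dim > 1:    # extra shared bumps, staggered in time
                for j in range(1, cfg.shared_dim):
                    zj = np.exp(-0.5 * ((grid - cz - 0.3 * j) / sig_z) ** 2)
                    drive += suppress[r] * np.outer(
                        a_trial[i] * zj, w_shared[r][:, j])
            rate = base[None, :] * np.exp(drive)
            if np.any(rate > cfg.lambda_max_hz):
                clipped = True
                rate = np.minimum(rate, cfg.lambda_max_hz)
            n_sp = rng.poisson(rate * _FINE_DT)
            for u in range(n_u):
                idx = np.nonzero(n_sp[:, u])[0]
                if idx.size == 0:
                    continue
                reps = n_sp[idx, u]
                times = (np.repeat(grid[idx], reps)
                         + rng.uniform(0.0, _FINE_DT, int(reps.sum())))
                per_unit[u].append(times)

        merged = []
        for u in range(n_u):
            sp = np.sort(np.concatenate(per_unit[u]))
            if sp.size > 1:                      # 1 ms dead time
                keep = np.concatenate([[True], np.diff(sp) >= dead])
                sp = sp[keep]
            merged.append(sp)
        units[r] = merged

    if clipped:
        warnings.warn("firing rate clipped at lambda_max", RuntimeWarning)

    session = SessionData(regions=regions, units=units, trials=trials,
                          animal_id=f"sim{cfg.seed}", stage=stage,
                          meta={"t_end": t_end})
    truth = SyntheticGroundTruth(
        w_shared=w_shared, w_local=w_local, baseline_hz=baseline,
        shared_amp_per_trial=a_trial, local_lag_ms=cfg.local_lag_ms,
        shared_lag_ms=cfg.shared_lag_ms, beta=cfg.beta,
        latent_centers_s=centers)
    return session, truth


def planted_axis_angle(truth: SyntheticGroundTruth, model,
                       region: str) -> float:
    """Angle (degrees) between the fitted top-CV axis and the planted
    shared loading vector for ``region``; in [0, 90]."""
    from .cca import subspace_angle   # local import to avoid cycle
    w_fit = model.weights[region][:, 0]
    w_true = truth.w_shared[region][:, 0]
    if w_fit.shape != w_true.shape:
        raise ValueError("dimension mismatch between fit and ground truth")
    return subspace_angle(w_fit[:, None], w_true[:, None])
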