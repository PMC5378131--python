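"""Batch experiment protocols.

All experiments share one RNG discipline: a master seed spawns one 31-bit
seed per trial; each trial's generator is consumed in a fixed order
(fibrosis sampling first, then the per-step burst draws), so any trial can
be replayed bit-exactly from its recorded seed — the storage format for
sample paths is the seed, not the state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .automaton import Automaton
from .classifiers import EpisodeRecord
from .geometry import AtrialMesh, build_substrate, sample_fibrosis
from .params import ModelParams

OBSERVE_S = 10.0          # post-burst observation window


def trial_seeds(master_seed: int, n: int) -> np.ndarray:
    """n reproducible 31-bit trial seeds derived from a master seed."""
    return np.random.default_rng(master_seed).integers(0, 2**31, size=n)


def _fresh_trial(mesh: AtrialMesh, params: ModelParams, seed: int,
                 engine: str = "numba") -> Automaton:
    """Resample fibrosis and build an automaton, both from one trial seed."""
    rng = np.random.default_rng(int(seed))
    sample_fibrosis(mesh, params.fc, rng, params)
    return Automaton(mesh, params, seed=rng, engine=engine)


# ---------------------------------------------------------------------------
# initiation probability vs burst duration
# ---------------------------------------------------------------------------

def run_initiation_trial(mesh: AtrialMesh, params: ModelParams,
                         burst_s: float, seed: int,
                         observe_s: float = OBSERVE_S,
                         engine: str = "numba"
                         ) -> Tuple[EpisodeRecord, Automaton]:
    """One trial of the initiation protocol: sinus throughout, PV bursts for
    ``burst_s`` seconds, then a quiet observation window; the verdict is
    classifier A (activity never zero during observation)."""
    auto = _fresh_trial(mesh, params, seed, engine)
    auto.advance(burst_s, bursts=True)
    obs = auto.advance(observe_s, bursts=False, stop_on_zero=True)
    sustained = obs.stop_reason is None   # survived the window without a zero
    rec = EpisodeRecord(seed=int(seed), sustained=sustained,
                        burst_window_s=(0.0, burst_s))
    return rec, auto


def initiation_experiment(params: ModelParams,
                          burst_durations: Sequence[float],
                          n_paths: int, seed: int,
                          mesh: Optional[AtrialMesh] = None,
                          level: int = 5,
                          observe_s: float = OBSERVE_S
                          ) -> Tuple[pd.DataFrame, List[EpisodeRecord]]:
    """Re-entry probability as a function of PV burst duration.

    Each (duration, path) trial uses a fresh fibrosis realization and burst
    stream.  Returns a table (duration_s, n, k, probability) and the
    per-trial episode records; fully determined by (params, seed).
    """
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    mesh = mesh if mesh is not None else build_substrate(params, level)
    rows, records = [], []
    for di, T in enumerate(burst_durations):
        seeds = trial_seeds(seed + di, n_paths)
        k = 0
        for s in seeds:
            if T == 0:
                rec = EpisodeRecord(seed=int(s), sustained=False,
                                    burst_window_s=(0.0, 0.0),
                                    notes="zero-duration burst")
            else:
                rec, _ = run_initiation_trial(mesh, params, T, s, observe_s)
            records.append(rec)
            k += bool(rec.sustained)
        rows.append({"duration_s": float(T), "n": n_paths, "k": k,
                     "probability": k / n_paths})
    return pd.DataFrame(rows), records


# ---------------------------------------------------------------------------
# onset-time survival
# ---------------------------------------------------------------------------

def onset_survival(params: ModelParams, horizon_s: float, n_paths: int,
                   seed: int, mesh: Optional[AtrialMesh] = None,
                   level: int = 5) -> Tuple[np.ndarray, List[EpisodeRecord]]:
    """Onset times tau of the dynamic classifier under continuous bursting.

    Returns one tau per path (inf when censored at the horizon) from which
    the empirical survival s(t) = Prob[tau > t] follows; right-censored
    paths count as tau > horizon.
    """
    mesh = mesh if mesh is not None else build_substrate(params, level)
    taus = np.full(n_paths, np.inf)
    records = []
    for i, s in enumerate(trial_seeds(seed, n_paths)):
        auto = _fresh_trial(mesh, params, s)
        res = auto.advance(horizon_s, bursts=True, stop_on_onset=True)
        tau = auto.time_s if res.stop_reason == "onset" else None
        if tau is not None:
            taus[i] = tau
        records.append(EpisodeRecord(seed=int(s), tau_s=tau,
                                     burst_window_s=(0.0, horizon_s)))
    return taus, records


# ---------------------------------------------------------------------------
# classifier agreement
# ---------------------------------------------------------------------------

def classifier_agreement(params: ModelParams, n_detected: int, seed: int,
                         mesh: Optional[AtrialMesh] = None, level: int = 5,
                         max_horizon_s: float = 300.0,
                         observe_s: float = OBSERVE_S,
                         max_trials: Optional[int] = None
                         ) -> Tuple[float, List[EpisodeRecord]]:
    """Fraction of dynamic-classifier detections confirmed as re-entry.

    Trials run with continuous bursts until the onset classifier fires; at
    tau the bursts are switched off and the system evolves for ``observe_s``
    with sinus pacing; the detection is confirmed if classifier A holds.
    """
    if n_detected < 1:
        raise ValueError("need at least one detection")
    mesh = mesh if mesh is not None else build_substrate(params, level)
    max_trials = max_trials or n_detected * 50
    confirmed, records = 0, []
    detections = 0
    for s in trial_seeds(seed, max_trials):
        auto = _fresh_trial(mesh, params, s)
        res = auto.advance(max_horizon_s, bursts=True, stop_on_onset=True)
        if res.stop_reason != "onset":
            continue
        tau = auto.time_s
        obs = auto.advance(observe_s, bursts=False, stop_on_zero=True)
        ok = obs.stop_reason is None
        confirmed += ok
        detections += 1
        records.append(EpisodeRecord(seed=int(s), sustained=ok, tau_s=tau))
        if detections >= n_detected:
            break
    if detections == 0:
        raise RuntimeError("no onsets detected within the trial budget")
    return confirmed / detections, records


# ---------------------------------------------------------------------------
# two-burst termination probe
# ---------------------------------------------------------------------------

@dataclass
class TerminationConfig:
    """Protocol of the termination probe (durations in seconds)."""

    t1_s: float = 1.0
    t2_values: Tuple[float, ...] = (0.5, 1, 2, 4, 6, 8, 10)
    second_burst_s: float = 1.0
    observe_s: float = 10.0
    repeats: int = 50
    n_paths: int = 500

    def __post_init__(self):
        for name in ("t1_s", "second_burst_s", "observe_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(t2 <= 0 for t2 in self.t2_values):
            raise ValueError("waiting windows must be positive")


@dataclass
class TerminationResult:
    matrix: pd.DataFrame          # rows: sample paths; columns: T2 values
    aggregate: float              # overall termination probability
    pool_seeds: List[int]
    trials_used: int              # trials consumed to build the AF pool


def replay_to_branch(mesh: AtrialMesh, params: ModelParams, seed: int,
                     t1_s: float) -> Automaton:
    """Recreate a sample path from its seed up to first-burst offset."""
    auto = _fresh_trial(mesh, params, seed)
    auto.advance(t1_s, bursts=True)
    return auto


def termination_experiment(params: ModelParams, cfg: TerminationConfig,
                           seed: int, mesh: Optional[AtrialMesh] = None,
                           level: int = 5,
                           max_pool_trials: Optional[int] = None
                           ) -> TerminationResult:
    """Second-burst termination probe.

    A pool of AF sample paths is collected by running the initiation
    protocol with first-burst duration T1 and keeping paths whose activity
    stays nonzero through the observation window.  Each pooled path is
    replayed from its seed to the first-burst offset (state hash checked
    against the one recorded at pool time), then branched: wait T2 without
    bursts, apply a 1 s burst, observe; terminated iff the post-burst
    observation is not sustained.
    """
    mesh = mesh if mesh is not None else build_substrate(params, level)
    max_pool_trials = max_pool_trials or cfg.n_paths * 500
    pool: List[Tuple[int, str]] = []
    trials = 0
    for s in trial_seeds(seed, max_pool_trials):
        trials += 1
        auto = _fresh_trial(mesh, params, s)
        auto.advance(cfg.t1_s, bursts=True)
        branch_hash = auto.state_hash()
        obs = auto.advance(cfg.observe_s, bursts=False, stop_on_zero=True)
        if obs.stop_reason is None:          # still in re-entry: pool it
            pool.append((int(s), branch_hash))
        if len(pool) >= cfg.n_paths:
            break
    if not pool:
        raise RuntimeError(
            f"no AF sample paths found in {trials} trials at T1 = {cfg.t1_s} s")

    probe_rng = np.random.default_rng(seed + 7)
    rows = []
    for path_id, (s, recorded_hash) in enumerate(pool):
        auto = replay_to_branch(mesh, params, s, cfg.t1_s)
        if auto.state_hash() != recorded_hash:
            raise RuntimeError(
                f"seed replay of path {path_id} diverged from the recorded state")
        snap = auto.snapshot()
        row = {}
        for t2 in cfg.t2_values:
            terminated = 0
            for _ in range(cfg.repeats):
                auto.restore(snap)
                auto.reseed(int(probe_rng.integers(0, 2**31)))
                auto.advance(t2, bursts=False)
                auto.advance(cfg.second_burst_s, bursts=True)
                obs = auto.advance(cfg.observe_s, bursts=False,
                                   stop_on_zero=True)
                terminated += obs.stop_reason is not None
            row[t2] = terminated / cfg.repeats
        rows.append(row)
    matrix = pd.DataFrame(rows)
    matrix.index.name = "path"
    return TerminationResult(matrix=matrix,
                             aggregate=float(matrix.to_numpy().mean()),
                             pool_seeds=[s for s, _ in pool],
                             trials_used=trials)
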