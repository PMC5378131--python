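"""Discrete-time multi-state excitation engine.

Each node carries an integer countdown state (0 = rest, >0 = activated); a
resting node is excited when at least ``threshold`` neighbours within the
interaction radius were activated in the past ``recent_window`` steps
(10 ms).  On excitation the node's refractory period is recomputed from its
diastolic interval through the restitution curve and the state is set to
that RP; activated nodes count down by one per step.  Sinus pacing excites
the resting part of the sinus-node disc every second; pulmonary-vein bursts
fire a random annulus group with per-step probability p = BR/400.

Two engines share identical semantics: a compiled kernel
(:mod:`afca._engine`) used for production runs, and :func:`step_reference`,
a transparent numpy implementation used for unit testing and as an
independent cross-check; both consume the same per-step uniform draws.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import _engine
from .geometry import AtrialMesh
from .params import ModelParams, STEPS_PER_SECOND, DT_S

INIT_NEG = _engine.INIT_NEG


# ---------------------------------------------------------------------------
# restitution
# ---------------------------------------------------------------------------

def restitution_rp(di, b: float, k: float, *, rp_scale: float = 121.0,
                   rp_min: int = 64, rp_max: int = 120):
    """Refractory period (steps) after a diastolic interval ``di`` (steps).

    RP = clamp(floor(rp_scale * (1 - B * exp(-DI/K))), rp_min, rp_max).
    The scale factor 121 with the floor gives a maximal RP of 120 steps
    (300 ms); the clamp enforces the 64-step (160 ms) physiological minimum.
    Monotone non-decreasing in DI for B > 0.  Accepts scalars or arrays.
    """
    di = np.asarray(di, dtype=np.float64)
    val = np.floor(rp_scale * (1.0 - b * np.exp(-di / k)))
    rp = np.clip(val, rp_min, rp_max).astype(np.int64)
    return int(rp) if rp.ndim == 0 else rp


def restitution_rp_with_memory(rp_prev, di, alpha: float, b: float, k: float,
                               *, rp_scale: float = 121.0,
                               rp_min: int = 64, rp_max: int = 120):
    """Restitution with memory: a convex blend of the previous RP and the
    instantaneous restitution target.

    RP = clamp(floor(alpha * RP_prev + (1-alpha) * rp_scale*(1 - B e^{-DI/K}))).
    alpha = 0 reproduces :func:`restitution_rp`; alpha = 1 freezes RP_prev
    (no restitution).
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    rp_prev = np.asarray(rp_prev, dtype=np.float64)
    di = np.asarray(di, dtype=np.float64)
    target = rp_scale * (1.0 - b * np.exp(-di / k))
    val = np.floor(alpha * rp_prev + (1.0 - alpha) * target)
    rp = np.clip(val, rp_min, rp_max).astype(np.int64)
    return int(rp) if rp.ndim == 0 else rp


# ---------------------------------------------------------------------------
# signals and state
# ---------------------------------------------------------------------------

@dataclass
class ActivitySignal:
    """Fraction of activated non-fibrotic, non-hole nodes, one sample per
    2.5 ms step.  Sample k of a signal starting at ``t0_s`` is assigned time
    t0_s + (k+1) * dt."""

    values: np.ndarray
    dt_s: float = DT_S
    t0_s: float = 0.0

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return self.t0_s + (np.arange(len(self.values)) + 1) * self.dt_s

    def window(self, t_start: float, t_end: float) -> "ActivitySignal":
        """Sub-signal with t_start < t <= t_end."""
        t = self.times
        sel = (t > t_start + 1e-12) & (t <= t_end + 1e-12)
        if not sel.any():
            raise ValueError("empty window")
        first = int(np.argmax(sel))
        return ActivitySignal(self.values[sel], self.dt_s,
                              t0_s=float(t[first]) - self.dt_s)

    @staticmethod
    def concat(parts: Sequence["ActivitySignal"]) -> "ActivitySignal":
        if not parts:
            return ActivitySignal(np.empty(0))
        return ActivitySignal(np.concatenate([p.values for p in parts]),
                              parts[0].dt_s, parts[0].t0_s)


@dataclass
class AutomatonState:
    """Per-node dynamic state plus the bookkeeping the engine needs."""

    state: np.ndarray        # int32 countdown, 0 = rest
    last_act: np.ndarray     # int64 step of last activation
    last_rest: np.ndarray    # int64 step of last return to rest
    rp: np.ndarray           # int32 current RP
    t: int = 0               # global step counter
    onset_runlen: int = 0    # consecutive steps with activity > 0.5
    ring_nodes: Optional[np.ndarray] = None
    ring_len: Optional[np.ndarray] = None
    ring_steps: Optional[np.ndarray] = None

    def copy(self) -> "AutomatonState":
        return AutomatonState(
            self.state.copy(), self.last_act.copy(), self.last_rest.copy(),
            self.rp.copy(), self.t, self.onset_runlen,
            None if self.ring_nodes is None else self.ring_nodes.copy(),
            None if self.ring_len is None else self.ring_len.copy(),
            None if self.ring_steps is None else self.ring_steps.copy())


def initial_state(mesh: AtrialMesh, params: ModelParams,
                  rng=None) -> AutomatonState:
    """All nodes at rest with effectively infinite preceding quiescence, so
    the first excitation of any node assigns the maximal RP.  With
    ``params.heterogeneous_init`` the stored RPs start uniform in
    [rp_min, rp_max] instead of at rp_max."""
    n = mesh.n_nodes
    if params.heterogeneous_init:
        rng = np.random.default_rng(rng)
        rp = rng.integers(params.rp_min, params.rp_max + 1, n).astype(np.int32)
    else:
        rp = np.full(n, params.rp_max, np.int32)
    w = params.recent_window
    return AutomatonState(
        state=np.zeros(n, np.int32),
        last_act=np.full(n, INIT_NEG, np.int64),
        last_rest=np.full(n, INIT_NEG, np.int64),
        rp=rp,
        t=0,
        ring_nodes=np.zeros((w, n), np.int32),
        ring_len=np.zeros(w, np.int64),
        ring_steps=np.full(w, INIT_NEG, np.int64),
    )


# ---------------------------------------------------------------------------
# reference (numpy) single step
# ---------------------------------------------------------------------------

def _recent_counts(state: AutomatonState, mesh: AtrialMesh,
                   params: ModelParams) -> np.ndarray:
    """Number of neighbours of each node activated in the past window,
    computed directly from the timestamps (no ring buffer)."""
    age = state.t - state.last_act
    recent = (age >= 1) & (age <= params.recent_window)
    cnt = np.zeros(mesh.n_nodes, np.int64)
    src = np.repeat(np.arange(mesh.n_nodes), np.diff(mesh.indptr))
    np.add.at(cnt, mesh.indices[recent[src]], 1)
    return cnt


def _excite(state: AutomatonState, params: ModelParams,
            nodes: np.ndarray) -> None:
    di = (state.t - state.last_rest[nodes]).astype(np.float64)
    target = params.rp_scale * (1.0 - params.b * np.exp(-di / params.k))
    if params.alpha > 0.0:
        target = params.alpha * state.rp[nodes] + (1.0 - params.alpha) * target
    rp = np.clip(np.floor(target), params.rp_min, params.rp_max).astype(np.int32)
    state.state[nodes] = rp
    state.rp[nodes] = rp
    state.last_act[nodes] = state.t


def fire_sinus(state: AutomatonState, mesh: AtrialMesh,
               params: ModelParams) -> np.ndarray:
    """Mark the resting part of the SN disc for excitation this step.

    Refractory SN nodes are untouched — sinus pacing never overrides
    refractoriness, which is what lets established re-entry suppress
    capture.  Returns the marked node indices (the caller applies them
    together with the other stimuli for synchronous semantics).
    """
    sn = mesh.sn_nodes
    ok = mesh.excitable[sn] & (state.state[sn] == 0)
    return sn[ok]


def fire_pv_burst(state: AutomatonState, mesh: AtrialMesh,
                  params: ModelParams, coin: float, loc_u: float) -> np.ndarray:
    """Marked nodes for a PV burst given the step's two uniform draws.

    With probability p one annulus node is chosen uniformly; it and its
    burst group fire to their (restitution-updated) maximal state.  Under
    ``burst_overrides_refractory`` group members are re-set regardless of
    their current state.
    """
    if params.p <= 0.0 or coin >= params.p:
        return np.empty(0, np.int64)
    na = mesh.annulus_nodes.shape[0]
    j = min(int(loc_u * na), na - 1)
    grp = mesh.group_indices[mesh.group_indptr[j]:mesh.group_indptr[j + 1]]
    ok = mesh.excitable[grp]
    if not params.burst_overrides_refractory:
        ok &= state.state[grp] == 0
    return grp[ok].astype(np.int64)


def step_reference(state: AutomatonState, mesh: AtrialMesh,
                   params: ModelParams, *, sinus: bool = False,
                   burst_draw: Optional[Tuple[float, float]] = None) -> int:
    """One synchronous update (numpy reference engine).  Returns the number
    of activated excitable nodes after the step."""
    t = state.t
    marked = np.zeros(mesh.n_nodes, bool)
    if sinus and t % params.sinus_period_steps == 0:
        marked[fire_sinus(state, mesh, params)] = True
    if burst_draw is not None:
        marked[fire_pv_burst(state, mesh, params, *burst_draw)] = True
    cnt = _recent_counts(state, mesh, params)
    bulk = mesh.excitable & (state.state == 0) & (cnt >= params.threshold)
    marked |= bulk
    exc = np.flatnonzero(marked)
    # countdowns first (reads pre-step state), then excitations
    down = ~marked & (state.state > 0)
    state.state[down] -= 1
    newly_rested = down & (state.state == 0)
    state.last_rest[newly_rested] = t
    if exc.size:
        _excite(state, params, exc)
    if state.ring_nodes is not None:  # keep the kernel's ring buffer coherent
        slot = t % params.recent_window
        state.ring_nodes[slot, :exc.size] = exc
        state.ring_len[slot] = exc.size
        state.ring_steps[slot] = t
    state.t = t + 1
    return int(np.count_nonzero(state.state[mesh.excitable]))


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

@dataclass
class AdvanceResult:
    signal: ActivitySignal
    steps: int
    stop_reason: Optional[str]       # None | "zero" | "onset"


@dataclass
class Phase:
    """One schedule segment: ``bursts`` switches the PV trigger on,
    ``sinus`` the 1 Hz pacing; the stop flags enable early exit."""
    duration_s: float
    bursts: bool = False
    sinus: bool = True
    stop_on_zero: bool = False
    stop_on_onset: bool = False
    label: str = ""


_STOP_NAMES = {_engine.STOP_NONE: None, _engine.STOP_ZERO: "zero",
               _engine.STOP_ONSET: "onset"}


class Automaton:
    """Stateful simulator bound to one substrate realization.

    The RNG stream is consumed in a fixed order (two uniforms per step when
    bursts are enabled), so a (mesh, params, seed, schedule) tuple fully
    determines the trajectory.
    """

    def __init__(self, mesh: AtrialMesh, params: ModelParams,
                 seed=None, engine: str = "numba"):
        if mesh.indptr is None:
            raise ValueError("mesh needs a neighbour map; call build_neighbour_map")
        if mesh.sn_nodes is None:
            raise ValueError("mesh needs functional regions; call mark_functional_regions")
        if engine not in ("numba", "python"):
            raise ValueError(f"unknown engine {engine!r}")
        self.mesh = mesh
        self.params = params
        self.engine = engine
        self.rng = np.random.default_rng(seed)
        self.state = initial_state(mesh, params, rng=self.rng)
        self.excitable = mesh.excitable.copy()
        self.n_signal = int(self.excitable.sum())

    @property
    def time_s(self) -> float:
        return self.state.t * self.params.dt_s

    # -- snapshots --------------------------------------------------------
    def snapshot(self) -> dict:
        return {"state": self.state.copy(),
                "region": self.mesh.region.copy(),
                "rng": self.rng.bit_generator.state}

    def restore(self, snap: dict) -> None:
        self.state = snap["state"].copy()
        self.mesh.region[:] = snap["region"]
        self.excitable = self.mesh.excitable.copy()
        self.n_signal = int(self.excitable.sum())
        self.rng = np.random.default_rng()
        self.rng.bit_generator.state = snap["rng"]

    def reseed(self, seed) -> None:
        """Replace the RNG stream (used to branch probe simulations)."""
        self.rng = np.random.default_rng(seed)

    def state_hash(self) -> str:
        h = hashlib.sha1()
        s = self.state
        for arr in (s.state, s.last_act, s.last_rest, s.rp):
            h.update(np.ascontiguousarray(arr).tobytes())
        h.update(np.int64(s.t).tobytes())
        h.update(self.mesh.region.tobytes())
        return h.hexdigest()

    def inject_excitation(self, nodes) -> None:
        """Externally excite ``nodes`` as one synchronous step at the current
        time (used e.g. to launch a wavefront from a polar disc).  Their RP
        follows the restitution rule from their own timestamps and they count
        as recently excited for the following steps."""
        nodes = np.asarray(nodes, dtype=np.int64)
        nodes = nodes[self.excitable[nodes]]
        t = self.state.t
        _excite(self.state, self.params, nodes)
        slot = t % self.params.recent_window
        self.state.ring_nodes[slot, :nodes.size] = nodes
        self.state.ring_len[slot] = nodes.size
        self.state.ring_steps[slot] = t
        self.state.t = t + 1

    # -- time stepping ----------------------------------------------------
    def advance(self, duration_s: float, *, bursts: bool = False,
                sinus: bool = True, stop_on_zero: bool = False,
                stop_on_onset: bool = False,
                onset_threshold: float = 0.5,
                onset_hold_s: float = 2.0) -> AdvanceResult:
        n_steps = int(round(duration_s * STEPS_PER_SECOND))
        p = self.params.p if bursts else 0.0
        if p > 0.0:
            rand2 = self.rng.random((n_steps, 2))
        else:
            rand2 = np.zeros((n_steps, 2))
        t0 = self.state.t
        onset_hold = int(round(onset_hold_s * STEPS_PER_SECOND)) + 1
        activity = np.empty(n_steps)
        if self.engine == "numba":
            s = self.state
            done, code, runlen = _engine.run_phase(
                s.state, s.last_act, s.last_rest, s.rp,
                self.excitable, self.mesh.indptr, self.mesh.indices,
                self.mesh.sn_nodes, self.mesh.annulus_nodes,
                self.mesh.group_indptr, self.mesh.group_indices,
                t0, n_steps, sinus, self.params.sinus_period_steps,
                p, self.params.burst_overrides_refractory,
                rand2,
                self.params.b, self.params.k, self.params.alpha,
                self.params.rp_scale, self.params.rp_min, self.params.rp_max,
                self.params.threshold, self.params.recent_window,
                s.ring_nodes, s.ring_len, s.ring_steps,
                self.n_signal, activity,
                stop_on_zero, stop_on_onset, onset_threshold, onset_hold,
                s.onset_runlen)
            s.t = t0 + done
            s.onset_runlen = runlen
        else:
            done, code, runlen = self._advance_python(
                n_steps, rand2, p, sinus, activity, stop_on_zero,
                stop_on_onset, onset_threshold, onset_hold)
        sig = ActivitySignal(activity[:done], t0_s=t0 * self.params.dt_s)
        return AdvanceResult(sig, done, _STOP_NAMES[code])

    def _advance_python(self, n_steps, rand2, p, sinus, activity,
                        stop_on_zero, stop_on_onset, onset_threshold,
                        onset_hold):
        runlen = self.state.onset_runlen
        done, code = 0, _engine.STOP_NONE
        for kk in range(n_steps):
            draw = tuple(rand2[kk]) if p > 0.0 else None
            active = step_reference(self.state, self.mesh, self.params,
                                    sinus=sinus, burst_draw=draw)
            frac = active / self.n_signal
            activity[kk] = frac
            done = kk + 1
            runlen = runlen + 1 if frac > onset_threshold else 0
            if stop_on_onset and runlen >= onset_hold:
                code = _engine.STOP_ONSET
                break
            if stop_on_zero and active == 0:
                code = _engine.STOP_ZERO
                break
        self.state.onset_runlen = runlen
        return done, code, runlen

    def run_schedule(self, phases: Sequence[Phase]) -> Tuple[ActivitySignal,
                                                             List[AdvanceResult]]:
        parts, results = [], []
        for ph in phases:
            res = self.advance(ph.duration_s, bursts=ph.bursts, sinus=ph.sinus,
                               stop_on_zero=ph.stop_on_zero,
                               stop_on_onset=ph.stop_on_onset)
            parts.append(res.signal)
            results.append(res)
            if res.stop_reason is not None:
                break
        full = ActivitySignal(np.concatenate([p.values for p in parts]))
        return full, results


def run(mesh: AtrialMesh, params: ModelParams, schedule: Sequence[Phase],
        seed=None, engine: str = "numba") -> Tuple[ActivitySignal, Automaton,
                                                   List[AdvanceResult]]:
    """Run a full schedule from the all-rest initial condition.

    Returns the recorded activity signal, the automaton (whose state is the
    final state) and the per-phase results.  Bit-reproducible for a given
    (mesh, params, schedule, seed).
    """
    auto = Automaton(mesh, params, seed=seed, engine=engine)
    signal, results = auto.run_schedule(schedule)
    return signal, auto, results
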