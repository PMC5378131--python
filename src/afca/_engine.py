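"""Compiled inner loop of the cellular automaton.

One synchronous update per step, in stimulus order sinus -> PV burst ->
bulk threshold rule, followed by countdown decrement.  All threshold tests
read the previous step's activation timestamps; the per-step "recently
excited" neighbour counts are rebuilt from a ring buffer of the last
``window`` activation lists, which is exactly equivalent to scanning
``1 <= t - last_activation <= window`` but touches only wavefront nodes.

The kernel and the pure-numpy reference step in :mod:`afca.automaton`
implement identical semantics and consume the same pre-generated per-step
uniforms (burst coin, burst location), so trajectories are bit-identical
between the two engines and fully reproducible from a seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# stop codes returned by run_phase
STOP_NONE = 0
STOP_ZERO = 1      # activity reached zero (observation early exit)
STOP_ONSET = 2     # onset-classifier hold satisfied

INIT_NEG = -1_000_000  # "long before t=0" timestamp


@njit(cache=True)
def _restitution(di: float, rp_prev: float, b: float, k: float, alpha: float,
                 rp_scale: float, rp_min: int, rp_max: int) -> int:
    val = rp_scale * (1.0 - b * np.exp(-di / k))
    if alpha > 0.0:
        val = alpha * rp_prev + (1.0 - alpha) * val
    r = int(np.floor(val))
    if r < rp_min:
        r = rp_min
    if r > rp_max:
        r = rp_max
    return r


@njit(cache=True)
def run_phase(state, last_act, last_rest, rp_arr,
              excitable, indptr, indices,
              sn_nodes, ann_nodes, grp_indptr, grp_indices,
              t_start, n_steps, sinus_on, sinus_period,
              p, burst_override,
              rand2,
              b, k, alpha, rp_scale, rp_min, rp_max, threshold, window,
              ring_nodes, ring_len, ring_steps,
              n_signal,
              activity_out,
              stop_on_zero, stop_on_onset, onset_thresh, onset_hold, runlen0):
    n = state.shape[0]
    cnt = np.zeros(n, np.int32)
    marked = np.zeros(n, np.uint8)
    exc = np.empty(n, np.int32)
    runlen = runlen0
    steps_done = 0
    stop_code = STOP_NONE
    for kk in range(n_steps):
        t = t_start + kk
        for i in range(n):
            cnt[i] = 0
            marked[i] = 0
        # neighbour counts of nodes activated in the past `window` steps
        for w in range(window):
            s_abs = ring_steps[w]
            d = t - s_abs
            if d >= 1 and d <= window:
                for q in range(ring_len[w]):
                    node = ring_nodes[w, q]
                    if last_act[node] == s_abs:  # not re-activated since
                        for jj in range(indptr[node], indptr[node + 1]):
                            cnt[indices[jj]] += 1
        m = 0
        # (i) sinus pacing: resting SN-disc nodes only (never overrides RP)
        if sinus_on and (t % sinus_period == 0):
            for si in range(sn_nodes.shape[0]):
                i = sn_nodes[si]
                if excitable[i] and state[i] == 0 and marked[i] == 0:
                    marked[i] = 1
                    exc[m] = i
                    m += 1
        # (ii) PV burst: one annulus node + its group, fired to maximal state
        if p > 0.0 and rand2[kk, 0] < p:
            na = ann_nodes.shape[0]
            j = int(rand2[kk, 1] * na)
            if j >= na:
                j = na - 1
            for gg in range(grp_indptr[j], grp_indptr[j + 1]):
                i = grp_indices[gg]
                if excitable[i] and marked[i] == 0 and (
                        burst_override or state[i] == 0):
                    marked[i] = 1
                    exc[m] = i
                    m += 1
        # (iii) bulk rule: resting nodes with >= threshold recent neighbours
        for i in range(n):
            if excitable[i] and state[i] == 0 and marked[i] == 0 \
                    and cnt[i] >= threshold:
                marked[i] = 1
                exc[m] = i
                m += 1
        # apply excitations and countdowns
        active = 0
        for i in range(n):
            if marked[i] == 1:
                di = float(t - last_rest[i])
                r = _restitution(di, float(rp_arr[i]), b, k, alpha,
                                 rp_scale, rp_min, rp_max)
                state[i] = r
                rp_arr[i] = r
                last_act[i] = t
            elif state[i] > 0:
                state[i] -= 1
                if state[i] == 0:
                    last_rest[i] = t
            if excitable[i] and state[i] > 0:
                active += 1
        slot = t % window
        for q in range(m):
            ring_nodes[slot, q] = exc[q]
        ring_len[slot] = m
        ring_steps[slot] = t
        frac = active / n_signal
        activity_out[kk] = frac
        steps_done = kk + 1
        if frac > onset_thresh:
            runlen += 1
        else:
            runlen = 0
        if stop_on_onset and runlen >= onset_hold:
            stop_code = STOP_ONSET
            break
        if stop_on_zero and active == 0:
            stop_code = STOP_ZERO
            break
    return steps_done, stop_code, runlen
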