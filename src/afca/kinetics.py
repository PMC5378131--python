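"""Coarse-grained stochastic kinetics of AF initiation and termination.

Under continuous pulmonary-vein bursting the automaton behaves, at the
episode level, like a two-state Markov chain SR <-> AF with initiation rate
r1 and inhibition/termination rate r2; starting from sinus rhythm the AF
occupancy follows the telegraph-process solution

    P_AF(t) = r1/(r1+r2) * (1 - exp(-(r1+r2) t)),

whose small-t slope is r1 and whose plateau r1/(r1+r2) can sit below 1.
For physiologically short burst trains the chain is gated by a burst ON/OFF
process with rates k1 (OFF->ON) and k2 (ON->OFF); while bursts are OFF the
SR/AF state is frozen.  This module provides the closed form, the linear
and nonlinear rate fits, and an exact event-driven simulator of the gated
chain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class RateFit:
    """Fitted coarse-grained rates (1/s) with fit diagnostics."""

    r1: float
    r2: float = 0.0
    cov: Optional[np.ndarray] = None
    residual_norm: float = 0.0
    model: str = "linear"                 # "linear" | "two_state"
    ok: bool = True
    message: str = ""

    def __post_init__(self):
        if self.ok and (self.r1 < 0 or self.r2 < 0):
            raise ValueError("rates must be non-negative")


@dataclass
class CTMCParams:
    """Burst-gated two-stage chain parameters (all rates 1/s).

    1/k1 and 1/k2 are the mean durations of the burst-OFF and burst-ON
    windows; r1/r2 act only while bursts are ON.  Short burst trains mean
    k2 >> k1 (a usage note, not enforced).
    """

    k1: float
    k2: float
    r1: float
    r2: float

    def __post_init__(self):
        for name in ("k1", "k2", "r1", "r2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class MultiStateParams(CTMCParams):
    """Scaffold for the stable/unstable-AF extension of the chain.

    AF is split into an unstable mode (terminable by further PV bursts) and
    a stable one.  The inter-mode rates are deliberately left unquantified:
    estimating them needs a classifier for the AF sub-state, which the
    temporal activity signal alone does not provide.  The flag exists so
    episode records can carry a stability annotation.
    """

    stable_label: str = "AF_stable"
    unstable_label: str = "AF_unstable"


def af_probability(t, r1: float, r2: float):
    """P_AF(t) for the two-state chain started in sinus rhythm.

    P(0) = 0; plateau r1/(r1+r2); r2 = 0 reduces to 1 - exp(-r1 t); the
    r1 = r2 = 0 limit is identically zero.
    """
    t = np.asarray(t, dtype=np.float64)
    s = r1 + r2
    if s == 0.0:
        out = np.zeros_like(t)
    else:
        out = (r1 / s) * (1.0 - np.exp(-s * t))
    return float(out) if out.ndim == 0 else out


def _binomial_sigma(probs: np.ndarray, n_paths) -> Optional[np.ndarray]:
    """Binomial standard errors sqrt(p(1-p)/n) with a floor at the smallest
    nonzero error (keeps p in {0, 1} from getting infinite weight)."""
    if n_paths is None:
        return None
    n = np.broadcast_to(np.asarray(n_paths, float), probs.shape)
    var = probs * (1.0 - probs) / n
    sig = np.sqrt(var)
    pos = sig[sig > 0]
    floor = pos.min() if pos.size else 1.0 / np.sqrt(n.max())
    return np.maximum(sig, floor)


def fit_linear_rate(durations: Sequence[float], probabilities: Sequence[float],
                    n_paths=None) -> RateFit:
    """Slope through the origin of the short-duration linear response;
    r1 is the initiation rate of the constant-rate model."""
    T = np.asarray(durations, float)
    P = np.asarray(probabilities, float)
    if T.size < 2:
        raise ValueError("need at least two points")
    if np.any((P < 0) | (P > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    sig = _binomial_sigma(P, n_paths)
    w = 1.0 / sig**2 if sig is not None else np.ones_like(P)
    denom = float(np.sum(w * T * T))
    slope = float(np.sum(w * T * P)) / denom
    resid = P - slope * T
    if np.all(P == 0):
        return RateFit(0.0, 0.0, cov=np.array([[np.inf]]), residual_norm=0.0,
                       model="linear", ok=True,
                       message="all-zero probabilities; rate indeterminate")
    if sig is not None:
        # binomial errors are known: absolute-sigma slope variance
        var = 1.0 / denom
    else:
        var = float(np.sum(w * resid**2)) / max(T.size - 1, 1) / denom
    return RateFit(max(slope, 0.0), 0.0, cov=np.array([[var]]),
                   residual_norm=float(np.linalg.norm(resid)), model="linear")


def fit_two_state(durations: Sequence[float], probabilities: Sequence[float],
                  n_paths=None) -> RateFit:
    """Nonlinear least squares of :func:`af_probability` to burst-duration
    response data spanning beyond the linear regime."""
    T = np.asarray(durations, float)
    P = np.asarray(probabilities, float)
    if T.size < 2:
        raise ValueError("need at least two points for a two-parameter fit")
    if np.any((P < 0) | (P > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    sig = _binomial_sigma(P, n_paths)
    slope0 = max(fit_linear_rate(T[T <= T.min() * 2 + 1e-12],
                                 P[T <= T.min() * 2 + 1e-12], None).r1
                 if (T <= T.min() * 2 + 1e-12).sum() >= 2 else P.max() / T.max(),
                 1e-8)
    p0 = (slope0, slope0 * 1e-2)
    try:
        popt, pcov = curve_fit(af_probability, T, P, p0=p0, sigma=sig,
                               absolute_sigma=sig is not None,
                               bounds=([0.0, 0.0], [np.inf, np.inf]),
                               maxfev=20000, xtol=1e-14, ftol=1e-14)
    except RuntimeError as err:
        return RateFit(0.0, 0.0, model="two_state", ok=False,
                       message=f"fit did not converge: {err}")
    resid = P - af_probability(T, *popt)
    return RateFit(float(popt[0]), float(popt[1]), cov=pcov,
                   residual_norm=float(np.linalg.norm(resid)),
                   model="two_state")


# ---------------------------------------------------------------------------
# burst-gated two-stage chain
# ---------------------------------------------------------------------------

@dataclass
class CTMCTrajectory:
    """Piecewise-constant trajectory of (burst ON/OFF, SR/AF).

    ``times`` holds the event instants starting at 0 and ending at the
    horizon; ``burst_on[i]``/``in_af[i]`` are the states on
    [times[i], times[i+1]).
    """

    times: np.ndarray
    burst_on: np.ndarray
    in_af: np.ndarray
    horizon_s: float

    def occupancy_af(self) -> float:
        """Fraction of total time spent in AF."""
        dt = np.diff(self.times)
        return float(np.sum(dt * self.in_af[:-1]) / self.horizon_s)

    def holding_times(self, which: str) -> np.ndarray:
        """Completed holding times of the burst flag ("on" or "off")."""
        flag = self.burst_on.astype(bool)
        want = flag if which == "on" else ~flag
        dt = np.diff(self.times)
        out, acc, inside = [], 0.0, False
        for i in range(len(dt)):
            if want[i]:
                acc += dt[i]
                inside = True
            elif inside:
                out.append(acc)
                acc, inside = 0.0, False
        # drop the (censored) final interval if it runs into the horizon
        return np.asarray(out)


def simulate_two_stage_ctmc(ctmc: CTMCParams, horizon_s: float,
                            seed=None) -> CTMCTrajectory:
    """Exact event-driven simulation of the burst-gated chain.

    Burst flag flips OFF->ON at rate k1 and ON->OFF at rate k2; while ON the
    rhythm flips SR->AF at r1 and AF->SR at r2; while OFF the rhythm is
    frozen.  Starts at (OFF, SR).
    """
    if horizon_s <= 0:
        raise ValueError("horizon must be positive")
    rng = np.random.default_rng(seed)
    t, on, af = 0.0, False, False
    times, burst, rhythm = [0.0], [False], [False]
    while True:
        if on:
            rates = [ctmc.k2, ctmc.r2 if af else ctmc.r1]
        else:
            rates = [ctmc.k1, 0.0]
        total = sum(rates)
        if total == 0.0:
            break
        dt = rng.exponential(1.0 / total)
        if t + dt >= horizon_s:
            break
        t += dt
        if rng.random() * total < rates[0]:
            on = not on
        else:
            af = not af
        times.append(t)
        burst.append(on)
        rhythm.append(af)
    times.append(horizon_s)
    burst.append(on)
    rhythm.append(af)
    return CTMCTrajectory(np.asarray(times), np.asarray(burst, bool),
                          np.asarray(rhythm, bool), horizon_s)


def survival_curve(taus: Sequence[float], horizon_s: float):
    """Empirical survival s(t) = Prob[tau > t] of onset times.

    ``taus`` may contain inf/nan for right-censored paths (counted as
    tau > horizon).  Returns (event_times, s_values) with s evaluated just
    after each event; s(0) = 1 by construction.
    """
    taus = np.asarray(taus, float)
    n = taus.size
    finite = np.sort(taus[np.isfinite(taus)])
    finite = finite[finite <= horizon_s]
    s = 1.0 - np.arange(1, finite.size + 1) / n
    return finite, s


def log_linear_fit(taus: Sequence[float], horizon_s: float):
    """Regress log s(t) on t at the event times; returns (rate, r_squared).

    An exponential waiting time gives a straight line of slope -rate.  The
    last event (s = 0 when nothing is censored) is excluded from the log.
    """
    t_ev, s = survival_curve(taus, horizon_s)
    keep = s > 0
    t_ev, s = t_ev[keep], s[keep]
    if t_ev.size < 3:
        raise ValueError("too few events for a survival regression")
    y = np.log(s)
    A = np.vstack([t_ev, np.ones_like(t_ev)]).T
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    yhat = A @ coef
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return -float(coef[0]), r2
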