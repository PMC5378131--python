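"""Episode classifiers operating on the activity signal.

Two complementary definitions of "in AF" are used: a retrospective one
(classifier A: the active fraction never returns to zero over a post-burst
observation window — re-entry must be self-sustaining because sinus rhythm
alone leaves the tissue fully at rest between beats) and an online one
(classifier B: the active fraction exceeds 0.5 for more than 2 s, an
ECG-monitor-like criterion that yields a random onset time tau without
perturbing the automaton).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional, Tuple

import numpy as np

from .automaton import ActivitySignal


@dataclass
class EpisodeRecord:
    """Per-trial outcome: seed, verdicts and protocol context."""

    seed: int
    sustained: Optional[bool] = None          # classifier A at end of observation
    tau_s: Optional[float] = None             # classifier B onset time
    burst_window_s: Optional[Tuple[float, float]] = None
    terminated: Optional[bool] = None         # termination-probe verdict
    notes: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, line: str) -> "EpisodeRecord":
        d = json.loads(line)
        if d.get("burst_window_s") is not None:
            d["burst_window_s"] = tuple(d["burst_window_s"])
        return cls(**d)


def classify_sustained(signal: ActivitySignal,
                       window: Optional[Tuple[float, float]] = None) -> bool:
    """True iff the active fraction is strictly positive at every step of
    the window (whole signal if no window is given)."""
    sig = signal if window is None else signal.window(*window)
    if len(sig) == 0:
        raise ValueError("empty window")
    return bool(np.all(sig.values > 0.0))


def detect_onset(signal: ActivitySignal, threshold: float = 0.5,
                 hold_s: float = 2.0) -> Optional[float]:
    """Onset time tau of the first run of more than ``hold_s`` consecutive
    seconds with active fraction > ``threshold``; None if never satisfied.

    tau is the time at which the hold condition is first met (the end of
    the qualifying run), i.e. the first instant the classifier indicates AF.
    """
    tau, _ = detect_onset_details(signal, threshold, hold_s)
    return tau


def detect_onset_details(signal: ActivitySignal, threshold: float = 0.5,
                         hold_s: float = 2.0
                         ) -> Tuple[Optional[float], Optional[float]]:
    """(tau, run_start): onset time and the start of its qualifying run."""
    above = signal.values > threshold
    # strictly more than hold_s: need hold_steps + 1 consecutive samples
    need = int(round(hold_s / signal.dt_s)) + 1
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= need:
            t = signal.times
            return float(t[i]), float(t[i - run + 1])
    return None, None


def write_episodes(path, records) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(rec.to_json() + "\n")


def read_episodes(path):
    with open(path) as fh:
        return [EpisodeRecord.from_json(line) for line in fh if line.strip()]
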