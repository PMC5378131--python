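"""Spectral analysis, Mollweide projection and file plumbing.

The dominant Fourier mode of the active-fraction signal during re-entry
reflects the rotation period of the re-entrant wavefront (~5 Hz for a
single circuit at conduction velocity 0.5 m/s); a subdominant ~2.5 Hz mode
appears where tissue experiences 2:1 conduction block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .automaton import ActivitySignal
from .geometry import AtrialMesh, REGION_NAMES
from .kinetics import RateFit


# ---------------------------------------------------------------------------
# Fourier analysis
# ---------------------------------------------------------------------------

@dataclass
class SpectrumResult:
    freqs_hz: np.ndarray
    power: np.ndarray
    dominant_hz: float
    peaks_hz: np.ndarray            # local maxima above 5x median power,
                                    # strongest first (ties -> lower frequency)
    window_s: Tuple[float, float]


def fourier_spectrum(signal: ActivitySignal,
                     window: Optional[Tuple[float, float]] = None,
                     min_hz: float = 0.0) -> SpectrumResult:
    """Power spectrum of the mean-subtracted active fraction on a window.

    Rectangular window on the exact observation interval; the dominant
    frequency is the argmax of power excluding the zero-frequency bin.
    ``min_hz`` optionally restricts the dominant/peak search to a
    physiological band: on this geometry no re-entrant circuit can rotate
    slower than a great circle at 0.5 m/s (~3.8 Hz), so sub-2 Hz power is
    window-scale drift rather than a rotation mode.
    """
    sig = signal if window is None else signal.window(*window)
    x = np.asarray(sig.values, float)
    if x.size < 2:
        raise ValueError("window must contain at least 2 samples")
    if window is None:
        window = (float(sig.times[0] - sig.dt_s), float(sig.times[-1]))
    if window[1] - window[0] < 2.0 - 1e-9:
        raise ValueError("spectral window must span at least 2 s")
    x = x - x.mean()
    F = np.fft.rfft(x)
    power = np.abs(F) ** 2
    freqs = np.fft.rfftfreq(x.size, d=sig.dt_s)
    first = max(1, int(np.searchsorted(freqs, min_hz)))
    dom = int(np.argmax(power[first:]) + first)
    # peak extraction: local maxima above 5x the median nonzero-bin power
    thresh = 5.0 * np.median(power[1:])
    peaks = []
    for i in range(first, power.size - 1):
        if power[i] > thresh and power[i] >= power[i - 1] \
                and power[i] > power[i + 1]:
            peaks.append(i)
    peaks.sort(key=lambda i: (-power[i], freqs[i]))
    return SpectrumResult(freqs, power, float(freqs[dom]),
                          np.asarray([freqs[i] for i in peaks]), window)


# ---------------------------------------------------------------------------
# Mollweide projection
# ---------------------------------------------------------------------------

def mollweide(theta, phi, centre_phi: float = np.pi, radius: float = 1.0):
    """Equal-area Mollweide projection of (colatitude, azimuth).

    Centred by default on the posterior wall (phi = pi).  The auxiliary
    angle beta solves 2 beta + sin 2 beta = pi sin(latitude) by Newton
    iteration to |delta| < 1e-10.  Returns planar (x, y); the north pole
    maps to (0, sqrt(2) * radius) and the full sphere to an ellipse of area
    4 pi radius^2.
    """
    theta = np.asarray(theta, float)
    phi = np.asarray(phi, float)
    lat = np.pi / 2 - theta
    beta = np.arcsin(np.clip(np.sin(lat), -1, 1)).astype(float)
    target = np.pi * np.sin(lat)
    for _ in range(100):
        f = 2 * beta + np.sin(2 * beta) - target
        fp = 2 + 2 * np.cos(2 * beta)
        step = np.where(np.abs(fp) > 1e-12, f / np.where(fp == 0, 1, fp), 0.0)
        # poles: fp -> 0 but beta = +-pi/2 is already the exact solution
        at_pole = np.isclose(np.abs(np.sin(lat)), 1.0)
        step = np.where(at_pole, 0.0, step)
        beta = beta - step
        if np.all(np.abs(step) < 1e-10):
            break
    lam = np.mod(phi - centre_phi + np.pi, 2 * np.pi) - np.pi
    x = radius * (2 * np.sqrt(2) / np.pi) * lam * np.cos(beta)
    y = radius * np.sqrt(2) * np.sin(beta)
    return x, y


def plot_state(mesh: AtrialMesh, state_values: np.ndarray, path,
               centre_phi: float = np.pi) -> None:
    """Write a static Mollweide-projected scatter of the node states."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x, y = mollweide(mesh.theta, mesh.phi, centre_phi=centre_phi)
    fig, ax = plt.subplots(figsize=(8, 4))
    hole = mesh.is_hole
    ax.scatter(x[hole], y[hole], s=2, c="k")
    fib = mesh.is_fibrotic
    ax.scatter(x[fib], y[fib], s=2, c="r")
    act = mesh.excitable
    ax.scatter(x[act], y[act], s=2, c=state_values[act], cmap="viridis",
               vmin=0, vmax=120)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


# ---------------------------------------------------------------------------
# tables and round-trip IO
# ---------------------------------------------------------------------------

def node_table(mesh: AtrialMesh) -> pd.DataFrame:
    return pd.DataFrame({
        "node_id": np.arange(mesh.n_nodes),
        "theta": mesh.theta,
        "phi": mesh.phi,
        "x": mesh.xyz[:, 0], "y": mesh.xyz[:, 1], "z": mesh.xyz[:, 2],
        "region_label": [REGION_NAMES[int(r)] for r in mesh.region],
    })


def write_node_table(mesh: AtrialMesh, path) -> None:
    node_table(mesh).to_csv(path, index=False)


def read_node_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def edge_list(mesh: AtrialMesh) -> pd.DataFrame:
    """Neighbour map as an (i, j) edge list with i < j."""
    src = np.repeat(np.arange(mesh.n_nodes), np.diff(mesh.indptr))
    dst = mesh.indices
    keep = src < dst
    return pd.DataFrame({"i": src[keep], "j": dst[keep]})


def write_edge_list(mesh: AtrialMesh, path) -> None:
    edge_list(mesh).to_csv(path, index=False)


def read_edge_list(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_activity(signal: ActivitySignal, path) -> None:
    pd.DataFrame({"time_s": signal.times,
                  "active_fraction": signal.values}).to_csv(path, index=False)


def read_activity(path) -> ActivitySignal:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    dt = float(t[1] - t[0]) if len(t) > 1 else 0.0025
    return ActivitySignal(df["active_fraction"].to_numpy(), dt_s=dt,
                          t0_s=float(t[0]) - dt)


def write_fit(fit: RateFit, path, key: Optional[str] = None) -> None:
    """Rates as JSON, optionally keyed by the (FC, p, B, K) tuple string."""
    d = {"r1": fit.r1, "r2": fit.r2, "model": fit.model, "ok": fit.ok,
         "residual_norm": fit.residual_norm, "message": fit.message}
    if fit.cov is not None:
        d["cov"] = np.asarray(fit.cov).tolist()
    out = {key: d} if key else d
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2)


def read_fit(path, key: Optional[str] = None) -> RateFit:
    with open(path) as fh:
        d = json.load(fh)
    if key:
        d = d[key]
    cov = np.asarray(d["cov"]) if "cov" in d else None
    return RateFit(d["r1"], d["r2"], cov=cov,
                   residual_norm=d.get("residual_norm", 0.0),
                   model=d.get("model", "linear"), ok=d.get("ok", True),
                   message=d.get("message", ""))


def param_key(fc: int, p: float, b: float, k: float) -> str:
    """Table-style parameter key, e.g. '(300, 0.05, 1, 40)'."""
    def fmt(x):
        return str(int(x)) if float(x).is_integer() else repr(float(x))
    return f"({fc}, {fmt(p)}, {fmt(b)}, {fmt(k)})"
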