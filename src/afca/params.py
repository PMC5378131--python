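"""Model parameters for the atrial cellular automaton.

All physical lengths are in millimetres on a sphere whose radius matches a
40 ml left atrium (21.2 mm); angles are radians on the unit sphere with
``theta`` the colatitude from the north pole (0 = north, pi = south) and
``phi`` in (-pi, pi].  Time is discretized in steps of 2.5 ms (400 steps per
second).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Tuple

PI = math.pi

#: steps per second at the 2.5 ms step
STEPS_PER_SECOND = 400
#: step duration in seconds
DT_S = 1.0 / STEPS_PER_SECOND


def physical_radius_from_volume(volume_ml: float) -> float:
    """Radius (mm) of a sphere with the given volume (ml).

    r = (3V / 4 pi)^(1/3); 1 ml = 1000 mm^3, so 40 ml gives 21.2 mm, the
    dimension used for the left-atrial sphere.
    """
    if volume_ml <= 0:
        raise ValueError(f"volume must be positive, got {volume_ml}")
    return (3.0 * volume_ml * 1000.0 / (4.0 * PI)) ** (1.0 / 3.0)


@dataclass
class ModelParams:
    """Cellular-automaton and physiology parameters.

    The defaults are the baseline conditions of the study: fibrosis count
    FC = 300 nodes, pulmonary-vein burst rate BR = 20 Hz (per-step burst
    probability p = BR/400), restitution steepness B = 1 and time constant
    K = 40 steps (100 ms).
    """

    # substrate severity / triggers
    fc: int = 300                       # number of fibrotic (inert) nodes
    br_hz: float = 20.0                 # continuous-time PV burst rate
    # restitution
    b: float = 1.0                      # steepness (dimensionless)
    k: float = 40.0                     # time constant (steps of 2.5 ms)
    rp_max: int = 120                   # 300 ms
    rp_min: int = 64                    # 160 ms, shortest physiological RP
    rp_scale: float = 121.0             # scale factor; floor gives max RP 120
    alpha: float = 0.0                  # restitution-memory weight (0 = none)
    # excitation rule
    threshold: int = 8                  # recently-excited neighbours needed
    interaction_radius_mm: float = 2.544
    recent_window: int = 4              # steps (10 ms)
    # pacing / triggers
    sinus_period_s: float = 1.0
    sn_centre: Tuple[float, float] = (5 * PI / 12, PI / 2)
    sn_radius_mm: float = 1.696
    annulus_width_mm: float = 2.0
    burst_group_radius_mm: float = 2.12
    burst_overrides_refractory: bool = True
    # anatomy
    volume_ml: float = 40.0
    scale_mm: float = 21.2              # sphere radius; 1 scaled unit = 21.2 mm
    pv_radius_mm: float = 5.0
    pv_centres: Tuple[Tuple[float, float], ...] = (
        (2 * PI / 5 - PI / 10, -PI / 3),
        (2 * PI / 5 - PI / 10, PI / 3),
        (2 * PI / 5 + PI / 10, -PI / 3),
        (2 * PI / 5 + PI / 10, PI / 3),
    )
    mv_centre: Tuple[float, float] = (PI, 0.0)
    mv_circumference_mm: float = 85.0
    # fibrosis distribution
    fibrosis_centre: Tuple[float, float] = (0.65 * PI, 0.0)
    fibrosis_sigma_radii: float = 0.4   # sphere radii, in arc length
    # initial condition
    heterogeneous_init: bool = False    # uniform random initial RPs in [64, 120]

    def __post_init__(self) -> None:
        if self.br_hz < 0:
            raise ValueError("burst rate must be non-negative")
        if not (0 <= self.p < 1):
            raise ValueError(
                f"per-step burst probability p = BR/400 = {self.p} must lie in [0, 1)"
            )
        if self.rp_min > self.rp_max:
            raise ValueError("rp_min must not exceed rp_max")
        for name in ("interaction_radius_mm", "sn_radius_mm",
                     "burst_group_radius_mm", "scale_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")

    # -- derived quantities ------------------------------------------------
    @property
    def p(self) -> float:
        """Per-step burst probability, p = BR * dt = BR/400."""
        return self.br_hz / STEPS_PER_SECOND

    @property
    def dt_s(self) -> float:
        return DT_S

    @property
    def sinus_period_steps(self) -> int:
        return int(round(self.sinus_period_s * STEPS_PER_SECOND))

    @property
    def pv_radius_rad(self) -> float:
        """PV disc angular radius (5 mm / 21.2 mm = 0.236 scaled units)."""
        return self.pv_radius_mm / self.scale_mm

    @property
    def mv_radius_rad(self) -> float:
        """Angular radius (from the south pole) of the disc whose rim has the
        mitral-valve circumference on the physical sphere."""
        s = self.mv_circumference_mm / (2 * PI * self.scale_mm)
        if not (0 < s <= 1):
            raise ValueError("MV circumference incompatible with sphere radius")
        return math.asin(s)

    @property
    def fibrosis_sigma_rad(self) -> float:
        return self.fibrosis_sigma_radii  # 1 sphere radius = 1 rad of arc

    def mm_to_rad(self, mm: float) -> float:
        return mm / self.scale_mm

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        d = dict(d)
        if "pv_centres" in d:
            d["pv_centres"] = tuple(tuple(c) for c in d["pv_centres"])
        for key in ("sn_centre", "mv_centre", "fibrosis_centre"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def replace(self, **kw) -> "ModelParams":
        return dataclasses.replace(self, **kw)
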