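"""Noise sources: machines, sound power, and stochastic duty cycles.

A machine is characterised by a single A-weighted sound power level L_WA
(dB re 1 pW) and a probabilistic duty cycle: at any simulation step it is
"Off", "Idle" or at "Full" power, with fixed probabilities and no temporal
persistence.  Off machines emit nothing (the background remains); idle
machines emit at a reduced level, by default 10 dB below full power since
measured idle levels are rarely reported alongside the full-power L_WA.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import RectRegion

__all__ = [
    "DutyState",
    "DutyCycleProbs",
    "WalkParams",
    "Machine",
    "sample_duty_state",
    "sound_power_watts",
    "effective_power",
    "W0",
]

#: reference sound power, watts (0 dB re 1 pW)
W0 = 1e-12

_PROB_TOL = 1e-9


class DutyState(enum.Enum):
    OFF = "off"
    IDLE = "idle"
    FULL = "full"


@dataclass(frozen=True)
class DutyCycleProbs:
    """Probabilities of the Full / Off / Idle duty states.

    Must form a probability vector: each in [0, 1], summing to 1.
    """

    p_on: float
    p_off: float
    p_idle: float

    def __post_init__(self) -> None:
        for name, p in (("p_on", self.p_on), ("p_off", self.p_off), ("p_idle", self.p_idle)):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        total = self.p_on + self.p_off + self.p_idle
        if abs(total - 1.0) > _PROB_TOL:
            raise ValueError(
                f"duty-cycle probabilities must sum to 1, got {total} "
                f"(p_on={self.p_on}, p_off={self.p_off}, p_idle={self.p_idle})"
            )


@dataclass(frozen=True)
class WalkParams:
    """Parameters of the random walk taken by a moving machine or worker.

    ``max_step`` bounds the step length a_j (metres); steps are drawn
    uniformly on (0, max_step] by default, or fixed at ``max_step`` for
    analytic comparisons.  ``boundary_policy`` controls confinement:
    ``reject_resample`` redraws direction and length until the new point
    falls inside the subarea (preserving isotropy away from the walls),
    ``clip`` clamps the proposed point to the subarea rectangle.
    """

    max_step: float = 5.0
    step_length_dist: str = "uniform"  # "uniform" | "fixed"
    boundary_policy: str = "reject_resample"  # "reject_resample" | "clip"

    def __post_init__(self) -> None:
        if self.max_step < 0:
            raise ValueError(f"max_step must be >= 0, got {self.max_step}")
        if self.step_length_dist not in ("uniform", "fixed"):
            raise ValueError(f"unknown step_length_dist {self.step_length_dist!r}")
        if self.boundary_policy not in ("reject_resample", "clip"):
            raise ValueError(f"unknown boundary_policy {self.boundary_policy!r}")


@dataclass(frozen=True)
class Machine:
    """A stationary or moving noise source.

    Stationary machines carry a fixed ``position``; moving machines roam a
    rectangular ``subarea`` under ``walk`` parameters.  ``lwa_full`` /
    ``lwa_idle`` are A-weighted sound power levels in dB re 1 pW.
    """

    label: str
    kind: str  # "stationary" | "moving"
    lwa_full: float
    duty: DutyCycleProbs
    lwa_idle: Optional[float] = None
    position: Optional[tuple[float, float]] = None
    subarea: Optional[RectRegion] = None
    walk: WalkParams = field(default_factory=WalkParams)

    def __post_init__(self) -> None:
        if self.kind not in ("stationary", "moving"):
            raise ValueError(f"machine {self.label!r}: unknown kind {self.kind!r}")
        if self.lwa_idle is None:
            object.__setattr__(self, "lwa_idle", self.lwa_full - 10.0)
        if self.lwa_idle > self.lwa_full:
            raise ValueError(
                f"machine {self.label!r}: lwa_idle ({self.lwa_idle}) exceeds "
                f"lwa_full ({self.lwa_full})"
            )
        if self.kind == "stationary":
            if self.position is None or self.subarea is not None:
                raise ValueError(
                    f"stationary machine {self.label!r} needs a position and no subarea"
                )
        else:
            if self.subarea is None or self.position is not None:
                raise ValueError(
                    f"moving machine {self.label!r} needs a subarea and no position"
                )


def sample_duty_state(duty: DutyCycleProbs, rng: np.random.Generator) -> DutyState:
    """Draw one duty state; consumes exactly one uniform variate.

    The unit interval is partitioned [0, p_off) → Off,
    [p_off, p_off + p_idle) → Idle, remainder → Full.
    """
    u = rng.random()
    if u < duty.p_off:
        return DutyState.OFF
    if u < duty.p_off + duty.p_idle:
        return DutyState.IDLE
    return DutyState.FULL


def sound_power_watts(lwa: float) -> float:
    """Convert a sound power level (dB re 1 pW) to watts: W = 10^(L/10)·1e-12."""
    return 10.0 ** (lwa / 10.0) * W0


def effective_power(machine: Machine, state: DutyState) -> float:
    """Emitted sound power (W) of a machine in a given duty state.

    Off machines emit nothing — only the background remains at the
    receiver; idle and full states use the respective power levels.
    """
    if state is DutyState.OFF:
        return 0.0
    if state is DutyState.IDLE:
        return sound_power_watts(machine.lwa_idle)
    return sound_power_watts(machine.lwa_full)
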