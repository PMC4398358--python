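"""Pearson random walk confined to a rectangular subarea.

Each step moves a walker by a·(cos θ, sin θ) with direction θ drawn
uniformly on [0, 2π) and length a drawn per the walk parameters: the new
location depends only on the previous location, never on the previous
direction.  Confinement keeps walkers inside their subarea; for an
unconfined walk with fixed step a the classical identity
E|R_n − R_0|² = n·a² holds, which the tests use as an analytic oracle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import RectRegion, contains
from .machinery import WalkParams

__all__ = ["WalkerState", "initial_position", "walk_step"]

logger = logging.getLogger(__name__)

#: redraw budget for reject_resample before falling back to clipping
_MAX_RESAMPLES = 1000


@dataclass
class WalkerState:
    """Current position of a walker, optionally recording its trajectory."""

    position: tuple[float, float]
    record: bool = False
    history: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.record and not self.history:
            self.history.append(self.position)


def initial_position(subarea: RectRegion, rng: np.random.Generator) -> tuple[float, float]:
    """Uniform random starting point inside the subarea.

    Consumes two uniform variates (x then y); a zero-extent subarea
    collapses to its corner point.
    """
    x = subarea.x0 + rng.random() * subarea.width
    y = subarea.y0 + rng.random() * subarea.depth
    return (x, y)


def _draw_step(params: WalkParams, rng: np.random.Generator) -> tuple[float, float]:
    """One (θ, a) draw: two variates for uniform lengths, one for fixed."""
    theta = rng.random() * 2.0 * math.pi
    if params.step_length_dist == "fixed":
        a = params.max_step
    else:
        a = rng.random() * params.max_step
    return theta, a


def _clip(p: tuple[float, float], subarea: RectRegion) -> tuple[float, float]:
    return (
        min(max(p[0], subarea.x0), subarea.x1),
        min(max(p[1], subarea.y0), subarea.y1),
    )


def walk_step(
    state: WalkerState,
    subarea: RectRegion,
    params: WalkParams,
    rng: np.random.Generator,
) -> WalkerState:
    """Advance a walker one Pearson step, confined to its subarea.

    Under ``reject_resample`` the (θ, a) pair is redrawn until the proposed
    point lands inside the subarea (up to a fixed budget, after which the
    point is clipped — only reachable for pathological geometry); under
    ``clip`` the proposal is clamped to the rectangle directly.
    """
    x, y = state.position
    if params.max_step == 0.0:
        new = state.position
    else:
        new = None
        attempts = _MAX_RESAMPLES if params.boundary_policy == "reject_resample" else 1
        for _ in range(attempts):
            theta, a = _draw_step(params, rng)
            cand = (x + a * math.cos(theta), y + a * math.sin(theta))
            if contains(subarea, cand):
                new = cand
                break
        if new is None:
            if params.boundary_policy == "reject_resample":
                logger.warning(
                    "walk_step: %d resamples exhausted in subarea %s; clipping",
                    _MAX_RESAMPLES,
                    subarea,
                )
            new = _clip(cand, subarea)
    out = WalkerState(position=new, record=state.record, history=state.history)
    if out.record:
        out.history.append(new)
    return out
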