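"""Instantaneous A-weighted SPL field from point sources on a grid.

Sources radiate hemispherically over a hard reflecting ground, so the
intensity at distance r from a source of power W is I = W / (2π r²).
Receiver levels are expressed in dB re the reference intensity
I0 = 1e-12 W/m².  Barrier effects follow the simple screening
approximation used for construction-site prediction: −5 dB when the
source remains visible past an obstacle (partial screening), −10 dB when
it is hidden (full screening), and +3 dB at receivers within 1 m of a
reflective building façade.  Corrections are applied per source path in
the level domain; the corrected per-source levels are then summed
energetically together with the (uncorrected, spatially uniform)
background intensity.

Air absorption, ground absorption, meteorology and source directivity are
deliberately out of scope: levels are single A-weighted scalars.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import (
    Barrier,
    GridSpec,
    Screening,
    blocked_mask_grid,
    facade_mask_grid,
    near_facade,
    segment_blocked,
)

__all__ = [
    "I0",
    "ATTENUATION_DB",
    "REFLECTION_DB",
    "PathCorrection",
    "SPLField",
    "euclidean_distance",
    "source_intensity",
    "path_correction_db",
    "spl_from_intensity",
    "source_level",
    "compute_field",
    "interpolate_level",
]

#: reference sound intensity, W/m²
I0 = 1e-12

#: screening-class → attenuation in dB
ATTENUATION_DB = {Screening.CLEAR: 0.0, Screening.PARTIAL: -5.0, Screening.FULL: -10.0}
#: façade reflection bonus in dB
REFLECTION_DB = 3.0


@dataclass(frozen=True)
class PathCorrection:
    """Barrier corrections for one source→receiver path, in dB."""

    attenuation: float  # 0, -5 or -10
    reflection: float  # 0 or +3

    @property
    def total(self) -> float:
        return self.attenuation + self.reflection


@dataclass(frozen=True)
class SPLField:
    """One step's grid of A-weighted sound pressure levels (dBA).

    ``levels`` has shape ``(n_rows, n_cols)``: row index runs along y,
    column index along x, matching :meth:`GridSpec.meshes`.
    """

    grid: GridSpec
    levels: np.ndarray
    step_index: int = 0


def euclidean_distance(p: tuple[float, float], q: tuple[float, float]) -> float:
    """Straight-line source→receiver distance in the mapping plane."""
    return math.hypot(p[0] - q[0], p[1] - q[1])


def source_intensity(power: float, r: float, min_r: float = 1.0) -> float:
    """Hemispherical-spreading intensity I = W / (2π max(r, min_r)²).

    ``min_r`` clamps the distance so a receiver node coinciding with a
    source stays finite; by default it equals the grid spacing.
    """
    if power < 0:
        raise ValueError(f"power must be >= 0 W, got {power}")
    r_eff = max(r, min_r)
    return power / (2.0 * math.pi * r_eff * r_eff)


def path_correction_db(
    src: tuple[float, float],
    rcv: tuple[float, float],
    barriers: list[Barrier],
    facade_radius: float = 1.0,
) -> PathCorrection:
    """Barrier attenuation and façade reflection for one path.

    Attenuation follows the strongest screening class crossed by the open
    src→rcv segment; reflection is a property of the receiver position
    (within ``facade_radius`` of a reflective façade) and both corrections
    may apply simultaneously.
    """
    att = ATTENUATION_DB[segment_blocked(src, rcv, barriers)]
    refl = REFLECTION_DB if near_facade(rcv, barriers, facade_radius) else 0.0
    return PathCorrection(attenuation=att, reflection=refl)


def spl_from_intensity(i_total: float) -> float:
    """Level in dB re I0: L = 10·log10(I / 1e-12)."""
    if i_total <= 0:
        raise ValueError(f"intensity must be positive, got {i_total}")
    return 10.0 * math.log10(i_total / I0)


def source_level(
    power: float,
    src: tuple[float, float],
    rcv: tuple[float, float],
    barriers: list[Barrier] = (),
    min_r: float = 1.0,
) -> float:
    """Corrected level of a single source at a single receiver.

    This is the per-path building block of :func:`compute_field`:
    hemispherical spreading, then barrier attenuation and façade
    reflection in the level domain.
    """
    r = euclidean_distance(src, rcv)
    level = spl_from_intensity(source_intensity(power, r, min_r))
    return level + path_correction_db(src, rcv, list(barriers)).total


def compute_field(
    active_sources: list[tuple[tuple[float, float], float]],
    barriers: list[Barrier],
    grid: GridSpec,
    background_level: float,
    min_r: float | None = None,
    step_index: int = 0,
    facade_radius: float = 1.0,
) -> SPLField:
    """Total A-weighted SPL at every grid node for one simulation step.

    Parameters
    ----------
    active_sources:
        ``(position, power_watts)`` pairs; powers come from
        :func:`noisewalk.machinery.effective_power` for the step's duty
        states.  Zero-power (off) sources contribute nothing.
    barriers:
        Screening/reflecting obstacles.
    background_level:
        L_BG in dBA; its intensity 10^(L_BG/10)·1e-12 W/m² is added,
        spatially uniform and unaffected by barriers.
    min_r:
        Distance clamp; defaults to the grid spacing.

    The per-source corrected levels are converted back to the linear
    domain and summed energetically with the background:
    L_i = 10·log10(10^(L_BG/10) + Σ_k 10^(L_ik/10)).
    """
    if min_r is None:
        min_r = grid.spacing
    X, Y = grid.meshes()
    # linear accumulator in units of I/I0
    linear = np.full(grid.shape, 10.0 ** (background_level / 10.0))
    refl_db = np.where(facade_mask_grid(X, Y, barriers, facade_radius), REFLECTION_DB, 0.0)
    for (sx, sy), power in active_sources:
        if power <= 0.0:
            continue
        r = np.hypot(X - sx, Y - sy)
        np.maximum(r, min_r, out=r)
        intensity = power / (2.0 * math.pi * r * r)
        att_db = np.zeros(grid.shape)
        for b in barriers:
            mask = blocked_mask_grid((sx, sy), X, Y, b.region)
            np.minimum(att_db, np.where(mask, ATTENUATION_DB[b.screening], 0.0), out=att_db)
        level = 10.0 * np.log10(intensity / I0) + att_db + refl_db
        linear += 10.0 ** (level / 10.0)
    return SPLField(grid=grid, levels=10.0 * np.log10(linear), step_index=step_index)


def interpolate_level(field: SPLField, p: tuple[float, float]) -> float:
    """Bilinear interpolation of the level field at an arbitrary point.

    Points must lie inside the grid's bounding box; a point exactly on a
    node returns that node's value.
    """
    x, y = p
    xs, ys = field.grid.x_coords, field.grid.y_coords
    if not (xs[0] <= x <= xs[-1] and ys[0] <= y <= ys[-1]):
        raise ValueError(f"point {p} lies outside the grid")
    d = field.grid.spacing
    ix = min(int((x - xs[0]) / d), len(xs) - 2) if len(xs) > 1 else 0
    iy = min(int((y - ys[0]) / d), len(ys) - 2) if len(ys) > 1 else 0
    if len(xs) == 1 and len(ys) == 1:
        return float(field.levels[0, 0])
    fx = (x - xs[ix]) / d if len(xs) > 1 else 0.0
    fy = (y - ys[iy]) / d if len(ys) > 1 else 0.0
    jx = ix + 1 if len(xs) > 1 else ix
    jy = iy + 1 if len(ys) > 1 else iy
    z = field.levels
    return float(
        z[iy, ix] * (1 - fx) * (1 - fy)
        + z[iy, jx] * fx * (1 - fy)
        + z[jy, ix] * (1 - fx) * fy
        + z[jy, jx] * fx * fy
    )
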