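"""Site geometry: mapping area, grid, rectangular subareas and barriers.

The model lives in a flat two-dimensional plane, in metres, with the origin
at the lower-left corner of the mapping area.  All receivers sit implicitly
on the 1.5 m measurement plane; there is no vertical coordinate.  Region
boundaries are closed: a point lying exactly on an edge counts as inside,
which keeps walkers clamped to a subarea edge legal.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MappingArea",
    "GridSpec",
    "RectRegion",
    "Barrier",
    "Screening",
    "mesh_grid",
    "contains",
    "segment_blocked",
    "near_facade",
    "segment_intersects_rect",
    "blocked_mask_grid",
    "facade_mask_grid",
]


class Screening(enum.Enum):
    """Line-of-sight classification of a source→receiver path.

    ``FULL`` screening (source hidden from the receiver) attenuates a path
    by 10 dB, ``PARTIAL`` (source still visible) by 5 dB; ``CLEAR`` paths
    are unattenuated.  The dB values themselves live in :mod:`.acoustics`.
    """

    CLEAR = "clear"
    PARTIAL = "partial"
    FULL = "full"


@dataclass(frozen=True)
class RectRegion:
    """Axis-aligned rectangle, lower-left corner plus extents (metres)."""

    x0: float
    y0: float
    width: float
    depth: float

    def __post_init__(self) -> None:
        if self.width < 0 or self.depth < 0:
            raise ValueError(
                f"RectRegion extents must be non-negative, got "
                f"width={self.width}, depth={self.depth}"
            )

    @property
    def x1(self) -> float:
        return self.x0 + self.width

    @property
    def y1(self) -> float:
        return self.y0 + self.depth

    @property
    def centroid(self) -> tuple[float, float]:
        return (self.x0 + self.width / 2.0, self.y0 + self.depth / 2.0)


@dataclass(frozen=True)
class Barrier:
    """Rectangular obstacle (building, wall, stockpile).

    ``screening`` states what happens to a source→receiver path whose open
    segment crosses the footprint; ``reflective`` marks façades that add
    +3 dB to receivers within 1 m of the outside of the rectangle.
    """

    region: RectRegion
    screening: Screening = Screening.FULL
    reflective: bool = False
    label: str = ""


@dataclass(frozen=True)
class MappingArea:
    """The rectangular area over which the noise map is predicted.

    Parameters
    ----------
    width, depth:
        Global extents in metres.
    grid_spacing:
        Receiver grid interval in metres (1 m by default).
    background_level:
        Spatially uniform background noise level L_BG in dBA.
    working_period:
        Exposure assessment horizon in minutes (480 = one 8 h shift).
    """

    width: float
    depth: float
    grid_spacing: float = 1.0
    background_level: float = 0.0
    working_period: float = 480.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.depth <= 0:
            raise ValueError(
                f"mapping area dimensions must be positive, got "
                f"{self.width} x {self.depth}"
            )
        if self.grid_spacing <= 0:
            raise ValueError(f"grid_spacing must be positive, got {self.grid_spacing}")
        if self.background_level < 0:
            raise ValueError(
                f"background_level must be >= 0 dBA, got {self.background_level}"
            )
        if self.working_period <= 0:
            raise ValueError(f"working_period must be positive, got {self.working_period}")

    @property
    def region(self) -> RectRegion:
        return RectRegion(0.0, 0.0, self.width, self.depth)


@dataclass(frozen=True)
class GridSpec:
    """Receiver grid: node coordinates along each axis.

    A ``W x D`` area meshed at spacing ``Δ`` carries
    ``(floor(W/Δ)+1) x (floor(D/Δ)+1)`` nodes with the origin node at
    ``(0, 0)``; e.g. 100 m x 70 m at 1 m spacing gives a 101 x 71 matrix.
    """

    x_coords: np.ndarray
    y_coords: np.ndarray
    spacing: float

    @property
    def n_cols(self) -> int:
        return len(self.x_coords)

    @property
    def n_rows(self) -> int:
        return len(self.y_coords)

    @property
    def shape(self) -> tuple[int, int]:
        """(n_rows, n_cols) — row index runs along y, column along x."""
        return (self.n_rows, self.n_cols)

    def meshes(self) -> tuple[np.ndarray, np.ndarray]:
        """X and Y coordinate matrices of shape ``(n_rows, n_cols)``."""
        return np.meshgrid(self.x_coords, self.y_coords)


# tolerance guarding float jitter in width/spacing divisions (e.g. 0.3/0.1)
_MESH_EPS = 1e-9


def mesh_grid(area: MappingArea) -> GridSpec:
    """Mesh the mapping area into evenly spaced receiver nodes.

    Node counts follow ``floor(extent / spacing) + 1`` per axis, so the
    grid always includes the origin and never extends past the area.
    """
    d = area.grid_spacing
    n_cols = math.floor(area.width / d + _MESH_EPS) + 1
    n_rows = math.floor(area.depth / d + _MESH_EPS) + 1
    return GridSpec(
        x_coords=np.arange(n_cols, dtype=float) * d,
        y_coords=np.arange(n_rows, dtype=float) * d,
        spacing=d,
    )


def contains(region: RectRegion, p: tuple[float, float]) -> bool:
    """Closed-boundary containment test: edge points are inside."""
    x, y = p
    return region.x0 <= x <= region.x1 and region.y0 <= y <= region.y1


def segment_intersects_rect(
    p0: tuple[float, float], p1: tuple[float, float], rect: RectRegion
) -> bool:
    """Whether the open segment p0→p1 crosses an axis-aligned rectangle.

    Liang–Barsky slab clipping: the parametric interval of the segment
    inside the rectangle is intersected with (0, 1); the endpoints
    themselves do not count, so a source sitting exactly on a barrier
    edge is not screened by that barrier.
    """
    lo, hi = 0.0, 1.0
    for a0, a1, r0, r1 in (
        (p0[0], p1[0], rect.x0, rect.x1),
        (p0[1], p1[1], rect.y0, rect.y1),
    ):
        d = a1 - a0
        if d == 0.0:
            if a0 < r0 or a0 > r1:
                return False
            continue
        t0, t1 = (r0 - a0) / d, (r1 - a0) / d
        if t0 > t1:
            t0, t1 = t1, t0
        lo, hi = max(lo, t0), min(hi, t1)
        if lo > hi:
            return False
    # non-empty overlap with the open interval (0, 1)
    return hi > 0.0 and lo < 1.0


def segment_blocked(
    src: tuple[float, float],
    rcv: tuple[float, float],
    barriers: list[Barrier],
) -> Screening:
    """Strongest screening class among barriers crossing the path.

    FULL dominates PARTIAL; the result is symmetric in (src, rcv).
    """
    result = Screening.CLEAR
    for b in barriers:
        if segment_intersects_rect(src, rcv, b.region):
            if b.screening is Screening.FULL:
                return Screening.FULL
            result = Screening.PARTIAL
    return result


def _rect_outside_distance(
    x: np.ndarray | float, y: np.ndarray | float, rect: RectRegion
) -> np.ndarray | float:
    """Distance to the rectangle for outside points; 0 inside."""
    dx = np.maximum(np.maximum(rect.x0 - x, x - rect.x1), 0.0)
    dy = np.maximum(np.maximum(rect.y0 - y, y - rect.y1), 0.0)
    return np.hypot(dx, dy)


def near_facade(
    rcv: tuple[float, float],
    barriers: list[Barrier],
    radius: float = 1.0,
) -> bool:
    """True iff the receiver stands within ``radius`` of a reflective
    façade, outside the building footprint itself."""
    x, y = rcv
    for b in barriers:
        if not b.reflective:
            continue
        if contains(b.region, rcv):
            continue
        if _rect_outside_distance(x, y, b.region) <= radius:
            return True
    return False


def blocked_mask_grid(
    src: tuple[float, float],
    xs: np.ndarray,
    ys: np.ndarray,
    rect: RectRegion,
) -> np.ndarray:
    """Vectorised open-segment/rectangle test from one source to many
    receivers.

    Same Liang–Barsky logic as :func:`segment_intersects_rect`, broadcast
    over receiver coordinate arrays; used in the per-step field loop where
    a per-node Python call would dominate the runtime.
    """
    sx, sy = src
    lo = np.zeros(np.broadcast(xs, ys).shape)
    hi = np.ones_like(lo)
    valid = np.ones_like(lo, dtype=bool)
    for a0, a1v, r0, r1 in ((sx, xs, rect.x0, rect.x1), (sy, ys, rect.y0, rect.y1)):
        d = np.asarray(a1v, dtype=float) - a0
        zero = d == 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            t0 = (r0 - a0) / d
            t1 = (r1 - a0) / d
        tlo = np.minimum(t0, t1)
        thi = np.maximum(t0, t1)
        # degenerate axis: inside the slab leaves the interval untouched,
        # outside rules the intersection out entirely
        inside_slab = (a0 >= r0) & (a0 <= r1)
        tlo = np.where(zero, -np.inf, tlo)
        thi = np.where(zero, np.inf, thi)
        valid &= np.where(zero, inside_slab, True)
        lo = np.maximum(lo, tlo)
        hi = np.minimum(hi, thi)
    return valid & (lo <= hi) & (hi > 0.0) & (lo < 1.0)


def facade_mask_grid(
    xs: np.ndarray,
    ys: np.ndarray,
    barriers: list[Barrier],
    radius: float = 1.0,
) -> np.ndarray:
    """Vectorised :func:`near_facade` over receiver coordinate arrays."""
    mask = np.zeros(np.broadcast(xs, ys).shape, dtype=bool)
    for b in barriers:
        if not b.reflective:
            continue
        d = _rect_outside_distance(np.asarray(xs, float), np.asarray(ys, float), b.region)
        mask |= (d > 0.0) & (d <= radius)
    return mask
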