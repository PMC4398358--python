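"""Occupational exposure metrics, noise indices and risk zoning.

Noise dose follows the dosimeter convention: a level L may be endured for
T_allowed(L) = T_c · 2^((CL − L)/Q) minutes, where CL is the criterion
level, T_c the criterion duration (8 h) and Q the exchange rate (the dB
increase that halves the allowed time).  The dose is the accumulated
fraction of allowance in percent; the TWA is the constant 8-hour level
carrying the same dose, TWA = CL + Q·log2(dose/100).  Defaults Q = 3 dB,
CL = 90 dBA, T_c = 480 min; a 5-dB exchange rate is a one-argument change.

Noise indices L10/L50/L90 are exceedance percentiles of the level series
(L10 = level exceeded 10 % of the time = 90th percentile), computed with
linear interpolation between order statistics.

Risk zones band LAeq into six categories from Safe (< 66 dBA) to
Extremely high risk (>= 86 dBA), in 5-dB classes resolved as left-closed,
right-open intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ExposureConfig",
    "ExposureResult",
    "LevelStatistics",
    "RiskZone",
    "RiskZoneSummary",
    "RISK_ZONE_EDGES",
    "dose_percent",
    "twa_from_dose",
    "exposure_from_series",
    "noise_indices",
    "level_statistics",
    "classify_risk",
    "risk_zone_percentages",
    "check_limit",
]


@dataclass(frozen=True)
class ExposureConfig:
    """Dosimeter convention: exchange rate Q, criterion level and duration."""

    exchange_rate: float = 3.0  # dB per halving of allowed time
    criterion_level: float = 90.0  # dBA
    criterion_duration: float = 480.0  # minutes

    def __post_init__(self) -> None:
        if self.exchange_rate <= 0:
            raise ValueError(f"exchange_rate must be > 0, got {self.exchange_rate}")
        if self.criterion_duration <= 0:
            raise ValueError(
                f"criterion_duration must be > 0, got {self.criterion_duration}"
            )

    def allowed_minutes(self, level: float) -> float:
        """T_allowed(L) = T_c · 2^((CL − L)/Q)."""
        return self.criterion_duration * 2.0 ** (
            (self.criterion_level - level) / self.exchange_rate
        )


@dataclass(frozen=True)
class ExposureResult:
    """A worker group's exposure over a stated working period."""

    laeq: float  # dBA
    dose: float  # percent of daily allowance
    twa: float  # dBA
    duration: float  # minutes


def dose_percent(
    levels: Sequence[float] | np.ndarray,
    total_duration: float,
    config: ExposureConfig = ExposureConfig(),
) -> float:
    """Noise dose (%) of a level series spanning ``total_duration`` minutes.

    Steps are equal time slices: D = 100 · Σ t_step / T_allowed(L_step).
    For a constant level this reduces to 100·(t/T_c)·2^((L−CL)/Q); e.g.
    85.9 dBA held for 30 min at Q=3, CL=90 gives 2.4 %.
    """
    levels = np.asarray(levels, dtype=float)
    if levels.size == 0:
        raise ValueError("cannot compute a dose from an empty level series")
    if total_duration <= 0:
        raise ValueError(f"total_duration must be > 0, got {total_duration}")
    t_step = total_duration / levels.size
    allowed = config.criterion_duration * 2.0 ** (
        (config.criterion_level - levels) / config.exchange_rate
    )
    return float(100.0 * np.sum(t_step / allowed))


def twa_from_dose(dose: float, config: ExposureConfig = ExposureConfig()) -> float:
    """Time-weighted average level from a dose: TWA = CL + Q·log2(D/100)."""
    if dose <= 0:
        raise ValueError(f"dose must be > 0 to define a TWA, got {dose}")
    return config.criterion_level + config.exchange_rate * math.log2(dose / 100.0)


def exposure_from_series(
    levels: Sequence[float] | np.ndarray,
    total_duration: float,
    config: ExposureConfig = ExposureConfig(),
) -> ExposureResult:
    """Bundle LAeq, dose and TWA for one exposure series."""
    levels = np.asarray(levels, dtype=float)
    laeq = float(10.0 * np.log10(np.mean(10.0 ** (levels / 10.0))))
    dose = dose_percent(levels, total_duration, config)
    return ExposureResult(
        laeq=laeq, dose=dose, twa=twa_from_dose(dose, config), duration=total_duration
    )


def noise_indices(levels: Sequence[float] | np.ndarray) -> tuple[float, float, float]:
    """(L10, L50, L90): levels exceeded 10/50/90 % of the time.

    Lx is the (100−x)th percentile of the series under the exceedance
    convention, with linear interpolation between order statistics;
    L90 <= L50 <= L10 always.
    """
    levels = np.asarray(levels, dtype=float)
    if levels.size == 0:
        raise ValueError("cannot compute indices of an empty series")
    l10, l50, l90 = np.percentile(levels, [90.0, 50.0, 10.0])
    return float(l10), float(l50), float(l90)


@dataclass(frozen=True)
class LevelStatistics:
    """Descriptive statistics of a level series."""

    laeq: float  # energetic mean, dBA
    std: float
    min: float
    max: float
    bin_edges: np.ndarray
    pdf: np.ndarray  # normalised histogram (density)
    cdf_levels: np.ndarray  # sorted sample
    cdf: np.ndarray  # empirical CDF at cdf_levels
    l10: float
    l50: float
    l90: float


def level_statistics(
    levels: Sequence[float] | np.ndarray, bin_width: float = 1.0
) -> LevelStatistics:
    """Histogram/PDF/CDF summary of a level series.

    The PDF is the density-normalised histogram at ``bin_width`` dB bins
    (masses sum to 1); the CDF is the empirical distribution over the
    sorted sample.
    """
    levels = np.asarray(levels, dtype=float)
    if levels.size == 0:
        raise ValueError("cannot summarise an empty series")
    lo = math.floor(levels.min() / bin_width) * bin_width
    hi = math.ceil(levels.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2.0, bin_width)
    pdf, edges = np.histogram(levels, bins=edges, density=True)
    sorted_levels = np.sort(levels)
    cdf = np.arange(1, levels.size + 1) / levels.size
    l10, l50, l90 = noise_indices(levels)
    return LevelStatistics(
        laeq=float(10.0 * np.log10(np.mean(10.0 ** (levels / 10.0)))),
        std=float(np.std(levels)),
        min=float(levels.min()),
        max=float(levels.max()),
        bin_edges=edges,
        pdf=pdf,
        cdf_levels=sorted_levels,
        cdf=cdf,
        l10=l10,
        l50=l50,
        l90=l90,
    )


#: risk-zone band edges in dBA; bands are left-closed, right-open
RISK_ZONE_EDGES = (66.0, 71.0, 76.0, 81.0, 86.0)

RiskZone = str

_ZONE_NAMES: tuple[RiskZone, ...] = (
    "Safe",
    "Tolerable",
    "Low risk",
    "Moderate risk",
    "High risk",
    "Extremely high risk",
)


def classify_risk(level: float) -> RiskZone:
    """Risk-zone category of a level: Safe below 66 dBA, then 5-dB bands
    up to Extremely high risk at and above 86 dBA."""
    if not math.isfinite(level):
        raise ValueError(f"level must be finite, got {level}")
    idx = int(np.digitize(level, RISK_ZONE_EDGES, right=False))
    return _ZONE_NAMES[idx]


@dataclass(frozen=True)
class RiskZoneSummary:
    """Per-node risk categories and the share of area in each."""

    category_grid: np.ndarray  # integer band index per node, 0..5
    zone_names: tuple[RiskZone, ...]
    percentages: dict[RiskZone, float]


def risk_zone_percentages(laeq_grid: np.ndarray) -> RiskZoneSummary:
    """Classify every node and report the percentage of area per zone.

    Percentages are node-count shares and sum to 100.
    """
    grid = np.asarray(laeq_grid, dtype=float)
    if not np.all(np.isfinite(grid)):
        raise ValueError("laeq_grid must be finite everywhere")
    idx = np.digitize(grid, RISK_ZONE_EDGES, right=False)
    total = grid.size
    percentages = {
        name: float(np.count_nonzero(idx == i) / total * 100.0)
        for i, name in enumerate(_ZONE_NAMES)
    }
    return RiskZoneSummary(
        category_grid=idx, zone_names=_ZONE_NAMES, percentages=percentages
    )


def check_limit(
    laeq_grid: np.ndarray, limit: float
) -> tuple[np.ndarray, float]:
    """Nodes exceeding a permissible limit (strict >) and their share.

    Returns ``(mask, percent_exceeding)``; a grid exactly at the limit
    exceeds nowhere.
    """
    grid = np.asarray(laeq_grid, dtype=float)
    mask = grid > limit
    return mask, float(np.count_nonzero(mask) / grid.size * 100.0)
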