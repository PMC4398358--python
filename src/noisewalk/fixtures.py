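"""Built-in machine inventories and case-study scenarios.

The machine inventory carries measured A-weighted sound power levels and
duty-cycle probabilities for the machines of three southern-Malaysian
workplaces: an oil palm mill (seven stationary machines plus a
narrow-gauge locomotive), a piling site, and a drainage excavation.

Machine *positions*, subareas and building footprints in the scenario
builders are illustrative reconstructions — the source site layouts are
drawings, not coordinate tables — so analyses should rely on the
inventory values, dimensions and background levels, never on the exact
placements.  A reference personal-exposure table for the mill's three
worker groups (30-minute dosimeter sessions) ships alongside for
comparison studies.
"""

from __future__ import annotations

from .engine import Scenario, WorkerGroup
from .geometry import Barrier, MappingArea, RectRegion, Screening
from .machinery import DutyCycleProbs, Machine, WalkParams

__all__ = [
    "MACHINE_INVENTORY",
    "MILL_EXPOSURE_REFERENCE",
    "STEP_SETTINGS",
    "case_study_mill",
    "case_study_piling",
    "case_study_excavation",
    "mill_receivers",
]

#: label → (name, kind, L_WA dBA, p_on, p_off, p_idle)
MACHINE_INVENTORY: dict[str, tuple[str, str, float, float, float, float]] = {
    "S1": ("Exhaust pipe", "stationary", 103.9, 0.9, 0.0, 0.1),
    "S2": ("Generator", "stationary", 119.7, 0.9, 0.0, 0.1),
    "S3": ("Oil purifier", "stationary", 105.0, 0.9, 0.0, 0.1),
    "S4": ("Conveyor 1", "stationary", 105.0, 0.9, 0.0, 0.1),
    "S5": ("Conveyor 2", "stationary", 109.2, 0.9, 0.0, 0.1),
    "S6": ("Silo fan 1", "stationary", 106.5, 0.5, 0.5, 0.0),
    "S7": ("Silo fan 2", "stationary", 106.5, 0.5, 0.5, 0.0),
    "D1": ("Narrow gauges", "moving", 96.8, 0.7, 0.0, 0.3),
    "D2": ("Piling machine", "moving", 111.1, 0.3, 0.1, 0.6),
    "D3": ("Excavator", "moving", 98.8, 0.7, 0.0, 0.3),
}

#: measured and predicted 30-min exposure of the mill's worker groups:
#: group → (laeq_measured, dose_measured, laeq_predicted, dose_predicted)
MILL_EXPOSURE_REFERENCE: dict[str, tuple[float, float, float, float]] = {
    "Group 1": (88.4, 4.4, 89.2, 4.2),
    "Group 2": (85.9, 2.4, 85.1, 2.5),
    "Group 3": (88.5, 4.4, 92.0, 4.6),
}

#: the step-count ladder used for the convergence sweeps
STEP_SETTINGS: tuple[int, ...] = (100, 250, 500, 750, 1000, 1250, 1500)


def _machine(label: str, **kwargs) -> Machine:
    name, kind, lwa, p_on, p_off, p_idle = MACHINE_INVENTORY[label]
    return Machine(
        label=label,
        kind=kind,
        lwa_full=lwa,
        duty=DutyCycleProbs(p_on=p_on, p_off=p_off, p_idle=p_idle),
        **kwargs,
    )


def case_study_mill() -> Scenario:
    """Oil palm mill: 143 m × 86 m, background 52.2 dBA.

    Seven stationary machines, one moving narrow-gauge locomotive, three
    worker groups, and two reflective buildings (illustrative layout).
    """
    area = MappingArea(
        width=143.0, depth=86.0, grid_spacing=1.0,
        background_level=52.2, working_period=480.0,
    )
    barriers = [
        Barrier(RectRegion(20.0, 48.0, 24.0, 14.0), Screening.FULL, reflective=True,
                label="engine room"),
        Barrier(RectRegion(92.0, 18.0, 22.0, 14.0), Screening.FULL, reflective=True,
                label="oil storage"),
    ]
    stationary = [
        _machine("S1", position=(50.0, 60.0)),
        _machine("S2", position=(32.0, 66.0)),
        _machine("S3", position=(60.0, 52.0)),
        _machine("S4", position=(72.0, 48.0)),
        _machine("S5", position=(84.0, 46.0)),
        _machine("S6", position=(104.0, 40.0)),
        _machine("S7", position=(112.0, 42.0)),
    ]
    moving = [
        _machine("D1", subarea=RectRegion(20.0, 8.0, 50.0, 24.0),
                 walk=WalkParams(max_step=5.0)),
    ]
    workers = [
        WorkerGroup("Group 1", RectRegion(46.0, 52.0, 14.0, 12.0)),
        WorkerGroup("Group 2", RectRegion(24.0, 10.0, 20.0, 14.0)),
        WorkerGroup("Group 3", RectRegion(76.0, 40.0, 16.0, 12.0)),
    ]
    return Scenario(area=area, barriers=barriers, stationary=stationary,
                    moving=moving, worker_groups=workers)


def case_study_piling() -> Scenario:
    """Piling site: 100 m × 60 m, background 48.4 dBA, one moving piling rig."""
    area = MappingArea(width=100.0, depth=60.0, grid_spacing=1.0,
                       background_level=48.4, working_period=480.0)
    moving = [
        _machine("D2", subarea=RectRegion(30.0, 15.0, 40.0, 30.0),
                 walk=WalkParams(max_step=5.0)),
    ]
    return Scenario(area=area, moving=moving)


def case_study_excavation() -> Scenario:
    """Drainage excavation: 60 m × 36 m, background 48.4 dBA, one excavator."""
    area = MappingArea(width=60.0, depth=36.0, grid_spacing=1.0,
                       background_level=48.4, working_period=480.0)
    moving = [
        _machine("D3", subarea=RectRegion(15.0, 8.0, 30.0, 20.0),
                 walk=WalkParams(max_step=5.0)),
    ]
    return Scenario(area=area, moving=moving)


def mill_receivers(n: int = 42) -> list[tuple[float, float]]:
    """Deterministic receiver ring surrounding the mill's machine cluster.

    ``n`` points are spaced evenly along the perimeter of the rectangle
    (16, 6)–(130, 78); the mill validation campaign used 42 receivers
    placed around the stationary machines.
    """
    x0, y0, x1, y1 = 16.0, 6.0, 130.0, 78.0
    w, d = x1 - x0, y1 - y0
    perim = 2 * (w + d)
    points = []
    for i in range(n):
        s = perim * i / n
        if s < w:
            points.append((x0 + s, y0))
        elif s < w + d:
            points.append((x1, y0 + (s - w)))
        elif s < 2 * w + d:
            points.append((x1 - (s - w - d), y1))
        else:
            points.append((x0, y1 - (s - 2 * w - d)))
    return points
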