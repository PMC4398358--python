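"""Step loop of the random-walk noise simulation.

Each of the ``n_steps`` iterations represents one equal slice of the
working period.  Within a step the order is fixed and documented, because
it fixes the RNG draw order and hence reproducibility:

1. sample one duty state per machine (stationary machines first, then
   moving machines, in list order — one uniform draw each);
2. advance every moving machine one Pearson step inside its subarea
   (in list order);
3. compute the SPL field over the whole grid from the active sources;
4. advance every worker one Pearson step (groups in list order, walkers
   within a group in index order) and read its exposure level from the
   current step's field by bilinear interpolation.

Before the loop, initial positions are drawn uniformly inside each
subarea: moving machines first, then workers, in the same order.  A single
seeded ``numpy.random.Generator`` serves the whole run, so identical
(scenario, config) pairs reproduce bit-identical results.  Repeats are
owned by :func:`experiment_grid`, which derives one child seed per
(step-setting, repeat) cell; ``SimulationConfig.repeats`` records the
requested repeat count for that harness.

After the loop, the per-node LAeq is the energetic mean over steps,
LAeq = 10·log10((1/N)·Σ 10^(L/10)), alongside per-node standard deviation,
minimum and maximum of the step levels (in dB).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .acoustics import SPLField, compute_field, interpolate_level
from .geometry import Barrier, GridSpec, MappingArea, RectRegion, contains, mesh_grid
from .machinery import DutyState, Machine, WalkParams, effective_power, sample_duty_state
from .walk import WalkerState, initial_position, walk_step

__all__ = [
    "WorkerGroup",
    "Scenario",
    "SimulationConfig",
    "StepRecord",
    "SimulationResult",
    "run_simulation",
    "aggregate_laeq",
    "experiment_grid",
]


@dataclass(frozen=True)
class WorkerGroup:
    """A group of workers confined to a rectangular subarea.

    Walkers within a group move independently; the group's exposure series
    is the per-step energetic mean across its walkers.
    """

    label: str
    subarea: RectRegion
    n_walkers: int = 1
    walk: WalkParams = field(default_factory=WalkParams)

    def __post_init__(self) -> None:
        if self.n_walkers < 1:
            raise ValueError(f"worker group {self.label!r}: n_walkers must be >= 1")


@dataclass(frozen=True)
class Scenario:
    """Full workplace description: area, barriers, machines, workers."""

    area: MappingArea
    barriers: list[Barrier] = field(default_factory=list)
    stationary: list[Machine] = field(default_factory=list)
    moving: list[Machine] = field(default_factory=list)
    worker_groups: list[WorkerGroup] = field(default_factory=list)

    def validate(self) -> None:
        """Raise ``ValueError`` listing every offending entity."""
        problems: list[str] = []
        region = self.area.region
        for m in self.stationary:
            if m.kind != "stationary":
                problems.append(f"machine {m.label!r} listed as stationary but kind={m.kind!r}")
            elif not contains(region, m.position):
                problems.append(f"stationary machine {m.label!r} position {m.position} outside area")
        for m in self.moving:
            if m.kind != "moving":
                problems.append(f"machine {m.label!r} listed as moving but kind={m.kind!r}")
            elif not _rect_inside(m.subarea, region):
                problems.append(f"moving machine {m.label!r} subarea outside mapping area")
        for g in self.worker_groups:
            if not _rect_inside(g.subarea, region):
                problems.append(f"worker group {g.label!r} subarea outside mapping area")
        for b in self.barriers:
            if not _rect_inside(b.region, region):
                problems.append(f"barrier {b.label or b.region!r} outside mapping area")
        if problems:
            raise ValueError("invalid scenario:\n  - " + "\n  - ".join(problems))

    @property
    def machines(self) -> list[Machine]:
        """All machines, stationary first — the duty-sampling order."""
        return list(self.stationary) + list(self.moving)


def _rect_inside(inner: RectRegion, outer: RectRegion) -> bool:
    return (
        inner.x0 >= outer.x0
        and inner.y0 >= outer.y0
        and inner.x1 <= outer.x1
        and inner.y1 <= outer.y1
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Run settings: step count, seed, repeats, optional field recording."""

    n_steps: int
    seed: int = 0
    repeats: int = 1
    record_steps: bool = False
    record_fields: bool = False

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError(f"n_steps must be >= 1, got {self.n_steps}")
        if self.repeats < 1:
            raise ValueError(f"repeats must be >= 1, got {self.repeats}")


@dataclass
class StepRecord:
    """Snapshot of one simulation step."""

    step_index: int
    duty_states: list[DutyState]
    machine_positions: list[tuple[float, float]]
    worker_positions: list[list[tuple[float, float]]]
    worker_levels: list[list[float]]
    field: Optional[SPLField] = None


@dataclass
class SimulationResult:
    """Aggregated outcome of one simulation run."""

    grid: GridSpec
    laeq_grid: np.ndarray
    std_grid: np.ndarray
    min_grid: np.ndarray
    max_grid: np.ndarray
    #: per group: array of shape (n_steps, n_walkers), dBA
    worker_levels: dict[str, np.ndarray]
    #: per group: array of shape (n_steps, n_walkers, 2), metres
    worker_positions: dict[str, np.ndarray]
    config: SimulationConfig
    scenario: Scenario
    step_records: Optional[list[StepRecord]] = None

    def group_series(self, label: str) -> np.ndarray:
        """Per-step exposure series of a group: energetic mean over walkers."""
        levels = self.worker_levels[label]
        return 10.0 * np.log10(np.mean(10.0 ** (levels / 10.0), axis=1))


def aggregate_laeq(level_series: Sequence[float] | np.ndarray) -> float:
    """Equivalent continuous level of a series of equal-duration levels.

    LAeq = 10·log10(mean(10^(L/10))) — steps are equal time slices.
    """
    levels = np.asarray(level_series, dtype=float)
    if levels.size == 0:
        raise ValueError("cannot aggregate an empty level series")
    return float(10.0 * np.log10(np.mean(10.0 ** (levels / 10.0))))


def run_simulation(scenario: Scenario, config: SimulationConfig) -> SimulationResult:
    """Execute the step loop and aggregate per-node LAeq statistics.

    See the module docstring for the within-step ordering and RNG draw
    order.  Fully reproducible: the same (scenario, config) pair yields a
    bit-identical result.
    """
    scenario.validate()
    if len(scenario.machines) < 1:
        raise ValueError("a simulation run needs at least one machine (m + n >= 1)")
    rng = np.random.default_rng(config.seed)
    grid = mesh_grid(scenario.area)
    area = scenario.area
    barriers = scenario.barriers

    machines = scenario.machines
    moving = scenario.moving

    # initial positions: moving machines first, then workers, in list order
    machine_pos: dict[int, tuple[float, float]] = {}
    for i, m in enumerate(moving):
        machine_pos[i] = initial_position(m.subarea, rng)
    walkers: dict[str, list[WalkerState]] = {}
    for g in scenario.worker_groups:
        walkers[g.label] = [
            WalkerState(initial_position(g.subarea, rng)) for _ in range(g.n_walkers)
        ]

    n = config.n_steps
    linear_sum = np.zeros(grid.shape)
    level_sum = np.zeros(grid.shape)
    level_sumsq = np.zeros(grid.shape)
    min_grid = np.full(grid.shape, np.inf)
    max_grid = np.full(grid.shape, -np.inf)
    worker_levels = {
        g.label: np.empty((n, g.n_walkers)) for g in scenario.worker_groups
    }
    worker_pos_hist = {
        g.label: np.empty((n, g.n_walkers, 2)) for g in scenario.worker_groups
    }
    records: Optional[list[StepRecord]] = [] if config.record_steps else None
    n_stat = len(scenario.stationary)

    for step in range(n):
        # (1) duty states, stationary then moving
        states = [sample_duty_state(m.duty, rng) for m in machines]
        # (2) moving machines advance
        for i, m in enumerate(moving):
            st = walk_step(WalkerState(machine_pos[i]), m.subarea, m.walk, rng)
            machine_pos[i] = st.position
        # (3) field from all active sources
        positions = [
            m.position if m.kind == "stationary" else machine_pos[j - n_stat]
            for j, m in enumerate(machines)
        ]
        sources = [
            (positions[j], effective_power(m, states[j])) for j, m in enumerate(machines)
        ]
        fld = compute_field(
            sources, barriers, grid, area.background_level, step_index=step
        )
        # (4) workers advance and read the current field
        step_worker_pos: list[list[tuple[float, float]]] = []
        step_worker_lvl: list[list[float]] = []
        for g in scenario.worker_groups:
            pos_list, lvl_list = [], []
            for w, st in enumerate(walkers[g.label]):
                new = walk_step(st, g.subarea, g.walk, rng)
                walkers[g.label][w] = new
                lvl = interpolate_level(fld, new.position)
                worker_levels[g.label][step, w] = lvl
                worker_pos_hist[g.label][step, w] = new.position
                pos_list.append(new.position)
                lvl_list.append(lvl)
            step_worker_pos.append(pos_list)
            step_worker_lvl.append(lvl_list)

        lv = fld.levels
        linear_sum += 10.0 ** (lv / 10.0)
        # accumulate deviations from the first step's levels: avoids the
        # catastrophic cancellation of sumsq - mean^2 at ~100 dB magnitudes
        if step == 0:
            level_ref = lv.copy()
        dv = lv - level_ref
        level_sum += dv
        level_sumsq += dv * dv
        np.minimum(min_grid, lv, out=min_grid)
        np.maximum(max_grid, lv, out=max_grid)
        if records is not None:
            records.append(
                StepRecord(
                    step_index=step,
                    duty_states=states,
                    machine_positions=positions,
                    worker_positions=step_worker_pos,
                    worker_levels=step_worker_lvl,
                    field=fld if config.record_fields else None,
                )
            )

    laeq = 10.0 * np.log10(linear_sum / n)
    mean_db = level_sum / n
    var_db = np.maximum(level_sumsq / n - mean_db * mean_db, 0.0)
    return SimulationResult(
        grid=grid,
        laeq_grid=laeq,
        std_grid=np.sqrt(var_db),
        min_grid=min_grid,
        max_grid=max_grid,
        worker_levels=worker_levels,
        worker_positions=worker_pos_hist,
        config=config,
        scenario=scenario,
        step_records=records,
    )


def experiment_grid(
    scenario: Scenario,
    step_settings: Sequence[int],
    repeats: int,
    receiver_points: Sequence[tuple[float, float]],
    base_seed: int = 0,
) -> pd.DataFrame:
    """Step-setting sweep: one predicted LAeq per (receiver, setting, repeat).

    Runs ``len(step_settings) × repeats`` independent simulations; each
    cell's seed is derived deterministically from ``base_seed`` via
    ``numpy.random.SeedSequence([base_seed, setting_index, repeat])``, so
    the sweep is reproducible and cells are independent.  Receiver LAeq
    values are read off each run's LAeq grid by bilinear interpolation.

    Returns a tidy DataFrame with columns
    ``receiver, x, y, n_steps, repeat, laeq``.
    """
    scenario.validate()
    rows = []
    for si, n_steps in enumerate(step_settings):
        for rep in range(repeats):
            seed = int(np.random.SeedSequence([base_seed, si, rep]).generate_state(1)[0] % (2**31))
            cfg = SimulationConfig(n_steps=int(n_steps), seed=seed, repeats=1)
            result = run_simulation(scenario, cfg)
            fld = SPLField(grid=result.grid, levels=result.laeq_grid)
            for ri, p in enumerate(receiver_points):
                rows.append(
                    {
                        "receiver": ri,
                        "x": p[0],
                        "y": p[1],
                        "n_steps": int(n_steps),
                        "repeat": rep,
                        "laeq": interpolate_level(fld, p),
                    }
                )
    return pd.DataFrame(rows)
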