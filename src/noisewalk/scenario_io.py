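"""Scenario files: YAML schema, validation, and synthetic generation.

A scenario file is a versioned YAML (or JSON — YAML is a superset)
document with sections ``area``, ``barriers``, ``stationary_machines``,
``moving_machines``, ``worker_groups``, ``exposure`` and ``simulation``.
Parsing is strict: schema violations raise with the offending section,
entity and field named, and the parse → serialize → parse round trip is
lossless.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from .engine import Scenario, SimulationConfig, WorkerGroup
from .exposure import ExposureConfig
from .geometry import Barrier, MappingArea, RectRegion, Screening
from .machinery import DutyCycleProbs, Machine, WalkParams

__all__ = [
    "SCHEMA_VERSION",
    "read_scenario",
    "load_run_setup",
    "write_scenario",
    "scenario_to_dict",
    "scenario_from_dict",
    "generate_synthetic_scenario",
]

SCHEMA_VERSION = 1


class ScenarioFormatError(ValueError):
    """A scenario document violating the schema."""


def _require(mapping: dict, key: str, context: str) -> Any:
    if key not in mapping:
        raise ScenarioFormatError(f"{context}: missing required field {key!r}")
    return mapping[key]


def _rect_from_dict(d: dict, context: str) -> RectRegion:
    try:
        return RectRegion(
            x0=float(_require(d, "x0", context)),
            y0=float(_require(d, "y0", context)),
            width=float(_require(d, "width", context)),
            depth=float(_require(d, "depth", context)),
        )
    except ValueError as exc:
        raise ScenarioFormatError(f"{context}: {exc}") from exc


def _rect_to_dict(r: RectRegion) -> dict:
    return {"x0": r.x0, "y0": r.y0, "width": r.width, "depth": r.depth}


def _walk_from_dict(d: dict, context: str) -> WalkParams:
    try:
        return WalkParams(
            max_step=float(d.get("max_step", 5.0)),
            step_length_dist=d.get("step_length_dist", "uniform"),
            boundary_policy=d.get("boundary_policy", "reject_resample"),
        )
    except ValueError as exc:
        raise ScenarioFormatError(f"{context}: {exc}") from exc


def _machine_from_dict(d: dict, kind: str, index: int) -> Machine:
    label = d.get("label", f"{kind}-{index}")
    context = f"{kind}_machines[{label}]"
    try:
        duty = DutyCycleProbs(
            p_on=float(_require(d, "p_on", context)),
            p_off=float(_require(d, "p_off", context)),
            p_idle=float(_require(d, "p_idle", context)),
        )
        kwargs: dict[str, Any] = {}
        if kind == "stationary":
            kwargs["position"] = (
                float(_require(d, "x", context)),
                float(_require(d, "y", context)),
            )
        else:
            kwargs["subarea"] = _rect_from_dict(
                _require(d, "subarea", context), f"{context}.subarea"
            )
            kwargs["walk"] = _walk_from_dict(d.get("walk", {}), f"{context}.walk")
        return Machine(
            label=label,
            kind=kind,
            lwa_full=float(_require(d, "lwa_full", context)),
            lwa_idle=(None if d.get("lwa_idle") is None else float(d["lwa_idle"])),
            duty=duty,
            **kwargs,
        )
    except ScenarioFormatError:
        raise
    except ValueError as exc:
        raise ScenarioFormatError(f"{context}: {exc}") from exc


def _machine_to_dict(m: Machine) -> dict:
    d: dict[str, Any] = {
        "label": m.label,
        "lwa_full": m.lwa_full,
        "lwa_idle": m.lwa_idle,
        "p_on": m.duty.p_on,
        "p_off": m.duty.p_off,
        "p_idle": m.duty.p_idle,
    }
    if m.kind == "stationary":
        d["x"], d["y"] = m.position
    else:
        d["subarea"] = _rect_to_dict(m.subarea)
        d["walk"] = {
            "max_step": m.walk.max_step,
            "step_length_dist": m.walk.step_length_dist,
            "boundary_policy": m.walk.boundary_policy,
        }
    return d


def scenario_from_dict(doc: dict) -> Scenario:
    """Build and validate a Scenario from a parsed document."""
    if not isinstance(doc, dict):
        raise ScenarioFormatError("scenario document must be a mapping")
    version = doc.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ScenarioFormatError(f"unsupported schema_version {version}")
    area_doc = _require(doc, "area", "scenario")
    try:
        area = MappingArea(
            width=float(_require(area_doc, "width", "area")),
            depth=float(_require(area_doc, "depth", "area")),
            grid_spacing=float(area_doc.get("grid_spacing", 1.0)),
            background_level=float(area_doc.get("background_level", 0.0)),
            working_period=float(area_doc.get("working_period", 480.0)),
        )
    except ValueError as exc:
        raise ScenarioFormatError(f"area: {exc}") from exc

    barriers = []
    for i, b in enumerate(doc.get("barriers", []) or []):
        context = f"barriers[{b.get('label', i)}]"
        screening = b.get("screening", "full")
        try:
            barriers.append(
                Barrier(
                    region=_rect_from_dict(b, context),
                    screening=Screening(screening),
                    reflective=bool(b.get("reflective", False)),
                    label=str(b.get("label", "")),
                )
            )
        except ValueError as exc:
            raise ScenarioFormatError(f"{context}: {exc}") from exc

    stationary = [
        _machine_from_dict(m, "stationary", i)
        for i, m in enumerate(doc.get("stationary_machines", []) or [])
    ]
    moving = [
        _machine_from_dict(m, "moving", i)
        for i, m in enumerate(doc.get("moving_machines", []) or [])
    ]

    workers = []
    for i, g in enumerate(doc.get("worker_groups", []) or []):
        label = g.get("label", f"group-{i}")
        context = f"worker_groups[{label}]"
        try:
            workers.append(
                WorkerGroup(
                    label=label,
                    subarea=_rect_from_dict(
                        _require(g, "subarea", context), f"{context}.subarea"
                    ),
                    n_walkers=int(g.get("n_walkers", 1)),
                    walk=_walk_from_dict(g.get("walk", {}), f"{context}.walk"),
                )
            )
        except ScenarioFormatError:
            raise
        except ValueError as exc:
            raise ScenarioFormatError(f"{context}: {exc}") from exc

    scenario = Scenario(
        area=area,
        barriers=barriers,
        stationary=stationary,
        moving=moving,
        worker_groups=workers,
    )
    scenario.validate()
    return scenario


def scenario_to_dict(
    scenario: Scenario,
    simulation: Optional[SimulationConfig] = None,
    exposure: Optional[ExposureConfig] = None,
) -> dict:
    """Serialize a scenario (and optional run settings) to a plain dict."""
    doc: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "area": {
            "width": scenario.area.width,
            "depth": scenario.area.depth,
            "grid_spacing": scenario.area.grid_spacing,
            "background_level": scenario.area.background_level,
            "working_period": scenario.area.working_period,
        },
        "barriers": [
            {
                **_rect_to_dict(b.region),
                "screening": b.screening.value,
                "reflective": b.reflective,
                "label": b.label,
            }
            for b in scenario.barriers
        ],
        "stationary_machines": [_machine_to_dict(m) for m in scenario.stationary],
        "moving_machines": [_machine_to_dict(m) for m in scenario.moving],
        "worker_groups": [
            {
                "label": g.label,
                "subarea": _rect_to_dict(g.subarea),
                "n_walkers": g.n_walkers,
                "walk": {
                    "max_step": g.walk.max_step,
                    "step_length_dist": g.walk.step_length_dist,
                    "boundary_policy": g.walk.boundary_policy,
                },
            }
            for g in scenario.worker_groups
        ],
    }
    if simulation is not None:
        doc["simulation"] = {
            "n_steps": simulation.n_steps,
            "seed": simulation.seed,
            "repeats": simulation.repeats,
            "record_steps": simulation.record_steps,
        }
    if exposure is not None:
        doc["exposure"] = {
            "exchange_rate": exposure.exchange_rate,
            "criterion_level": exposure.criterion_level,
            "criterion_duration": exposure.criterion_duration,
        }
    return doc


def read_scenario(path: str | Path) -> Scenario:
    """Read and validate a scenario file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return scenario_from_dict(doc)


def load_run_setup(
    path: str | Path,
) -> tuple[Scenario, SimulationConfig, ExposureConfig]:
    """Read a scenario file together with its run settings.

    Missing ``simulation`` / ``exposure`` sections fall back to defaults
    (1000 steps, seed 0; Q=3 dB, CL=90 dBA, 480 min).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    scenario = scenario_from_dict(doc)
    sim_doc = doc.get("simulation", {}) or {}
    sim = SimulationConfig(
        n_steps=int(sim_doc.get("n_steps", 1000)),
        seed=int(sim_doc.get("seed", 0)),
        repeats=int(sim_doc.get("repeats", 1)),
        record_steps=bool(sim_doc.get("record_steps", False)),
    )
    exp_doc = doc.get("exposure", {}) or {}
    exposure = ExposureConfig(
        exchange_rate=float(exp_doc.get("exchange_rate", 3.0)),
        criterion_level=float(exp_doc.get("criterion_level", 90.0)),
        criterion_duration=float(exp_doc.get("criterion_duration", 480.0)),
    )
    return scenario, sim, exposure


def write_scenario(
    scenario: Scenario,
    path: str | Path,
    simulation: Optional[SimulationConfig] = None,
    exposure: Optional[ExposureConfig] = None,
) -> None:
    """Serialize a scenario (plus optional run settings) to YAML."""
    doc = scenario_to_dict(scenario, simulation, exposure)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _random_rect(
    rng: np.random.Generator, width: float, depth: float, min_frac: float = 0.05
) -> RectRegion:
    w = rng.uniform(min_frac * width, 0.5 * width)
    d = rng.uniform(min_frac * depth, 0.5 * depth)
    return RectRegion(
        x0=rng.uniform(0.0, width - w),
        y0=rng.uniform(0.0, depth - d),
        width=w,
        depth=d,
    )


def _random_duty(rng: np.random.Generator) -> DutyCycleProbs:
    p_on = rng.uniform(0.3, 1.0)
    rest = 1.0 - p_on
    p_off = rng.uniform(0.0, rest)
    return DutyCycleProbs(p_on=p_on, p_off=p_off, p_idle=rest - p_off)


def generate_synthetic_scenario(
    n_stationary: int = 3,
    n_moving: int = 1,
    n_worker_groups: int = 1,
    n_barriers: int = 1,
    width: float = 100.0,
    depth: float = 70.0,
    seed: int = 0,
) -> Scenario:
    """Random but valid scenario for testing and benchmarking.

    Sound power levels are drawn uniformly on [95, 120] dBA — the span of
    the built-in machine inventory — with random duty-cycle probability
    vectors, random subareas/barriers inside the area, and a background
    level on [40, 55] dBA.  Reproducible from ``seed``.
    """
    if min(n_stationary, n_moving, n_worker_groups, n_barriers) < 0:
        raise ValueError("entity counts must be >= 0")
    rng = np.random.default_rng(seed)
    area = MappingArea(
        width=width,
        depth=depth,
        grid_spacing=1.0,
        background_level=float(rng.uniform(40.0, 55.0)),
        working_period=480.0,
    )
    stationary = [
        Machine(
            label=f"S{i + 1}",
            kind="stationary",
            lwa_full=float(rng.uniform(95.0, 120.0)),
            duty=_random_duty(rng),
            position=(float(rng.uniform(0, width)), float(rng.uniform(0, depth))),
        )
        for i in range(n_stationary)
    ]
    moving = [
        Machine(
            label=f"D{i + 1}",
            kind="moving",
            lwa_full=float(rng.uniform(95.0, 120.0)),
            duty=_random_duty(rng),
            subarea=_random_rect(rng, width, depth),
            walk=WalkParams(max_step=float(rng.uniform(1.0, 8.0))),
        )
        for i in range(n_moving)
    ]
    workers = [
        WorkerGroup(label=f"Group {i + 1}", subarea=_random_rect(rng, width, depth))
        for i in range(n_worker_groups)
    ]
    barriers = [
        Barrier(
            region=_random_rect(rng, width, depth, min_frac=0.02),
            screening=Screening.FULL if rng.random() < 0.5 else Screening.PARTIAL,
            reflective=bool(rng.random() < 0.5),
            label=f"B{i + 1}",
        )
        for i in range(n_barriers)
    ]
    return Scenario(
        area=area,
        barriers=barriers,
        stationary=stationary,
        moving=moving,
        worker_groups=workers,
    )
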