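"""Result export: CSV matrices, exposure reports, contour maps, manifest.

Grid CSVs are written row 0 = y = 0 (south), columns west→east, one row
per y-node, at full double precision so a re-read grid compares equal to
the in-memory one.  The run manifest embeds the scenario document, the
simulation settings and the software version — enough to replay the run
and reproduce every exported file.
"""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .engine import SimulationResult
from .exposure import (
    ExposureConfig,
    exposure_from_series,
    risk_zone_percentages,
)
from .scenario_io import scenario_to_dict

__all__ = ["export_results", "render_contour"]

_GRID_HEADER = (
    "# LAeq grid, dBA; row 0 = y = 0 (south), columns west -> east at "
    "{spacing} m spacing; shape {rows} rows x {cols} cols"
)


def _write_grid_csv(path: Path, grid: np.ndarray, spacing: float) -> None:
    header = _GRID_HEADER.format(
        spacing=spacing, rows=grid.shape[0], cols=grid.shape[1]
    )
    with open(path, "w") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, grid, delimiter=",", fmt="%.17g")


def read_grid_csv(path: str | Path) -> np.ndarray:
    """Re-read a grid CSV written by :func:`export_results`."""
    return np.loadtxt(path, delimiter=",", comments="#")


def render_contour(
    result: SimulationResult,
    path: str | Path,
    band_interval: float = 5.0,
    title: str = "Predicted LAeq",
) -> None:
    """Filled contour map of the LAeq grid with 5 dBA bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = result.grid
    lo = np.floor(result.laeq_grid.min() / band_interval) * band_interval
    hi = np.ceil(result.laeq_grid.max() / band_interval) * band_interval
    levels = np.arange(lo, hi + band_interval / 2, band_interval)
    if len(levels) < 2:
        levels = np.array([lo, lo + band_interval])
    fig, ax = plt.subplots(figsize=(8, 8 * len(grid.y_coords) / len(grid.x_coords)))
    cf = ax.contourf(
        grid.x_coords, grid.y_coords, result.laeq_grid, levels=levels, cmap="turbo"
    )
    cs = ax.contour(
        grid.x_coords, grid.y_coords, result.laeq_grid, levels=levels,
        colors="k", linewidths=0.4,
    )
    ax.clabel(cs, fmt="%.0f", fontsize=7)
    fig.colorbar(cf, ax=ax, label="LAeq, dBA")
    ax.set_xlabel("x, m")
    ax.set_ylabel("y, m")
    ax.set_title(title)
    ax.set_aspect("equal")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def export_results(
    result: SimulationResult,
    outdir: str | Path,
    exposure_config: Optional[ExposureConfig] = None,
    render: bool = True,
) -> dict[str, str]:
    """Write the full result file set and return the file inventory.

    Files: ``laeq_grid.csv``, ``worker_exposure.csv`` (step, group,
    walker, x, y, dBA), ``exposure_report.json`` (per-group LAeq, dose %,
    TWA over the scenario's working period), ``risk_zones.csv`` (integer
    band index per node) with percentages in ``risk_summary.json``,
    ``contour.png`` and ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exposure_config = exposure_config or ExposureConfig()
    scenario = result.scenario
    files: dict[str, str] = {}

    grid_path = outdir / "laeq_grid.csv"
    _write_grid_csv(grid_path, result.laeq_grid, result.grid.spacing)
    files["laeq_grid"] = grid_path.name

    worker_path = outdir / "worker_exposure.csv"
    with open(worker_path, "w") as fh:
        fh.write("step,group,walker,x,y,level_dba\n")
        for g in scenario.worker_groups:
            levels = result.worker_levels[g.label]
            pos = result.worker_positions[g.label]
            for step in range(levels.shape[0]):
                for w in range(levels.shape[1]):
                    fh.write(
                        f"{step},{g.label},{w},{pos[step, w, 0]:.6f},"
                        f"{pos[step, w, 1]:.6f},{levels[step, w]:.6f}\n"
                    )
    files["worker_exposure"] = worker_path.name

    report = {}
    for g in scenario.worker_groups:
        series = result.group_series(g.label)
        res = exposure_from_series(
            series, scenario.area.working_period, exposure_config
        )
        report[g.label] = {
            "laeq_dba": res.laeq,
            "dose_percent": res.dose,
            "twa_dba": res.twa,
            "duration_min": res.duration,
        }
    report_path = outdir / "exposure_report.json"
    report_path.write_text(json.dumps(report, indent=2))
    files["exposure_report"] = report_path.name

    zones = risk_zone_percentages(result.laeq_grid)
    zones_path = outdir / "risk_zones.csv"
    with open(zones_path, "w") as fh:
        fh.write(
            "# risk-zone band index per node (0=Safe .. 5=Extremely high risk); "
            "row 0 = y = 0 (south), columns west -> east\n"
        )
        np.savetxt(fh, zones.category_grid, delimiter=",", fmt="%d")
    files["risk_zones"] = zones_path.name
    summary_path = outdir / "risk_summary.json"
    summary_path.write_text(json.dumps(zones.percentages, indent=2))
    files["risk_summary"] = summary_path.name

    if render:
        contour_path = outdir / "contour.png"
        render_contour(result, contour_path)
        files["contour"] = contour_path.name

    manifest = {
        "software": {"name": "noisewalk", "version": __version__,
                     "python": platform.python_version()},
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "simulation": {
            "n_steps": result.config.n_steps,
            "seed": result.config.seed,
            "repeats": result.config.repeats,
        },
        "exposure": {
            "exchange_rate": exposure_config.exchange_rate,
            "criterion_level": exposure_config.criterion_level,
            "criterion_duration": exposure_config.criterion_duration,
        },
        "scenario": scenario_to_dict(scenario),
        "files": files,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    files["manifest"] = manifest_path.name
    return files
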