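"""Simulation step loop, LAeq aggregation, and the experiment harness."""

import numpy as np
import pytest

from noisewalk.acoustics import compute_field
from noisewalk.engine import (
    Scenario,
    SimulationConfig,
    WorkerGroup,
    aggregate_laeq,
    experiment_grid,
    run_simulation,
)
from noisewalk.geometry import MappingArea, RectRegion, mesh_grid
from noisewalk.machinery import DutyCycleProbs, Machine, WalkParams, sound_power_watts


def _stationary(label, lwa, pos, p=(1.0, 0.0, 0.0)):
    return Machine(label=label, kind="stationary", lwa_full=lwa,
                   duty=DutyCycleProbs(*p), position=pos)


def _moving(label, lwa, sub, p=(1.0, 0.0, 0.0), max_step=3.0):
    return Machine(label=label, kind="moving", lwa_full=lwa,
                   duty=DutyCycleProbs(*p), subarea=sub,
                   walk=WalkParams(max_step=max_step))


@pytest.fixture
def deterministic_scenario():
    """All-stationary, always-on machines: every step's field is identical."""
    area = MappingArea(30, 20, background_level=45.0)
    return Scenario(
        area=area,
        stationary=[
            _stationary("A", 105.0, (5.0, 5.0)),
            _stationary("B", 110.0, (22.0, 14.0)),
        ],
        worker_groups=[WorkerGroup("G", RectRegion(10, 5, 8, 8))],
    )


@pytest.fixture
def moving_scenario():
    area = MappingArea(40, 20, background_level=45.0)
    return Scenario(
        area=area,
        moving=[_moving("D", 108.0, RectRegion(2, 2, 16, 16))],
        worker_groups=[WorkerGroup("G", RectRegion(25, 5, 10, 10))],
    )


class TestAggregateLaeq:
    def test_constant(self):
        assert aggregate_laeq([80.0] * 5) == pytest.approx(80.0)

    def test_two_levels(self):
        # 10·log10((1e8 + 1e9)/2)
        assert aggregate_laeq([80.0, 90.0]) == pytest.approx(87.4036, abs=1e-3)

    def test_single(self):
        assert aggregate_laeq([73.2]) == pytest.approx(73.2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_laeq([])


class TestRunSimulation:
    def test_deterministic_limit_equals_single_field(self, deterministic_scenario):
        """With p_on = 1 everywhere and no movement the LAeq grid is the
        single-step SPL field."""
        sc = deterministic_scenario
        result = run_simulation(sc, SimulationConfig(n_steps=5, seed=3))
        grid = mesh_grid(sc.area)
        sources = [(m.position, sound_power_watts(m.lwa_full)) for m in sc.stationary]
        field = compute_field(sources, [], grid, sc.area.background_level)
        assert np.max(np.abs(result.laeq_grid - field.levels)) < 1e-12
        assert np.max(result.std_grid) < 1e-9

    def test_seed_reproducibility_bit_identical(self, moving_scenario):
        cfg = SimulationConfig(n_steps=40, seed=77)
        a = run_simulation(moving_scenario, cfg)
        b = run_simulation(moving_scenario, cfg)
        assert np.array_equal(a.laeq_grid, b.laeq_grid)
        assert np.array_equal(a.worker_levels["G"], b.worker_levels["G"])
        assert np.array_equal(a.worker_positions["G"], b.worker_positions["G"])

    def test_different_seeds_differ(self, moving_scenario):
        a = run_simulation(moving_scenario, SimulationConfig(n_steps=40, seed=1))
        b = run_simulation(moving_scenario, SimulationConfig(n_steps=40, seed=2))
        assert not np.array_equal(a.laeq_grid, b.laeq_grid)

    def test_confined_machine_shapes_the_map(self):
        """A machine confined to the left half leaves the left-half
        centroid louder than the mirrored right-half point."""
        area = MappingArea(40, 20, background_level=45.0)
        sc = Scenario(area=area,
                      moving=[_moving("D", 108.0, RectRegion(0, 0, 20, 20))])
        result = run_simulation(sc, SimulationConfig(n_steps=1500, seed=5))
        left = result.laeq_grid[10, 10]   # (x=10, y=10): left-half centroid
        right = result.laeq_grid[10, 30]  # mirrored point in the right half
        assert left > right

    def test_per_node_bounds_and_series_length(self, moving_scenario):
        result = run_simulation(moving_scenario, SimulationConfig(n_steps=60, seed=9))
        assert np.all(result.laeq_grid >= result.min_grid - 1e-12)
        assert np.all(result.laeq_grid <= result.max_grid + 1e-12)
        assert np.all(result.laeq_grid >= moving_scenario.area.background_level - 1e-12)
        assert result.worker_levels["G"].shape == (60, 1)
        series = result.group_series("G")
        assert series.shape == (60,)

    def test_step_records(self, moving_scenario):
        cfg = SimulationConfig(n_steps=10, seed=1, record_steps=True)
        result = run_simulation(moving_scenario, cfg)
        assert len(result.step_records) == 10
        rec = result.step_records[4]
        assert len(rec.duty_states) == 1
        assert len(rec.machine_positions) == 1
        # recorded worker level equals the stored exposure series entry
        assert rec.worker_levels[0][0] == result.worker_levels["G"][4, 0]

    def test_empty_scenario_rejected(self):
        sc = Scenario(area=MappingArea(10, 10))
        with pytest.raises(ValueError, match="at least one machine"):
            run_simulation(sc, SimulationConfig(n_steps=1))

    def test_validation_lists_offenders(self):
        area = MappingArea(10, 10)
        sc = Scenario(
            area=area,
            stationary=[_stationary("far", 100.0, (50.0, 50.0))],
            worker_groups=[WorkerGroup("G", RectRegion(8, 8, 5, 5))],
        )
        with pytest.raises(ValueError) as err:
            run_simulation(sc, SimulationConfig(n_steps=1))
        assert "far" in str(err.value) and "G" in str(err.value)


class TestExperimentGrid:
    def test_prediction_count(self, moving_scenario):
        table = experiment_grid(
            moving_scenario, step_settings=[10, 20], repeats=2,
            receiver_points=[(5.0, 5.0), (30.0, 10.0), (20.0, 2.0)],
        )
        assert len(table) == 3 * 2 * 2
        assert set(table.columns) == {"receiver", "x", "y", "n_steps", "repeat", "laeq"}

    def test_single_cell(self, moving_scenario):
        table = experiment_grid(moving_scenario, [15], 1, [(5.0, 5.0)])
        assert len(table) == 1

    def test_deterministic_from_base_seed(self, moving_scenario):
        a = experiment_grid(moving_scenario, [10], 2, [(5.0, 5.0)], base_seed=4)
        b = experiment_grid(moving_scenario, [10], 2, [(5.0, 5.0)], base_seed=4)
        assert a.equals(b)

    def test_more_steps_reduce_repeat_scatter(self):
        """Between-repeat std of predicted LAeq shrinks from 100 to 1500
        steps for a moving-machine scenario (Monte-Carlo convergence)."""
        area = MappingArea(20, 12, grid_spacing=2.0, background_level=45.0)
        sc = Scenario(area=area,
                      moving=[_moving("D", 105.0, RectRegion(1, 1, 10, 10))])
        receivers = [(4.0, 4.0), (16.0, 4.0), (10.0, 10.0)]
        table = experiment_grid(sc, [100, 1500], 10, receivers, base_seed=8)
        scatter = (
            table.groupby(["n_steps", "receiver"])["laeq"].std().groupby("n_steps").mean()
        )
        assert scatter[1500] < scatter[100]
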