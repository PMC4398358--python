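"""Hemispherical propagation, barrier corrections and SPL field assembly."""

import math

import numpy as np
import pytest

from noisewalk.acoustics import (
    I0,
    compute_field,
    euclidean_distance,
    interpolate_level,
    path_correction_db,
    source_intensity,
    source_level,
    spl_from_intensity,
    SPLField,
)
from noisewalk.geometry import (
    Barrier,
    MappingArea,
    RectRegion,
    Screening,
    mesh_grid,
    near_facade,
    segment_blocked,
)
from noisewalk.machinery import sound_power_watts
from noisewalk.scenario_io import generate_synthetic_scenario


@pytest.mark.parametrize(
    "p, q, d",
    [((0, 0), (3, 4), 5.0), ((2, 2), (2, 2), 0.0), ((1, 2), (4, 6), 5.0)],
)
def test_euclidean_distance(p, q, d):
    assert euclidean_distance(p, q) == pytest.approx(d)


class TestSourceIntensity:
    def test_unit_intensity_at_one_metre(self):
        assert source_intensity(2 * math.pi, 1.0) == pytest.approx(1.0)

    def test_zero_power(self):
        assert source_intensity(0.0, 7.0) == 0.0

    def test_inverse_square(self):
        assert source_intensity(1.0, 20.0) == pytest.approx(source_intensity(1.0, 10.0) / 4)

    def test_distance_clamp(self):
        assert source_intensity(1.0, 0.0, min_r=1.0) == source_intensity(1.0, 1.0)


class TestSplFromIntensity:
    @pytest.mark.parametrize("i, level", [(1e-12, 0.0), (1.0, 120.0), (1e-4, 80.0)])
    def test_reference_levels(self, i, level):
        assert spl_from_intensity(i) == pytest.approx(level)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            spl_from_intensity(0.0)


class TestPathCorrection:
    barriers = [
        Barrier(RectRegion(4, -1, 2, 2), Screening.FULL, reflective=True),
        Barrier(RectRegion(4, 5, 2, 2), Screening.PARTIAL),
    ]

    def test_clear_path(self):
        c = path_correction_db((0, 10), (10, 10), [])
        assert (c.attenuation, c.reflection) == (0.0, 0.0)

    def test_full_screening(self):
        c = path_correction_db((0, 0), (10, 0), self.barriers)
        assert c.attenuation == -10.0

    def test_partial_screening(self):
        c = path_correction_db((0, 6), (10, 6), self.barriers)
        assert c.attenuation == -5.0

    def test_facade_reflection(self):
        # receiver 0.5 m from the reflective barrier's east face, clear path
        c = path_correction_db((10, 10), (6.5, 0.5), self.barriers)
        assert c.reflection == 3.0


class TestComputeField:
    def test_background_only_uniform(self):
        grid = mesh_grid(MappingArea(20, 10, background_level=52.2))
        field = compute_field([], [], grid, background_level=52.2)
        assert np.allclose(field.levels, 52.2)

    def test_single_source_closed_form(self):
        """A 103.9 dBA source observed at 10 m reads L_WA − 10·log10(2πr²)
        ≈ 75.9 dBA when the background is negligible."""
        grid = mesh_grid(MappingArea(20, 10))
        power = sound_power_watts(103.9)
        field = compute_field([((0.0, 0.0), power)], [], grid, background_level=0.0)
        expected = 103.9 - 10 * math.log10(2 * math.pi * 10.0**2)
        assert field.levels[0, 10] == pytest.approx(expected, abs=1e-6)
        assert round(expected, 1) == 75.9

    def test_distance_doubling_loses_6dB(self):
        grid = mesh_grid(MappingArea(50, 4))
        field = compute_field([((0.0, 0.0), 1.0)], [], grid, background_level=0.0)
        drop = field.levels[0, 10] - field.levels[0, 20]
        assert drop == pytest.approx(10 * math.log10(4), abs=1e-6)  # 6.02 dB

    def test_removing_source_never_raises_levels(self):
        grid = mesh_grid(MappingArea(30, 20))
        sources = [((5.0, 5.0), 0.01), ((20.0, 15.0), 0.05), ((12.0, 9.0), 0.001)]
        full = compute_field(sources, [], grid, background_level=45.0)
        reduced = compute_field(sources[:-1], [], grid, background_level=45.0)
        assert np.all(full.levels >= reduced.levels - 1e-12)

    def test_energetic_dominance(self):
        grid = mesh_grid(MappingArea(30, 20))
        sources = [((5.0, 5.0), 0.01), ((22.0, 12.0), 0.05)]
        bg = 48.0
        total = compute_field(sources, [], grid, bg)
        assert np.all(total.levels >= bg - 1e-12)
        for src in sources:
            single = compute_field([src], [], grid, background_level=0.0)
            # background-free single-source level never exceeds the total
            assert np.all(total.levels >= single.levels - 1e-9)

    def test_matches_scalar_loop_oracle(self):
        """Vectorized field equals an independent per-node, per-source
        scalar loop to <1e-9 dB on a random scenario with barriers."""
        scenario = generate_synthetic_scenario(
            n_stationary=3, n_moving=2, n_barriers=2, width=30, depth=20, seed=42
        )
        grid = mesh_grid(scenario.area)
        rng = np.random.default_rng(0)
        sources = []
        for m in scenario.stationary:
            sources.append((m.position, sound_power_watts(m.lwa_full)))
        for m in scenario.moving:
            p = (rng.uniform(m.subarea.x0, m.subarea.x1),
                 rng.uniform(m.subarea.y0, m.subarea.y1))
            sources.append((p, sound_power_watts(m.lwa_full)))
        bg = scenario.area.background_level
        field = compute_field(sources, scenario.barriers, grid, bg)

        # independent oracle: scalar per-node accumulation
        for iy in range(0, grid.n_rows, 3):
            for ix in range(0, grid.n_cols, 4):
                rcv = (grid.x_coords[ix], grid.y_coords[iy])
                lin = 10.0 ** (bg / 10.0)
                for src, power in sources:
                    r = max(euclidean_distance(src, rcv), grid.spacing)
                    level = 10 * math.log10(power / (2 * math.pi * r * r) / I0)
                    att = {"clear": 0, "partial": -5, "full": -10}[
                        segment_blocked(src, rcv, scenario.barriers).value
                    ]
                    refl = 3.0 if near_facade(rcv, scenario.barriers) else 0.0
                    lin += 10.0 ** ((level + att + refl) / 10.0)
                assert field.levels[iy, ix] == pytest.approx(
                    10 * math.log10(lin), abs=1e-9
                )

    def test_source_level_barrier_deltas_exact(self):
        """Per-source SPL drops by exactly 10 dB (full) / 5 dB (partial)
        and rises by exactly 3 dB near a reflective façade."""
        power = sound_power_watts(110.0)
        src, rcv = (0.0, 0.0), (20.0, 0.0)
        free = source_level(power, src, rcv)
        full = [Barrier(RectRegion(9, -1, 2, 2), Screening.FULL)]
        partial = [Barrier(RectRegion(9, -1, 2, 2), Screening.PARTIAL)]
        wall = [Barrier(RectRegion(21, -5, 2, 10), Screening.FULL, reflective=True)]
        assert source_level(power, src, rcv, full) - free == -10.0
        assert source_level(power, src, rcv, partial) - free == -5.0
        assert source_level(power, src, rcv, wall) - free == 3.0


class TestInterpolateLevel:
    def _field(self, levels):
        levels = np.asarray(levels, dtype=float)
        area = MappingArea(levels.shape[1] - 1.0, levels.shape[0] - 1.0)
        return SPLField(grid=mesh_grid(area), levels=levels)

    def test_node_value(self):
        field = self._field([[70, 72], [74, 76]])
        assert interpolate_level(field, (1.0, 1.0)) == 76.0

    def test_uniform_field(self):
        field = self._field(np.full((4, 5), 63.0))
        assert interpolate_level(field, (2.3, 1.7)) == pytest.approx(63.0)

    def test_cell_centre_bilinear(self):
        # nodes (70, 70) on the south row, (80, 80) on the north row
        field = self._field([[70, 70], [80, 80]])
        assert interpolate_level(field, (0.5, 0.5)) == pytest.approx(75.0)

    def test_outside_grid_rejected(self):
        field = self._field([[70, 70], [80, 80]])
        with pytest.raises(ValueError):
            interpolate_level(field, (1.5, 0.5))
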