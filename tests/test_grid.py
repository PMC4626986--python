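"""Road grid: effective traversal times, shortest-time fields, routes."""

import networkx as nx
import numpy as np
import pytest

from emsim import (
    GridError,
    PenaltyOverlay,
    RoadGrid,
    UnreachableError,
    make_random_scenario,
)


def overlay(cause, factor=1.0, cells=None, start=0.0, end=1e9):
    return PenaltyOverlay(cells=cells, factor=factor, start=start, end=end,
                          cause=cause)


SNOW = overlay("snow", 3.0)
RAIN = overlay("rain", 2.0)
CONGESTION = overlay("congestion")
FESTIVITY = overlay("festivity")


def brute_force_time(grid, source, target, overlays=(), stress=1.0, t=0.0):
    """Independent oracle: exhaustive enumeration of all simple paths.

    Path cost = sum of effective traversal times of the cells entered.
    """
    dg = nx.DiGraph()
    w = {c: grid.effective_traversal_time(c, t, overlays, stress)
         for c in grid.road_cells}
    for r, c in grid.road_cells:
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            nb = (r + dr, c + dc)
            if grid.is_road(nb):
                dg.add_edge((r, c), nb, weight=w[nb])
    if source == target:
        return 0.0
    best = np.inf
    try:
        for path in nx.all_simple_paths(dg, source, target):
            cost = sum(w[c] for c in path[1:])
            best = min(best, cost)
    except nx.NodeNotFound:
        return np.inf
    return best


class TestEffectiveTraversal:
    def test_weather_factor_applies(self, line_grid):
        assert line_grid.effective_traversal_time((0, 3), overlays=[SNOW]) == 3.0

    def test_no_overlay_is_static(self, line_grid):
        assert line_grid.effective_traversal_time((0, 3)) == 1.0

    def test_weather_and_congestion_compose_multiplicatively(self, line_grid):
        got = line_grid.effective_traversal_time((0, 3), overlays=[SNOW, CONGESTION])
        assert got == 6.0

    def test_simultaneous_weather_combines_by_max(self, line_grid):
        got = line_grid.effective_traversal_time((0, 3), overlays=[SNOW, RAIN])
        assert got == 3.0

    def test_congestion_and_festivity_each_double(self, line_grid):
        got = line_grid.effective_traversal_time(
            (0, 3), overlays=[CONGESTION, FESTIVITY]
        )
        assert got == 4.0

    def test_stress_scales(self, line_grid):
        assert line_grid.effective_traversal_time((0, 3), stress=2.0) == 2.0

    def test_off_road_is_infinite(self, line_grid):
        assert line_grid.effective_traversal_time((0, 100)) == np.inf

    def test_inactive_overlay_ignored(self, line_grid):
        past = overlay("snow", 3.0, start=0.0, end=10.0)
        assert line_grid.effective_traversal_time((0, 3), t=20.0, overlays=[past]) == 1.0

    def test_local_overlay_only_affects_its_cells(self, line_grid):
        local = overlay("congestion", cells=frozenset({(0, 2)}))
        assert line_grid.effective_traversal_time((0, 2), overlays=[local]) == 2.0
        assert line_grid.effective_traversal_time((0, 3), overlays=[local]) == 1.0


class TestShortestTimeField:
    def test_straight_road_distances(self, line_grid):
        f = line_grid.shortest_time_field((0, 0))
        for i in range(11):
            assert f.at((0, i)) == pytest.approx(i)

    def test_source_is_zero(self, line_grid):
        assert line_grid.shortest_time_field((0, 4)).at((0, 4)) == 0.0

    def test_uniform_overlay_scales_field(self, line_grid):
        base = line_grid.shortest_time_field((0, 0)).values
        snowy = line_grid.shortest_time_field((0, 0), overlays=[SNOW]).values
        assert np.allclose(snowy, 3.0 * base)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_enumeration(self, seed):
        grid = make_random_scenario(seed, rows=5, cols=5).grid
        src = grid.hub
        ovs = [overlay("rain", 2.0),
               overlay("congestion", cells=frozenset(grid.road_cells[:3]))]
        f = grid.shortest_time_field(src, overlays=ovs)
        for cell in grid.road_cells:
            assert f.at(cell) == pytest.approx(
                brute_force_time(grid, src, cell, overlays=ovs), rel=1e-9
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_overlay_monotonicity(self, seed):
        grid = make_random_scenario(seed, rows=6, cols=6).grid
        base = grid.shortest_time_field(grid.hub).values
        extra = overlay("congestion", cells=frozenset(grid.road_cells[::2]))
        penal = grid.shortest_time_field(grid.hub, overlays=[extra]).values
        finite = np.isfinite(base)
        assert (penal[finite] >= base[finite] - 1e-12).all()

    def test_symmetry_on_uniform_grid(self):
        cells = [(r, c) for r in range(4) for c in range(4)]
        contents = {c: {"road"} for c in cells}
        contents[(0, 0)] |= {"hub", "hospital"}
        grid = RoadGrid((4, 4), contents, {c: 1.0 for c in cells})
        fa = grid.shortest_time_field((0, 0))
        fb = grid.shortest_time_field((3, 2))
        assert fa.at((3, 2)) == pytest.approx(fb.at((0, 0)))


class TestRoute:
    def test_self_route_is_empty(self, line_grid):
        path, dur = line_grid.route((0, 3), (0, 3))
        assert path == [] and dur == 0.0

    def test_straight_route_duration(self, line_grid):
        path, dur = line_grid.route((0, 0), (0, 8))
        assert dur == pytest.approx(8.0)
        assert path == [(0, c) for c in range(1, 9)]

    @pytest.mark.parametrize("seed", range(10))
    def test_route_duration_matches_field(self, seed):
        grid = make_random_scenario(seed, rows=6, cols=6).grid
        rng = np.random.default_rng(seed)
        cells = grid.road_cells
        f = grid.shortest_time_field(grid.hub)
        for _ in range(10):
            dst = cells[rng.integers(len(cells))]
            _, dur = grid.route(grid.hub, dst)
            assert dur == pytest.approx(f.at(dst))

    def test_route_is_deterministic(self):
        cells = [(r, c) for r in range(3) for c in range(3)]
        contents = {c: {"road"} for c in cells}
        contents[(0, 0)] |= {"hub", "hospital"}
        grid = RoadGrid((3, 3), contents, {c: 1.0 for c in cells})
        paths = {tuple(grid.route((0, 0), (2, 2))[0]) for _ in range(5)}
        assert len(paths) == 1

    def test_unreachable_raises_distinct_error(self):
        cells = [(0, 0), (0, 1), (0, 3), (0, 4)]
        contents = {c: {"road"} for c in cells}
        contents[(0, 0)] |= {"hub", "hospital"}
        # (0,3)-(0,4) are road but disconnected from the hub: invalid grid
        with pytest.raises(GridError):
            RoadGrid((1, 5), contents, {c: 1.0 for c in cells})

    def test_route_endpoint_validation(self, line_grid):
        with pytest.raises(GridError):
            line_grid.route((0, 0), (0, 99))


class TestGridValidation:
    def test_exactly_one_hub_required(self):
        cells = [(0, 0), (0, 1)]
        contents = {(0, 0): {"road", "hospital"}, (0, 1): {"road"}}
        with pytest.raises(GridError, match="hub"):
            RoadGrid((1, 2), contents, {c: 1.0 for c in cells})

    def test_hospital_required(self):
        contents = {(0, 0): {"road", "hub"}, (0, 1): {"road"}}
        with pytest.raises(GridError, match="hospital"):
            RoadGrid((1, 2), contents, {(0, 0): 1.0, (0, 1): 1.0})

    def test_nonpositive_traversal_rejected(self):
        contents = {(0, 0): {"road", "hub", "hospital"}}
        with pytest.raises(GridError):
            RoadGrid((1, 1), contents, {(0, 0): 0.0})
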