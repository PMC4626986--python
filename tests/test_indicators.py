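"""Coverage curves, town coverage, occupation, rescue fields, averaging."""

import numpy as np
import pandas as pd
import pytest

from emsim import (
    AmbulanceState,
    IsochroneField,
    availability_vs_coverage,
    coverage_curve,
    dynamic_rescue_field,
    occupation,
    phi_k,
    pi_k,
    time_average,
)
from emsim.indicators import IndicatorError
from emsim.scenario import TownRecord

K = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0)


def static_iso(grid, thresholds=K):
    return IsochroneField(
        values=grid.shortest_time_field(grid.hub).values, thresholds=thresholds
    )


class TestDynamicRescueField:
    def test_all_free_at_hub_equals_static(self, line_grid):
        units = [AmbulanceState(i, cell=line_grid.hub) for i in range(2)]
        f = dynamic_rescue_field(line_grid, units, now=0.0)
        assert np.array_equal(
            f.values, line_grid.shortest_time_field(line_grid.hub).values
        )

    def test_single_busy_unit_adds_remaining_wait(self, line_grid):
        u = AmbulanceState(0, cell=(0, 5), stage="to_hospital",
                           availability_time=12.0,
                           availability_cell=line_grid.hub)
        f = dynamic_rescue_field(line_grid, [u], now=0.0)
        static = line_grid.shortest_time_field(line_grid.hub).values
        finite = np.isfinite(static)
        assert np.allclose(f.values[finite], static[finite] + 12.0)

    def test_free_unit_dominates_where_closer(self, line_grid):
        free = AmbulanceState(0, cell=(0, 10))
        busy = AmbulanceState(1, cell=(0, 0), stage="prep",
                              availability_time=100.0,
                              availability_cell=line_grid.hub)
        f = dynamic_rescue_field(line_grid, [free, busy], now=0.0)
        # only the free unit counts: field measured from (0,10)
        assert f.at((0, 10)) == 0.0
        assert f.at((0, 0)) == pytest.approx(10.0)

    def test_dynamic_never_below_static(self, line_grid):
        u = AmbulanceState(0, cell=(0, 3), stage="returning",
                           availability_time=7.0,
                           availability_cell=line_grid.hub)
        f = dynamic_rescue_field(line_grid, [u], now=0.0)
        static = line_grid.shortest_time_field(line_grid.hub).values
        finite = np.isfinite(static)
        assert (f.values[finite] >= static[finite] - 1e-12).all()

    def test_no_units_rejected(self, line_grid):
        with pytest.raises(IndicatorError):
            dynamic_rescue_field(line_grid, [], now=0.0)


class TestPopulationCoverage:
    def test_fixture_static_curve_hits_published_marks(self, avila, avila_static_field):
        field = IsochroneField(values=avila_static_field.values, thresholds=K)
        curve = coverage_curve(field, avila.towns, K)
        phis = curve.as_dict()
        assert round(100 * phis[10.0]) == 75
        assert phis[50.0] == 1.0
        assert phis[60.0] == 1.0

    def test_curve_monotone_and_bounded(self, avila, avila_static_field):
        field = IsochroneField(values=avila_static_field.values, thresholds=K)
        phis = coverage_curve(field, avila.towns, K).phi
        assert (np.diff(phis) >= 0).all()
        assert ((phis >= 0) & (phis <= 1)).all()

    def test_unreachable_field_gives_zero(self, avila):
        field = IsochroneField(values=np.full(avila.grid.shape, np.inf), thresholds=K)
        for k in K:
            assert phi_k(field, avila.towns, k) == 0.0

    def test_zero_population_rejected(self, line_grid):
        field = static_iso(line_grid)
        with pytest.raises(Exception):
            TownRecord(name="ghost", cell=(0, 8), static_population=0.0)
        with pytest.raises(IndicatorError):
            phi_k(field, [], 10.0)


class TestTownCoverage:
    def test_constant_coverage(self):
        assert pi_k([(0.0, 5.0)], k=10.0, frame=(0.0, 100.0)) == 1.0
        assert pi_k([(0.0, 50.0)], k=10.0, frame=(0.0, 100.0)) == 0.0

    def test_half_frame_covered(self):
        timeline = [(0.0, 5.0), (50.0, 25.0)]
        assert pi_k(timeline, k=10.0, frame=(0.0, 100.0)) == pytest.approx(0.5)

    def test_static_town_bands_from_fixture(self, avila, avila_static_field):
        frame = (0.0, 1000.0)
        by_name = {t.name: t for t in avila.towns}
        cap = [(0.0, avila_static_field.at(by_name["Avila"].cell))]
        assert all(pi_k(cap, k, frame) == 1.0 for k in K)
        nav = [(0.0, avila_static_field.at(by_name["Navaluenga"].cell))]
        assert pi_k(nav, 30.0, frame) == 0.0
        assert pi_k(nav, 40.0, frame) == 1.0


class TestOccupation:
    def test_zero_accidents_means_fully_free(self):
        rep = occupation({0: []}, horizon=1000.0, n_units=1)
        assert rep.fractions.loc[0, "free"] == 1.0
        assert rep.availability == 1.0

    def test_even_quarters_scripted_log(self):
        log = {0: [
            (0.0, 250.0, "prep"),
            (250.0, 375.0, "to_scene"),
            (375.0, 500.0, "returning"),
            (500.0, 750.0, "on_scene"),
        ]}
        rep = occupation(log, horizon=1000.0, n_units=1)
        row = rep.fractions.loc[0]
        assert row["preparation"] == pytest.approx(0.25)
        assert row["travelling"] == pytest.approx(0.25)
        assert row["assistance"] == pytest.approx(0.25)
        assert row["free"] == pytest.approx(0.25)

    @pytest.mark.parametrize("seed", range(5))
    def test_fractions_sum_to_one_on_random_logs(self, seed):
        rng = np.random.default_rng(seed)
        stages = ["prep", "to_scene", "on_scene", "to_hospital", "at_hospital",
                  "returning"]
        log, t = [], 0.0
        while t < 800.0:
            for s in stages:
                d = rng.uniform(1, 30)
                log.append((t, t + d, s))
                t += d
            t += rng.uniform(0, 50)
        rep = occupation({0: log}, horizon=1000.0, n_units=1)
        assert rep.fractions.loc[0].sum() == pytest.approx(1.0, abs=1e-9)

    def test_overlapping_log_rejected(self):
        log = {0: [(0.0, 10.0, "prep"), (5.0, 15.0, "to_scene")]}
        with pytest.raises(IndicatorError):
            occupation(log, horizon=100.0, n_units=1)


class TestTimeAverage:
    def test_constant_timeline_is_identity(self):
        assert time_average([(0.0, 7.5)], (0.0, 10.0)) == 7.5

    def test_two_halves_average(self):
        assert time_average([(0.0, 2.0), (5.0, 4.0)], (0.0, 10.0)) == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_riemann_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ts = np.sort(rng.uniform(0, 100, size=20))
        ts[0] = 0.0
        vals = rng.uniform(-5, 5, size=20)
        timeline = list(zip(ts, vals))
        frame = (0.0, 100.0)
        # oracle: fine-grained left Riemann sum
        xs = np.linspace(0, 100, 200_001)[:-1]
        y = vals[np.searchsorted(ts, xs, side="right") - 1]
        assert time_average(timeline, frame) == pytest.approx(y.mean(), abs=1e-3)

    def test_chaining_subframes(self):
        timeline = [(0.0, 1.0), (3.0, 5.0), (7.0, 2.0)]
        whole = time_average(timeline, (0.0, 10.0))
        parts = (
            time_average(timeline, (0.0, 4.0)) * 4
            + time_average(timeline, (4.0, 10.0)) * 6
        ) / 10
        assert whole == pytest.approx(parts)

    def test_empty_timeline_rejected(self):
        with pytest.raises(IndicatorError):
            time_average([], (0.0, 1.0))

    def test_vector_valued_timeline(self):
        timeline = [(0.0, np.array([1.0, 2.0])), (5.0, np.array([3.0, 4.0]))]
        out = time_average(timeline, (0.0, 10.0))
        assert np.allclose(out, [2.0, 3.0])


class TestAvailabilityVsCoverage:
    class _Res:
        def __init__(self, avail, phi):
            self.availability = avail
            self.mean_phi = phi

    def test_single_configuration_one_row(self):
        table = availability_vs_coverage(
            {1: self._Res(0.5, {10.0: 0.4, 60.0: 0.7})}
        )
        assert len(table) == 1
        assert table.loc[1, "availability"] == 0.5
        assert table.loc[1, "phi_60"] == 0.7

    def test_rows_sorted_by_ambulance_count(self):
        table = availability_vs_coverage(
            {2: self._Res(0.8, {60.0: 0.9}), 1: self._Res(0.6, {60.0: 0.7})}
        )
        assert list(table.index) == [1, 2]
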