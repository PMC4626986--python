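"""Bundle round-trips, validation errors, indicator export, GeoJSON bands."""

import numpy as np
import pandas as pd
import pytest

from emsim import (
    BundleError,
    IsochroneField,
    export_indicators,
    export_isochrone_bands,
    load_indicators,
    load_scenario,
    make_random_scenario,
    replicate,
    save_scenario,
)
from emsim.fixtures import make_avila_like_scenario
from emsim.scenario import ScenarioError


class TestBundleRoundTrip:
    def test_fixture_bundle_loads_with_expected_shape(self, avila, tmp_path):
        save_scenario(avila, tmp_path / "bundle")
        sc = load_scenario(tmp_path / "bundle")
        assert sc.ambulance_count == 1
        assert len(sc.accident_rates.segments) == 18
        named = [t for t in sc.towns if "synthetic" not in t.name]
        assert len(named) == 6
        assert sc.thresholds == (10, 20, 30, 40, 50, 60)

    @pytest.mark.parametrize("seed", [0, 3])
    def test_load_export_is_identity(self, seed, tmp_path):
        sc = make_random_scenario(seed)
        save_scenario(sc, tmp_path / "b")
        assert load_scenario(tmp_path / "b") == sc

    def test_avila_round_trip_identity(self, avila, tmp_path):
        save_scenario(avila, tmp_path / "b")
        assert load_scenario(tmp_path / "b") == avila

    def test_missing_table_named_in_error(self, avila, tmp_path):
        save_scenario(avila, tmp_path / "b")
        (tmp_path / "b" / "meteorology.csv").unlink()
        with pytest.raises(BundleError, match="meteorology.csv"):
            load_scenario(tmp_path / "b")

    def test_empty_accident_table_is_valid(self, avila, tmp_path):
        from emsim import AccidentRateTable

        sc = avila.with_(accident_rates=AccidentRateTable(rates={}, segment_cells={}))
        save_scenario(sc, tmp_path / "b")
        loaded = load_scenario(tmp_path / "b")
        assert loaded.accident_rates.segments == []

    def test_subunit_weather_factor_rejected(self, avila, tmp_path):
        save_scenario(avila, tmp_path / "b")
        p = tmp_path / "b" / "weather_events.csv"
        df = pd.read_csv(p)
        df["Penalty factor"] = df["Penalty factor"].astype(float)
        df.loc[df["Event"] == "snow", "Penalty factor"] = 0.5
        df.to_csv(p, index=False)
        with pytest.raises(BundleError, match="snow"):
            load_scenario(tmp_path / "b")

    def test_negative_rate_rejected_with_offenders(self, avila, tmp_path):
        save_scenario(avila, tmp_path / "b")
        p = tmp_path / "b" / "accidents.csv"
        df = pd.read_csv(p)
        df.loc[df["Roads"] == "N-110", "MAR"] = -2
        df.to_csv(p, index=False)
        with pytest.raises(BundleError, match="N-110"):
            load_scenario(tmp_path / "b")

    def test_town_off_grid_rejected(self, avila, tmp_path):
        save_scenario(avila, tmp_path / "b")
        p = tmp_path / "b" / "towns.csv"
        df = pd.read_csv(p)
        df.loc[0, "col"] = 999
        df.to_csv(p, index=False)
        with pytest.raises(ScenarioError):
            load_scenario(tmp_path / "b")


class TestIndicatorExport:
    def test_round_trip_is_bit_exact(self, tmp_path):
        sc = make_random_scenario(1, horizon_days=7)
        rs = replicate(sc, n=2, master_seed=1)
        export_indicators(rs, tmp_path / "out")
        loaded = load_indicators(tmp_path / "out")
        for i, k in enumerate(rs.thresholds):
            col = f"phi_{int(k)}"
            for j, r in enumerate(rs.results):
                assert loaded["phi"].loc[str(j), col] == r.phi[k]
        assert loaded["phi"].loc["mean", "phi_60"] == np.mean(
            [r.phi[60.0] for r in rs.results]
        )
        occ = loaded["occupation"]
        assert occ[["travelling", "preparation", "assistance", "free"]].sum(
            axis=1
        ).round(9).eq(1.0).all()

    def test_empty_results_rejected(self, tmp_path):
        from emsim import ReplicationSet

        with pytest.raises(ValueError):
            export_indicators(ReplicationSet([], (10.0,)), tmp_path)


class TestIsochroneBands:
    def line_field(self, grid, thresholds):
        return IsochroneField(
            values=grid.shortest_time_field(grid.hub).values, thresholds=thresholds
        )

    def test_line_splits_into_two_bands(self, line_grid):
        field = self.line_field(line_grid, (5.0, 10.0))
        fc = export_isochrone_bands(field)
        by_label = {f["properties"]["label"]: f["properties"]["cells"]
                    for f in fc["features"]}
        # 11 road cells (0..10 min) on a 1x11 grid: 6 within 5 min incl. the
        # hub, 5 in (5,10]; the rest of the lattice is unreachable
        assert by_label["(0, 5] min"] == 6
        assert by_label["(5, 10] min"] == 5

    def test_uniform_field_single_band(self):
        field = IsochroneField(values=np.full((3, 3), 55.0),
                               thresholds=(10, 20, 30, 40, 50, 60))
        fc = export_isochrone_bands(field)
        assert len(fc["features"]) == 1
        assert fc["features"][0]["properties"]["label"] == "(50, 60] min"

    def test_fixture_capital_in_first_band(self, avila, avila_static_field):
        field = IsochroneField(values=avila_static_field.values,
                               thresholds=avila.thresholds)
        capital = next(t for t in avila.towns if t.name == "Avila")
        assert field.band_index(capital.cell) == 0

    def test_bands_partition_the_grid(self, avila, avila_static_field):
        field = IsochroneField(values=avila_static_field.values,
                               thresholds=avila.thresholds)
        fc = export_isochrone_bands(field)
        total = sum(f["properties"]["cells"] for f in fc["features"])
        assert total == field.values.size

    def test_infinite_cells_fall_in_last_band(self):
        values = np.array([[1.0, np.inf, 7.0]])
        field = IsochroneField(values=values, thresholds=(5.0, 10.0))
        fc = export_isochrone_bands(field)
        by_label = {f["properties"]["label"]: f["properties"]["cells"]
                    for f in fc["features"]}
        assert by_label["> 10 min"] == 1

    def test_empty_grid_rejected(self):
        field = IsochroneField(values=np.zeros((0, 0)), thresholds=(10.0,))
        with pytest.raises(ValueError):
            export_isochrone_bands(field)

    def test_written_file_is_valid_geojson(self, line_grid, tmp_path):
        import json

        field = self.line_field(line_grid, (5.0, 10.0))
        export_isochrone_bands(field, path=tmp_path / "iso.geojson")
        fc = json.loads((tmp_path / "iso.geojson").read_text())
        assert fc["type"] == "FeatureCollection"
        assert all(f["geometry"]["type"] in ("Polygon", "MultiPolygon")
                   for f in fc["features"])
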