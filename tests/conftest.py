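import numpy as np
import pytest

from emsim import (
    AccidentRateTable,
    Calendar,
    RoadGrid,
    Scenario,
    ServiceTimeSpec,
    TownRecord,
    WeatherSpec,
    make_avila_like_scenario,
)
from emsim.fixtures import WEATHER_EVENTS


@pytest.fixture(scope="session")
def avila():
    return make_avila_like_scenario(seed=1)


@pytest.fixture(scope="session")
def avila_static_field(avila):
    """Static hub travel-time field on the Avila-like fixture."""
    return avila.grid.shortest_time_field(avila.grid.hub)


@pytest.fixture
def line_grid():
    """Straight 11-cell road, 1 min per cell; hub+hospital at one end."""
    cells = [(0, c) for c in range(11)]
    contents = {c: {"road"} for c in cells}
    contents[(0, 0)] |= {"hub", "hospital"}
    contents[(0, 8)] |= {"town"}
    return RoadGrid((1, 11), contents, {c: 1.0 for c in cells})


def quiet_scenario(grid, towns, segment, rates_jan, horizon_days=3, **kw):
    """Minimal scenario: one rated segment, no weather, no festivities."""
    rates = AccidentRateTable(
        rates={"R": tuple([float(rates_jan)] + [0.0] * 11)},
        segment_cells={"R": tuple(segment)},
    )
    weather = WeatherSpec(events=dict(WEATHER_EVENTS), monthly_days={})
    defaults = dict(
        name="quiet",
        grid=grid,
        towns=towns,
        accident_rates=rates,
        weather=weather,
        service_times=ServiceTimeSpec(),
        calendar=Calendar(2014),
        horizon_days=horizon_days,
        replications=1,
        seed=5,
    )
    defaults.update(kw)
    return Scenario(**defaults)


@pytest.fixture
def line_scenario(line_grid):
    """One accident hot-spot at the line's 5-minute cell."""
    towns = [TownRecord(name="end-town", cell=(0, 8), static_population=1000.0)]
    return quiet_scenario(line_grid, towns, [(0, 5)], rates_jan=40.0)
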