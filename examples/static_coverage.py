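"""Static isochrone coverage on the Ávila-like scenario.

Builds the fixture from the published 2014 input tables, computes the
travel-time field from the hub under perfect conditions (an ambulance
always available at the base) and prints the cumulative population
coverage phi_k for k = 10..60 minutes, plus the per-town travel times.
phi_k is the fraction of the regional population living within k minutes
of the hub; the 60-minute threshold is the Golden Hour.
"""

from emsim import IsochroneField, coverage_curve, export_isochrone_bands
from emsim import make_avila_like_scenario

scenario = make_avila_like_scenario()
grid = scenario.grid
field = IsochroneField(
    values=grid.shortest_time_field(grid.hub).values,
    thresholds=scenario.thresholds,
)

curve = coverage_curve(field, scenario.towns, scenario.thresholds)
print(f"total population: {curve.population_total:.0f}")
for k, phi in curve.as_dict().items():
    print(f"  phi_{int(k):2d} = {100 * phi:5.1f}%")

print("\ntravel time from the hub:")
for town in scenario.towns:
    print(f"  {town.name:26s} {field.at(town.cell):5.1f} min "
          f"(band {field.band_index(town.cell)})")

fc = export_isochrone_bands(field, path="scratch_isochrones.geojson")
print(f"\n{len(fc['features'])} isochrone bands written to "
      "scratch_isochrones.geojson")
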