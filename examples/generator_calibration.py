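"""Calibration of the accident and weather generators.

Re-simulates 1,000 independent Januaries and compares the sample means
with the monthly input tables: per-road accident counts follow Poisson
arrivals with the tabulated monthly means, and weather events are
Poisson-many per month with the tabulated mean event-days.  The printed
values should sit within a few standard errors of the inputs.
"""

import numpy as np

from emsim import (
    RandomStream,
    make_avila_like_scenario,
    sample_weather_calendar,
    simulate_monthly_accident_counts,
)

JANUARY = 31 * 1440.0
scenario = make_avila_like_scenario()
stream = RandomStream(2024)

counts = simulate_monthly_accident_counts(
    scenario.accident_rates, month=0, n_months=1000,
    rng=stream.accidents, month_length_minutes=JANUARY,
)
segs = scenario.accident_rates.segments
print("January accident counts over 1,000 simulated months:")
for name in ("N-110", "CL-501", "AP-51"):
    j = segs.index(name)
    lam = scenario.accident_rates.rates[name][0]
    print(f"  {name:7s} mean {counts[:, j].mean():6.2f}  (input rate {lam:g})")
total = counts.sum(axis=1)
print(f"  total   mean {total.mean():6.2f}  "
      f"(sum of input rates {scenario.accident_rates.monthly_total(0):g})")

rain = [
    sum(1 for ov in sample_weather_calendar(
        0, scenario.weather, stream.weather, 0.0, JANUARY
    ) if ov.cause == "rain")
    for _ in range(1000)
]
print(f"\nJanuary rain events: mean {np.mean(rain):.2f} (input mean days 5.9)")
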