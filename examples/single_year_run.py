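"""One simulated year of the EMS with a single ambulance.

Runs the discrete-event model for 365 days on the Ávila-like scenario
and prints the dynamic indicators: time-averaged population coverage
phi_k (now degraded by ambulance unavailability, weather, congestion and
festivities), per-town time coverage pi_k, and the occupation split of
the unit's year into travelling / preparation / assistance / free time.
"""

from emsim import make_avila_like_scenario, run

scenario = make_avila_like_scenario(seed=2024)
result = run(scenario)

print(f"accidents served: {len(result.accidents)}")
print(f"mean response time: {result.response_times.mean():.1f} min")

print("\ntime-averaged population coverage:")
for k, phi in result.phi.items():
    print(f"  phi_{int(k):2d} = {100 * phi:5.1f}%")

print("\nper-town time coverage pi_k (%):")
print((100 * result.pi).round(1).to_string())

print("\nambulance occupation (fractions of the year):")
print(result.occupation.fractions.round(3).to_string())
print(f"availability = {100 * result.availability:.1f}%")
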