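"""The deployment question: how many ambulances should staff the hub?

Replicates one simulated year under common random numbers for c = 1, 2
and 3 ambulances (scaled down to 5 replications here; the scenario's
default is 20) and prints availability next to the mean coverage curve.
The jump from one to two units should dwarf the gain from a third —
the economic argument of the deployment analysis.
"""

from emsim import availability_vs_coverage, make_avila_like_scenario, replicate

scenario = make_avila_like_scenario(seed=2024)
by_c = {
    c: replicate(scenario.with_(ambulance_count=c), n=5, collect_field=False)
    for c in (1, 2, 3)
}

table = availability_vs_coverage(by_c)
print((100 * table).round(1).to_string())

g12 = by_c[2].mean_phi[60.0] - by_c[1].mean_phi[60.0]
g23 = by_c[3].mean_phi[60.0] - by_c[2].mean_phi[60.0]
print(f"\nGolden-Hour coverage gain: +{100 * g12:.1f} pts (1 -> 2 units), "
      f"+{100 * g23:.1f} pts (2 -> 3 units)")
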