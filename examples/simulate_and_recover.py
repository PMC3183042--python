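"""Simulate a multilocus pattern under known sex bias and re-estimate it.

Draws 50 unlinked loci per marker class under (2Nm = 1, p = 0.8) with the
Monte Carlo generator, then recovers the parameters by maximum likelihood.
"""

from sexmig import (
    DemographicScenario,
    MarkerClass,
    ObservedPattern,
    SimulationConfig,
    likelihood_surface,
    simulate_pattern,
)

scenario = DemographicScenario(scaled_total_mig=1.0, female_fraction=0.8)
pattern, provenance = simulate_pattern(
    {mk: 50 for mk in MarkerClass}, SimulationConfig(scenario, seed=2024)
)
print("simulated pattern (truth: 2Nm = 1, p = 0.8, seed = 2024):")
for rec in pattern.records:
    print(f"  {rec.marker.value:2s} {rec.branch.value:5s} x{rec.count}")

surface = likelihood_surface(pattern)
print(f"\nMLE (2Nm, p): {surface.mle}")
i = [abs(v - 1.0) for v in surface.grid.mig_values]
print(f"true point inside 95% region: "
      f"{bool(surface.ci_mask[i.index(min(i)), list(surface.grid.p_values).index(0.8)])}")
print()
print("With 200 loci the surface localizes both the total migration rate")
print("and the female fraction; the MLE lands near the truth and the 95%")
print("region covers it.")
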