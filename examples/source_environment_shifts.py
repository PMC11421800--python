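"""Attribute the daily community to source environments and contrast
storm periods against the pre-event baseline.

Each ASV carries a probability profile over eight source environments
(freshwater, sediment, soil, groundwater, biofilm, marine,
sewage-wastewater, other); the community composition per day is the
abundance-weighted mean profile. Early-event and post-event days are
compared to pre-event days with the exact Mann-Whitney U test.
"""

from microcq import (
    SimulationConfig,
    community_environment_fractions,
    period_contrast,
    rarefy,
    simulate_campaign,
)

sim = simulate_campaign(SimulationConfig(rng_seed=1))
counts = rarefy(sim["counts"], depth=4000, seed=1)

composition = community_environment_fractions(counts, sim["habitats"])
print("pre-event mean composition (%):")
print((100 * composition.iloc[:4].mean()).round(1).to_string())

days = composition.index
periods = {"pre": list(days[:4]), "early_event": list(days[4:9]), "post_event": list(days[9:])}
contrast = period_contrast(composition, periods)
cols = ["environment", "period", "mean_difference_pct", "direction", "U", "p_two_sided"]
print("\nshifts vs pre-event baseline:")
print(contrast[cols].round(3).to_string(index=False))

# Soil- and biofilm-associated taxa (the mobilized classes' habitats) gain
# representation during the event while freshwater taxa lose it; small-n
# exact Mann-Whitney p-values quantify which shifts beat daily variability.
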