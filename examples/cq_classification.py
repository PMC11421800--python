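"""Classify each taxon's abundance-discharge (cQ) response and test
group-level patterns against shuffled surrogates.

Every ASV detected on >=3 days is regressed on daily discharge: positive
significant slope (p < 0.1) = mobilized, negative = diluted, otherwise
static. Group-level class fractions are compared with the 5th-95th
percentile band of 1,000 shuffled surrogates.
"""

import pandas as pd

from microcq import (
    SimulationConfig,
    assign_groups,
    class_fraction_timeseries,
    classify_all,
    rarefy,
    simulate_campaign,
    surrogate_null,
)

sim = simulate_campaign(SimulationConfig(rng_seed=1))
counts = rarefy(sim["counts"], depth=4000, seed=1)
hydro = sim["hydro"]

classification = classify_all(counts, hydro, alpha=0.1, min_detections=3)
print("label counts:", classification["label"].value_counts().to_dict())

truth = pd.Series(sim["truth"].taxon_class)
for label in ("mobilized", "diluted"):
    idx = truth[truth == label].index.intersection(counts.index)
    rate = (classification.loc[idx, "label"] == label).mean()
    print(f"recovery of true {label} taxa: {rate:.0%}")

fractions = class_fraction_timeseries(counts, classification)
peak = hydro["discharge_cms"].idxmax()
print("mobilized fraction: pre-event %.3f -> peak day %.3f" % (
    fractions["mobilized"].iloc[:4].mean(), fractions.loc[peak, "mobilized"]))

groups = assign_groups(sim["taxonomy"], counts)
surrogates = surrogate_null(counts, hydro, groups, n_surrogates=1000, seed=2)
print("\nsignificant group-class fractions (outside surrogate 5th-95th band):")
print(surrogates[surrogates.significant].round(3).to_string(index=False))

# Abundant true mobilized/diluted taxa are recovered almost perfectly (rare
# taxa lack statistical power, which pulls the overall rates down); event-only
# taxa that surge at high flow also register as mobilized. The mobilized share
# of the community peaks on the peak-discharge day, and the surrogate test
# flags the taxonomy groups whose class composition cannot be explained by
# chance assignment of counts to taxa.
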