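# microcq

**Microbial community concentration–discharge analysis: the stream
microbiome as a hydrologic tracer.**

During a storm, the water leaving a catchment is mostly "old" water that was
already stored there — stable-isotope hydrograph separation shows it — but
isotopes say little about *where* that water was stored or which flowpaths
carried it. The microbial community carries that missing information:
thousands of taxa wash into the stream from soils, groundwater, sediments
and biofilms, and their daily dynamics track the hydrograph. `microcq`
implements the analysis stack for daily 16S amplicon (ASV) samples
collected around a storm event, for hydrologists and microbial ecologists
working at the interface:

- **Diversity vs the hydrograph** — rarefaction, richness, Shannon index
  (H = −Σ pᵢ log₂ pᵢ), Bray-Curtis dissimilarity
  (BC = Σ|n_iu − n_iv| / Σ(n_iu + n_iv)), mean distance from the pre-event
  baseline, PCoA, and OLS of discharge on principal coordinates or
  diversity (adjusted r²).
- **Per-taxon cQ classification** — each ASV detected on ≥3 days is
  regressed on daily discharge and labelled *mobilized* (positive slope,
  p < 0.1), *diluted* (negative), *static*, or *uncharacterized*; group-level
  class fractions are tested against 1,000 shuffled surrogates (per-day
  count shuffling plus day-order shuffling, observed fraction vs the
  surrogate 5th–95th percentile band).
- **Source-environment attribution** — per-ASV habitat-preference hits
  collapsed into eight environments, abundance-weighted daily community
  composition, and exact Mann-Whitney U contrasts of storm periods against
  the pre-event baseline.
- **Isotope tools** — deuterium excess (δ²H − 8·δ¹⁸O) and two-component
  hydrograph separation f_new = (c_stream − c_old)/(c_new − c_old).
- **A synthetic storm-campaign generator** with known ground truth
  (hydrograph, coupled count matrix, isotope series, habitat profiles), so
  the whole stack is testable end to end without any download.

## Worked example

Two-component separation on the observed storm values — stream δ²H rising
from −53.9‰ (pre-event) to −52.1‰ at peak flow, against event
precipitation at −38.7‰:

```python
>>> from microcq import two_component_fraction
>>> f = two_component_fraction(-52.1, c_old=-53.9, c_new=-38.7)
>>> round(f, 4), round(100 * (1 - f), 1)
(0.1184, 88.2)
```

Only ~12% of peak streamflow is new storm water; ~88% was already in the
catchment. With discharge rising from 0.25 to 1.8 CMS (a 620% increase),
that is roughly 0.18 CMS of new water at the peak.

Classifying a synthetic campaign (`python examples/cq_classification.py`):

```
label counts: {'mobilized': 111, 'static': 56, 'diluted': 18, 'uncharacterized': 12}
recovery of true mobilized taxa: 88%
recovery of true diluted taxa: 76%
mobilized fraction: pre-event 0.462 -> peak day 0.861
```

Taxa the generator truly coupled to discharge are recovered (abundant ones
near-perfectly; rare taxa lack power), event-only taxa that surge at high
flow register as mobilized, and the mobilized share of the community peaks
on the peak-discharge day — the community-level fingerprint of terrestrial
source environments switching on during the storm.

Each script in `examples/` demonstrates one capability (simulation,
diversity/ordination, cQ classification, source attribution, isotope
separation, the full pipeline) and prints what the numbers mean. A thin CLI
wraps the same library:

```sh
microcq simulate --seed 1 --outdir sim/
microcq run --config run.yaml
microcq report out/
```

Every run writes `manifest.json` (seeds, thresholds, input checksums);
identical configs reproduce byte-identical outputs.

## Documentation

`docs/methods.md` describes the models, defaults, the synthetic generator's
scope, numerical choices, and known limitations — including an important
calibration caveat for the group-level surrogate test under heavy-tailed
abundance distributions.
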