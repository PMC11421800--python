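# Methods

`microcq` treats a stream's microbial community as a hydrologic tracer. Its
inputs are a daily ASV-by-sample count matrix from 16S rRNA amplicon
sequencing, a taxonomy table, daily mean discharge and precipitation, stream
δ²H/δ¹⁸O series, and per-ASV habitat-preference hits. This note documents
the models and procedures, the defaults and why they are set where they are,
what the synthetic generator does and does not emulate, and the known
limitations.

## Diversity and ordination

Counts are rarefied to a common depth (default 4,000 reads per sample) by an
exact uniform subsample without replacement (a multivariate hypergeometric
draw per sample); a sample below the depth is an error, never silently
dropped. The main analysis uses a single rarefaction at a recorded seed;
repeated-rarefaction averaging is possible by looping over seeds but is not
the default.

Alpha diversity is taxonomic richness and the Shannon index in base 2,
H = −Σᵢ pᵢ log₂ pᵢ, over each day's ASV proportions (0·log 0 = 0). Beta
diversity is Bray-Curtis dissimilarity,

    BC(u, v) = Σᵢ |n_iu − n_iv| / Σᵢ (n_iu + n_iv),

in the standard orientation: 0 for identical composition, 1 for disjoint
support. The per-day distance from baseline is the mean BC (or, for scalar
tracers, mean absolute difference) from each of the s = 4 pre-event days;
for a pre-event day itself the self-pair (distance 0) is included by
default, so baseline means are small but defined — set
`include_self=False` to average over the other s − 1 days instead.

Ordination is classical scaling (PCoA): Gower-centre −D²/2, symmetric
eigendecomposition, coordinates = eigenvectors scaled by √eigenvalue.
Bray-Curtis matrices are generally non-Euclidean, so negative eigenvalues
can appear; they are dropped (not corrected), their magnitudes are logged,
and proportions explained are relative to the sum of the positive
eigenvalues.

Discharge is related to community structure by OLS with an intercept:
discharge on the first p principal coordinates (default p = 4, with the
full r²-vs-p profile reported; r² is non-decreasing in p because the models
are nested), and simple regressions on richness and Shannon index, plus a
joint two-predictor fit on δ²H and δ¹⁸O. p-values are two-sided t-tests
with n − p − 1 degrees of freedom; adjusted r² = 1 − (1 − r²)(n − 1)/(n − p − 1).

## Per-taxon cQ classification

The core statistic adapts concentration-discharge (cQ) analysis to
individual taxa. For every ASV detected on at least `min_detections`
(default 3) days, its per-day rarefied count (equivalently, relative
abundance up to the constant depth; `use_proportions=True` switches
explicitly) is regressed on daily mean discharge over the whole study
period, zero-count days included. Labels: *mobilized* if the slope is
positive and significant at the 90% confidence level (two-sided p < 0.1),
*diluted* if negative and significant, *static* otherwise, *uncharacterized*
if under the detection filter. Tie-breaks: a zero-variance abundance series
or an exactly zero slope is static. The vectorised implementation is checked
in the test suite against `scipy.stats.linregress` taxon by taxon.

## Shuffled-surrogate group test

To ask whether a taxonomy group's class composition could arise by chance,
each of `n_surrogates` (default 1,000) surrogates (i) permutes, for every
sample day independently, the assignment of that day's count values to ASV
ids — preserving each day's abundance structure exactly while dissociating
counts from taxon identity — and (ii) permutes the day-to-discharge
alignment, destroying the hydrograph pattern. The classification and the
per-group sequence-weighted class fractions are recomputed for each
surrogate; an observed fraction above the 95th or below the 5th percentile
(linear interpolation between order statistics) of its surrogate
distribution is flagged significant. Each tail is a 5% test, so the
two-sided rule has a nominal 10% flag rate under the null. By default the
per-day permutation runs over the full ASV id set; `shuffle_scope="nonzero"`
restricts it to that day's detected ASVs.

**Calibration caveat (important).** The surrogate ensemble treats taxa as
exchangeable. The per-taxon classifier itself is exactly calibrated (the
mobilized+diluted call rate under a no-coupling simulation measures 0.107
against the nominal 0.10), but the *group-level sequence-weighted* statistic
is not distribution-free: when per-taxon abundances are heavy-tailed, the
observed fraction has fatter tails than the surrogate ensemble (a single
dominant taxon that lands a chance label moves the observed fraction far
more than any homogenised surrogate row can), and the two-sided rule flags
more than 10% under the null. Measured over 50 null simulations (no
coupling, no event taxa, 1,000 surrogates each), the flag rate is ~4% when
taxa abundances are near-uniform and rises to ~15–17% at the generator's
default lognormal σ = 2.4. The acceptance suite runs this measurement and
reports it; users should treat group-level flags as descriptive screening,
strongest when abundance is not concentrated in a few taxa, rather than as
exact 10%-level tests.

Fraction-of-sequences time series (the per-day share of mobilized / static /
diluted sequences) exclude uncharacterized taxa from the denominator; the
default denominator is per-day retained sequences, with a whole-study
option.

## Source-environment attribution

Habitat hits per ASV (ProkAtlas-style output) are collapsed through a
habitat→environment map into eight categories — freshwater, sediment, soil,
groundwater, biofilm, marine, sewage-wastewater, other — and normalised to
a per-ASV probability profile (zero-hit ASVs are pure "other"; the shipped
default map covers only the synthetic generator's names, so real analyses
supply their own map). Daily community composition is the abundance-weighted
mean profile, computed on the rarefied matrix by default. Periods — pre
(default: first four sample days), early event (default: rising limb through
the peak-discharge day), post event (the rest) — are contrasted per
environment by the Mann-Whitney U test on daily composition values: exact by
full enumeration when n_x + n_y ≤ 12 with no ties, otherwise the normal
approximation with tie correction. The reported one-sided p is the smaller
tail. Daily differences from the pre-event mean are reported in percentage
points.

## Isotope tools

Deuterium excess is the standard Dansgaard definition d = δ²H − 8·δ¹⁸O.
Two-component hydrograph separation solves f_new = (c_stream − c_old) /
(c_new − c_old) per day; the old-water endmember defaults to the pre-event
stream mean and the new-water endmember is the (precipitation-weighted, if
weights exist) event precipitation value. Endmembers closer than a minimum
separation (default 1‰ for δ²H) are an error — the mixing model is
unidentifiable. Fractions outside [0, 1], routine with noisy endmembers,
are reported raw and clipped with a warning rather than raised. The event
summary reports pre-event mean discharge, peak discharge and date, percent
increase, and event-water discharge at the peak.

## Synthetic generator

The generator emulates the study design so that every stage is testable
against known ground truth with no external data: 17 daily samples;
baseflow 0.25 CMS rising linearly over the storm to a 1.8 CMS peak, then
geometric recession of the excess (shape 0.6/day — each post-peak day
retains 60% of the previous day's excess over baseflow); raw library sizes
uniform on 4,333–37,740.

Community model: core taxon i has expected relative abundance
∝ aᵢ·max(0, 1 + βᵢ·z(t)) with z(t) standardised discharge; βᵢ =
+effect_scale (jittered ±25%) for mobilized taxa, negative for diluted,
zero for static, with class probabilities (0.15, 0.13, 0.72). Negative
expectations under strong dilution are clipped at zero, which keeps the
multinomial valid. Baseline abundances aᵢ are lognormal(0, 2.4) — heavy-
tailed, so a realistic share of the 120 core taxa sits below the
rarefaction detection limit and baseline richness lands near 85 rather than
120. Eighty event-only taxa with milder lognormal(0, 0.6) weights switch on
when discharge exceeds a threshold (default: midpoint of baseflow and
peak), producing the richness spike at high flow; because they surge with
discharge they typically classify as mobilized when detected on ≥3 days.
Daily counts are a single multinomial draw at the drawn library size.

Isotopes: the true event-water fraction is f(t) = φ·(Q(t) − q_base)/Q(t)
with φ = 0.14, so f is exactly 0 at baseflow and ≈ 0.12 at the 1.8 CMS peak
— a weak new-water signal of the kind the separation is meant to resolve.
Stream δ²H mixes endmembers −53.9‰ (old) and −38.7‰ (new) with Gaussian
noise of 0.16‰ (typical analytical precision); δ¹⁸O uses endmembers placed
on d-excess ≈ 10 and one-eighth the noise. With noise off, the separation
round-trips f(t) to 1e−12.

Habitat profiles are per-ASV Dirichlet draws whose concentration depends on
the true class: mobilized taxa lean toward soil and biofilm, diluted toward
freshwater and sediment, static and event-only mixed. Rows sum to 1.

One global seed drives three independent substreams (hydrograph, community,
isotopes), so each component reproduces in isolation.

What the generator does *not* emulate: sequencing error, chimeras or
compositional artefacts below the ASV level; phylogenetic correlation
between taxonomy and discharge response (synthetic lineages are assigned
independently of class, so group-level signal arises only through sampling);
temporal autocorrelation of community composition beyond what the hydrograph
induces; and hysteresis between rising and falling limbs. Passing recovery
tests therefore demonstrate correctness of the statistical machinery under
the stated model, not performance guarantees on field data.

## Problem sizes and numerical choices

Tests and the acceptance script use the 17-day campaign with 120 + 80 taxa
(down to 60 + 20 in pipeline round-trip checks), 150–1,000 surrogates, and
5–50 seeds per Monte-Carlo property; these sizes give stable estimates for
every property checked while keeping the whole suite fast. Percentiles use
linear interpolation; PCoA drops eigenvalues within machine tolerance of
zero; rank-deficient regression designs are rejected naming the collinear
columns; all randomness flows from explicit seeds and the pipeline manifest
echoes every seed, threshold and input checksum, making runs byte-identical.

## Known limitations

- The group-level surrogate test's level depends on abundance heterogeneity
  (see the calibration caveat above).
- The linear-in-standardised-discharge coupling is the simplest monotone
  choice; real cQ relationships can be power-law or hysteretic, and the
  classifier only reads the sign of a linear slope.
- Period boundaries (early vs post event) have no canonical definition;
  defaults are documented and configurable, and the contrast report echoes
  the definitions used.
- Attribution quality is bounded by the habitat database and the 80→8
  environment mapping supplied by the user.
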