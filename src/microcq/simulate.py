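"""Synthetic storm-event microbiome generator with known ground truth.

Emulates a 17-day daily sampling campaign around an isolated autumn storm on
a small stream: a baseflow -> rising limb -> peak -> geometric recession
hydrograph, an ASV count matrix whose taxa are linearly coupled (positively,
negatively, or not at all) to standardised discharge, event-only taxa that
produce a richness spike at high flow, a stream-isotope series from
two-endmember mixing, and per-ASV habitat profiles over eight source
environments.  Every downstream stage of the package is testable against the
returned ground truth without any external data.

One global seed drives three independent sub-streams (hydrograph, community,
isotopes) so that each component is reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ENVIRONMENTS, TAXONOMY_GROUPS

CLASSES = ("mobilized", "diluted", "static")

#: Dirichlet concentrations over ENVIRONMENTS by true class.  Mobilized taxa
#: are weighted toward soil and biofilm (terrestrial storm sources), diluted
#: taxa toward freshwater and sediment (resident planktonic community),
#: static and event-only taxa are mixed.
_HABITAT_ALPHA = {
    "mobilized": np.array([0.5, 0.5, 4.0, 0.5, 2.0, 0.2, 0.2, 0.5]),
    "diluted": np.array([4.0, 2.0, 0.5, 0.5, 0.3, 0.2, 0.2, 0.5]),
    "static": np.ones(8),
    "event-only": np.ones(8),
}


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic storm campaign.

    Defaults mirror the observed event: 17 daily samples, baseflow 0.25 CMS
    rising to a 1.8 CMS peak, raw library sizes between 4,333 and 37,740
    sequences, and a weak new-water isotope signal (peak event-water fraction
    around 0.12).
    """

    n_days: int = 17
    q_base: float = 0.25
    q_peak: float = 1.8
    event_start_day: int = 4
    rise_days: int = 3
    recession_shape: float = 0.6
    n_core_taxa: int = 120
    n_event_taxa: int = 80
    class_probabilities: tuple[float, float, float] = (0.15, 0.13, 0.72)
    effect_scale: float = 1.0
    library_size_range: tuple[int, int] = (4333, 37740)
    event_taxon_threshold: float | None = None  # default: midpoint(q_base, q_peak)
    delta_old: float = -53.9
    delta_new: float = -38.7
    delta18_old: float = -7.99
    delta18_new: float = -6.09
    isotope_noise_sd: float = 0.16
    event_fraction_scale: float = 0.14
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 3:
            raise ValueError("n_days must be at least 3")
        for name in ("q_base", "q_peak", "recession_shape", "effect_scale"):
            v = float(getattr(self, name))
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite")
        if not (self.q_peak > self.q_base > 0):
            raise ValueError("require q_peak > q_base > 0")
        if self.recession_shape <= 0:
            raise ValueError("recession_shape must be positive")
        if self.effect_scale < 0:
            raise ValueError("effect_scale must be nonnegative")
        if not (0 <= self.event_start_day < self.n_days):
            raise ValueError("event_start_day must lie inside the campaign")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("library sizes must be positive with lo <= hi")
        p = np.asarray(self.class_probabilities, dtype=float)
        if p.shape != (3,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("class_probabilities must be a 3-vector summing to 1")
        if self.delta_old == self.delta_new:
            raise ValueError("isotope endmembers must differ")
        if not (0 < self.event_fraction_scale <= 1):
            raise ValueError("event_fraction_scale must lie in (0, 1]")

    @property
    def threshold(self) -> float:
        if self.event_taxon_threshold is not None:
            return float(self.event_taxon_threshold)
        return 0.5 * (self.q_base + self.q_peak)

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range("2020-10-06", periods=self.n_days, freq="D")

    def substream(self, name: str) -> np.random.Generator:
        """Named child generator; hydrograph/community/isotopes are independent."""
        order = {"hydrograph": 0, "community": 1, "isotopes": 2}
        children = np.random.SeedSequence(self.rng_seed).spawn(3)
        return np.random.default_rng(children[order[name]])


@dataclass
class GroundTruth:
    """True per-taxon classes and coupling, and the true event-water fraction."""

    taxon_class: dict[str, str]
    beta: dict[str, float]
    event_water_fraction: pd.Series = field(default=None)

    def to_json(self, path) -> None:
        f = self.event_water_fraction
        payload = {
            "taxon_class": self.taxon_class,
            "beta": self.beta,
            "event_water_fraction": {}
            if f is None
            else {d.date().isoformat(): float(v) for d, v in f.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def generate_hydrograph(config: SimulationConfig) -> pd.DataFrame:
    """Baseflow, linear rise to the peak, then geometric recession.

    Discharge is ``q_base`` strictly before ``event_start_day``; it rises
    linearly over ``rise_days`` days to ``q_peak`` and then the excess over
    baseflow decays as ``recession_shape**k``.  Precipitation is nonzero only
    on the rising-limb days.
    """
    n = config.n_days
    q = np.full(n, config.q_base, dtype=float)
    peak_day = min(config.event_start_day + config.rise_days, n - 1)
    rise = np.linspace(config.q_base, config.q_peak, peak_day - config.event_start_day + 2)
    q[config.event_start_day : peak_day + 1] = rise[1:]
    excess = config.q_peak - config.q_base
    for k in range(1, n - peak_day):
        q[peak_day + k] = config.q_base + excess * config.recession_shape**k
    precip = np.zeros(n)
    rng = config.substream("hydrograph")
    n_rain = peak_day - config.event_start_day + 1
    precip[config.event_start_day : peak_day + 1] = rng.gamma(2.0, 6.0, size=n_rain)
    return pd.DataFrame(
        {"discharge_cms": q, "precip_mm": precip}, index=config.dates()
    )


def _draw_classes(rng: np.random.Generator, config: SimulationConfig) -> np.ndarray:
    return rng.choice(CLASSES, size=config.n_core_taxa, p=config.class_probabilities)


def generate_community(
    hydro: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, GroundTruth, pd.DataFrame]:
    """Draw the ASV count matrix and its ground truth.

    Each core taxon i has expected relative abundance proportional to
    ``a_i * max(0, 1 + beta_i * z(t))`` where ``z`` is standardised
    discharge; ``beta_i`` is positive for mobilized taxa, negative for
    diluted, and zero for static.  Event-only taxa carry weight only on days
    where discharge exceeds a threshold (default: midpoint of baseflow and
    peak), producing the richness spike at high flow.  Negative expected
    abundances for strongly diluted taxa are clipped at zero, which keeps the
    multinomial valid.  Daily counts are multinomial at a library size drawn
    uniformly from ``library_size_range``.

    Returns ``(counts, truth, taxonomy)`` where taxonomy assigns each ASV a
    plausible lineage so the group-level analyses are exercised end to end.
    """
    if len(hydro) < config.n_days:
        raise ValueError("hydrograph does not cover all campaign days")
    rng = config.substream("community")
    q = hydro["discharge_cms"].to_numpy()[: config.n_days]
    z = (q - q.mean()) / q.std(ddof=0)

    classes = _draw_classes(rng, config)
    sign = np.where(classes == "mobilized", 1.0, np.where(classes == "diluted", -1.0, 0.0))
    beta = sign * config.effect_scale * rng.uniform(0.75, 1.25, size=config.n_core_taxa)
    # Skewed (lognormal) baseline abundances: many rare core taxa stay below
    # the rarefaction detection limit, giving a realistic baseline richness
    # well under n_core_taxa.
    base_weight = rng.lognormal(mean=0.0, sigma=2.4, size=config.n_core_taxa)

    lam_core = base_weight[:, None] * np.clip(1.0 + beta[:, None] * z[None, :], 0.0, None)

    n_event = config.n_event_taxa
    event_weight = rng.lognormal(mean=0.0, sigma=0.6, size=n_event)
    active = (q > config.threshold).astype(float)
    lam_event = event_weight[:, None] * active[None, :]

    lam = np.vstack([lam_core, lam_event])
    ids = [f"ASV{i + 1:04d}" for i in range(lam.shape[0])]
    all_classes = list(classes) + ["event-only"] * n_event
    all_beta = list(beta) + [0.0] * n_event

    lo, hi = config.library_size_range
    counts = np.zeros_like(lam, dtype=np.int64)
    for t in range(config.n_days):
        col = lam[:, t]
        total = col.sum()
        if total <= 0:
            raise RuntimeError("degenerate day with zero expected abundance")
        size = int(rng.integers(lo, hi + 1))
        counts[:, t] = rng.multinomial(size, col / total)

    dates = config.dates()
    count_df = pd.DataFrame(counts, index=ids, columns=dates)
    truth = GroundTruth(
        taxon_class=dict(zip(ids, all_classes)),
        beta=dict(zip(ids, (float(b) for b in all_beta))),
    )
    taxonomy = _synthetic_taxonomy(ids, rng)
    return count_df, truth, taxonomy


_LINEAGES = {
    "Actinobacteriota": "d__Bacteria;p__Actinobacteriota;c__Actinobacteria",
    "Bacteroidota": "d__Bacteria;p__Bacteroidota;c__Bacteroidia",
    "Cyanobacteria": "d__Bacteria;p__Cyanobacteria;c__Cyanobacteriia",
    "Planctomycetota": "d__Bacteria;p__Planctomycetota;c__Planctomycetes",
    "Verrucomicrobiota": "d__Bacteria;p__Verrucomicrobiota;c__Verrucomicrobiae",
    "Gammaproteobacteria": "d__Bacteria;p__Proteobacteria;c__Gammaproteobacteria",
    "Alphaproteobacteria": "d__Bacteria;p__Proteobacteria;c__Alphaproteobacteria",
    "Other": "d__Bacteria;p__Firmicutes;c__Bacilli",
}


def _synthetic_taxonomy(ids: list[str], rng: np.random.Generator) -> pd.DataFrame:
    groups = rng.choice(TAXONOMY_GROUPS, size=len(ids))
    lineages = [_LINEAGES[g] for g in groups]
    return pd.DataFrame({"lineage": lineages}, index=pd.Index(ids, name="asv_id"))


def generate_isotopes(
    hydro: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.Series]:
    """Stream isotopes from two-endmember mixing over the hydrograph.

    The true event-water fraction is ``f(t) = phi * (Q(t) - q_base) / Q(t)``
    (zero at baseflow, rising with storm discharge), and the stream value is
    the f-weighted mix of the new- and old-water endmembers plus Gaussian
    analytical noise.  Returns the series and the true ``f(t)``.
    """
    rng = config.substream("isotopes")
    q = hydro["discharge_cms"].to_numpy()[: config.n_days]
    f = config.event_fraction_scale * (q - config.q_base) / q
    f = np.clip(f, 0.0, 1.0)
    d2h = f * config.delta_new + (1 - f) * config.delta_old
    d18o = f * config.delta18_new + (1 - f) * config.delta18_old
    if config.isotope_noise_sd > 0:
        d2h = d2h + rng.normal(0.0, config.isotope_noise_sd, size=len(f))
        d18o = d18o + rng.normal(0.0, config.isotope_noise_sd / 8.0, size=len(f))
    dates = config.dates()
    series = pd.DataFrame({"d2H": d2h, "d18O": d18o}, index=dates)
    return series, pd.Series(f, index=dates, name="event_water_fraction")


def generate_habitat_profiles(
    truth: GroundTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Per-ASV Dirichlet profiles over the eight source environments.

    Concentrations depend on the true class, so mobilized taxa lean toward
    soil/biofilm and diluted taxa toward freshwater/sediment; rows sum to 1.
    """
    rng = config.substream("community").spawn(1)[0]
    ids = list(truth.taxon_class)
    rows = np.vstack(
        [rng.dirichlet(_HABITAT_ALPHA[truth.taxon_class[a]]) for a in ids]
    )
    return pd.DataFrame(rows, index=pd.Index(ids, name="asv_id"), columns=list(ENVIRONMENTS))


def simulate_campaign(config: SimulationConfig):
    """Generate every input of the analysis in one call.

    Returns a dict with keys ``hydro``, ``counts``, ``taxonomy``,
    ``isotopes``, ``habitats``, ``truth``.
    """
    hydro = generate_hydrograph(config)
    counts, truth, taxonomy = generate_community(hydro, config)
    isotopes, f = generate_isotopes(hydro, config)
    truth = dataclasses.replace(truth, event_water_fraction=f)
    habitats = generate_habitat_profiles(truth, config)
    return {
        "hydro": hydro,
        "counts": counts,
        "taxonomy": taxonomy,
        "isotopes": isotopes,
        "habitats": habitats,
        "truth": truth,
    }
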