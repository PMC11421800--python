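"""End-to-end orchestration: rarefy -> diversity/PCoA -> regressions ->
cQ classification -> surrogate test -> source attribution -> isotope
separation, with a reproducibility manifest.

The pipeline is driven by a single :class:`RunConfig` (loadable from YAML)
whose defaults are the study settings: rarefaction to 4,000 reads, slope
test at a 90% confidence level, a 3-detection filter, 1,000 shuffled
surrogates, and the first four sample days as the pre-event baseline.
Missing optional inputs (isotopes, habitats) skip their stages with a
warning; every seed and threshold is echoed verbatim into
``manifest.json`` so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cq, diversity, io, isotopes as iso, regression, sources

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    counts_path: str = "counts.tsv"
    taxonomy_path: str = "taxonomy.tsv"
    hydro_path: str = "hydro.csv"
    isotopes_path: str | None = "isotopes.csv"
    habitats_path: str | None = "habitats.tsv"
    habitat_map_path: str | None = None
    outdir: str = "microcq_out"
    rarefaction_depth: int = 4000
    rarefaction_seed: int = 0
    alpha: float = 0.1
    min_detections: int = 3
    n_surrogates: int = 1000
    surrogate_seed: int = 0
    n_regression_axes: int = 4
    n_preevent_days: int = 4
    preevent_dates: list[str] | None = None
    early_event_dates: list[str] | None = None
    post_event_dates: list[str] | None = None
    delta_new: float | None = None
    min_endmember_separation: float = 1.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _default_periods(counts: pd.DataFrame, hydro: pd.DataFrame, config: RunConfig):
    """Pre = first k sample days; early event = rising limb through the peak
    day; post event = the remaining sample days."""
    dates = pd.DatetimeIndex(counts.columns)
    if config.preevent_dates:
        pre = pd.DatetimeIndex(pd.to_datetime(config.preevent_dates))
    else:
        pre = dates[: config.n_preevent_days]
    if config.early_event_dates:
        early = pd.DatetimeIndex(pd.to_datetime(config.early_event_dates))
    else:
        peak = hydro.loc[hydro.index.intersection(dates), "discharge_cms"].idxmax()
        early = dates[(~dates.isin(pre)) & (dates <= peak)]
    if config.post_event_dates:
        post = pd.DatetimeIndex(pd.to_datetime(config.post_event_dates))
    else:
        post = dates[~dates.isin(pre) & ~dates.isin(early)]
    return {"pre": list(pre), "early_event": list(early), "post_event": list(post)}


def _read_habitats(config: RunConfig) -> pd.DataFrame | None:
    if not config.habitats_path or not Path(config.habitats_path).exists():
        if config.habitats_path:
            logger.warning("habitat table %s not found; source stage skipped", config.habitats_path)
        return None
    head = pd.read_csv(config.habitats_path, sep="\t", nrows=1)
    if set(io.ENVIRONMENTS) <= set(head.columns):
        return pd.read_csv(config.habitats_path, sep="\t", index_col=0)
    hits = io.read_habitat_hits(config.habitats_path)
    if config.habitat_map_path:
        mapping = io.read_habitat_map(config.habitat_map_path)
    else:
        logger.warning("no habitat map supplied; all habitats fall to 'other'")
        mapping = pd.Series(dtype=object)
    return sources.aggregate_habitats(hits, mapping)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write every stage's outputs.

    Returns the in-memory result bundle; writes CSV/TSV outputs, the
    manifest, and a human-readable report under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": config}

    counts_raw = io.read_count_table(config.counts_path)
    taxonomy = io.read_taxonomy_table(config.taxonomy_path)
    hydro = io.read_timeseries(config.hydro_path, "hydro")
    hydro = io.align_to_counts(hydro, counts_raw)

    counts = diversity.rarefy(
        counts_raw, config.rarefaction_depth, seed=config.rarefaction_seed
    )
    groups = io.assign_groups(taxonomy, counts)
    periods = _default_periods(counts, hydro, config)
    pre_dates = pd.DatetimeIndex(periods["pre"])
    bundle["periods"] = {k: [d.date().isoformat() for d in v] for k, v in periods.items()}

    # --- diversity ---------------------------------------------------------
    alpha_div = diversity.alpha_diversity(counts)
    bc = diversity.bray_curtis_matrix(counts)
    pre_ids = [d.date().isoformat() for d in pre_dates]
    pre_bc = diversity.mean_preevent_distance(bc, pre_ids)
    ordination = diversity.pcoa(bc)
    bundle.update(alpha=alpha_div, bc=bc, preevent_bc=pre_bc, pcoa=ordination)

    # --- regressions -------------------------------------------------------
    p = min(config.n_regression_axes, ordination.coordinates.shape[1])
    coord_fit, profile = regression.discharge_from_coordinates(ordination, hydro, p)
    alpha_fits = regression.diversity_discharge_fit(alpha_div, hydro)
    bundle.update(coord_fit=coord_fit, r2_profile=profile, alpha_fits=alpha_fits)

    # --- cQ classification and surrogate null ------------------------------
    classification = cq.classify_all(
        counts, hydro, alpha=config.alpha, min_detections=config.min_detections
    )
    fractions_ts = cq.class_fraction_timeseries(counts, classification)
    group_fracs = cq.group_class_fractions(classification, groups, counts)
    surrogate = cq.surrogate_null(
        counts,
        hydro,
        groups,
        n_surrogates=config.n_surrogates,
        seed=config.surrogate_seed,
        alpha=config.alpha,
        min_detections=config.min_detections,
    )
    bundle.update(
        classification=classification,
        class_fractions=fractions_ts,
        group_fractions=group_fracs,
        surrogate=surrogate,
    )

    # --- source attribution -------------------------------------------------
    profiles = _read_habitats(config)
    if profiles is not None:
        env_comp = sources.community_environment_fractions(counts, profiles)
        contrast = sources.period_contrast(env_comp, periods)
        bundle.update(env_profiles=profiles, env_composition=env_comp, contrast=contrast)

    # --- isotopes -----------------------------------------------------------
    if config.isotopes_path and Path(config.isotopes_path).exists():
        iso_series = io.read_timeseries(config.isotopes_path, "isotope")
        iso_series = iso_series.assign(
            d_excess=iso.d_excess(iso_series["d2H"], iso_series["d18O"])
        )
        alpha_fits.update(
            regression.diversity_discharge_fit(iso_series[["d2H", "d18O"]], hydro)
        )
        c_new = config.delta_new
        if c_new is not None:
            mixing = iso.hydrograph_separation(
                iso_series,
                hydro,
                c_new=c_new,
                preevent_dates=pre_dates,
                min_separation=config.min_endmember_separation,
            )
            summary = iso.event_response_summary(hydro, mixing, pre_dates)
            bundle.update(mixing=mixing, event_summary=summary)
        else:
            logger.warning("no precipitation endmember (delta_new); separation skipped")
        pre_euclid = diversity.mean_preevent_euclid(iso_series["d2H"], pre_dates)
        bundle.update(isotopes=iso_series, preevent_d2h=pre_euclid)
    elif config.isotopes_path:
        logger.warning("isotope series %s not found; isotope stages skipped", config.isotopes_path)

    _write_bundle(bundle, outdir, config)
    return bundle


def _round_df(df: pd.DataFrame, ndigits: int = 10) -> pd.DataFrame:
    return df.round(ndigits)


def _write_bundle(bundle: dict, outdir: Path, config: RunConfig) -> None:
    written = []

    def save(df: pd.DataFrame, name: str, **kwargs) -> None:
        path = outdir / name
        _round_df(df.copy()).to_csv(path, **kwargs)
        written.append(name)

    alpha = bundle["alpha"].copy()
    alpha.index = alpha.index.date
    save(alpha, "alpha.csv", index_label="date")
    bc_df = pd.DataFrame(bundle["bc"].data, index=bundle["bc"].ids, columns=bundle["bc"].ids)
    save(bc_df, "bc_matrix.tsv", sep="\t", index_label="sample")
    save(bundle["pcoa"].coordinates, "pcoa_coords.csv", index_label="sample")
    save(bundle["preevent_bc"], "preevent_distance.csv")
    save(bundle["r2_profile"], "r2_profile.csv")
    save(bundle["classification"], "classification.tsv", sep="\t")
    cf = bundle["class_fractions"].copy()
    cf.index = cf.index.date
    save(cf, "class_fractions_by_day.csv", index_label="date")
    save(bundle["group_fractions"], "group_fractions.tsv", sep="\t", index=False)
    save(bundle["surrogate"], "surrogate_report.csv", index=False)
    if "env_composition" in bundle:
        save(bundle["env_profiles"], "env_profiles.tsv", sep="\t", index_label="asv_id")
        env = bundle["env_composition"].copy()
        env.index = env.index.date
        save(env, "env_composition_by_day.csv", index_label="date")
        save(
            bundle["contrast"].drop(columns=["differences_pct"]),
            "period_contrast.csv",
            index=False,
        )
    if "mixing" in bundle:
        mix = bundle["mixing"].copy()
        mix.index = mix.index.date
        save(mix, "mixing.csv", index_label="date")
        with open(outdir / "summary.json", "w") as fh:
            json.dump(bundle["event_summary"], fh, indent=1)
        written.append("summary.json")

    regressions = {
        "coordinates": bundle["coord_fit"].to_dict(),
        **{k: v.to_dict() for k, v in bundle["alpha_fits"].items()},
    }
    with open(outdir / "regression_report.json", "w") as fh:
        json.dump(regressions, fh, indent=1)
    written.append("regression_report.json")

    text = report(bundle)
    (outdir / "report.md").write_text(text)
    written.append("report.md")

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "periods": bundle["periods"],
        "input_checksums": {
            name: _sha256(path)
            for name, path in {
                "counts": config.counts_path,
                "taxonomy": config.taxonomy_path,
                "hydro": config.hydro_path,
                "isotopes": config.isotopes_path,
                "habitats": config.habitats_path,
            }.items()
            if path and Path(path).exists()
        },
        "outputs": sorted(written),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def report(bundle: dict) -> str:
    """One-page markdown summary of a result bundle."""
    lines = ["# microcq run summary", ""]
    alpha = bundle["alpha"]
    lines += [
        "## Alpha diversity",
        f"- richness: min {alpha['richness'].min()} -> max {alpha['richness'].max()}",
        f"- Shannon index: min {alpha['shannon'].min():.2f} -> max {alpha['shannon'].max():.2f}",
        "",
    ]
    fit = bundle["coord_fit"]
    best = max(
        [("PCoA coordinates", fit.r2_adjusted)]
        + [(k, v.r2_adjusted) for k, v in bundle["alpha_fits"].items()],
        key=lambda kv: kv[1],
    )
    lines += [
        "## Discharge regressions (adjusted r2)",
        f"- first {fit.p} PCoA coordinates: {fit.r2_adjusted:.3f}",
        *(f"- {k}: {v.r2_adjusted:.3f}" for k, v in bundle["alpha_fits"].items()),
        f"- best model: {best[0]}",
        "",
    ]
    cls = bundle["classification"]
    if len(cls):
        tally = cls["label"].value_counts()
        lines += [
            "## cQ classification",
            *(
                f"- {label}: {int(tally.get(label, 0))} taxa"
                for label in cq.LABELS
            ),
            "",
        ]
    else:
        lines += ["## cQ classification", "- zero classified taxa", ""]
    sig = bundle["surrogate"]
    sig = sig[sig["significant"]]
    lines.append("## Significant group-class fractions (shuffled surrogates)")
    if len(sig):
        lines += [
            f"- {r.group} / {r.label}: observed {r.observed_fraction:.3f} "
            f"outside [{r.surrogate_p5:.3f}, {r.surrogate_p95:.3f}]"
            for r in sig.itertuples()
        ]
    else:
        lines.append("- none")
    lines.append("")
    if "contrast" in bundle:
        sigc = bundle["contrast"]
        sigc = sigc[sigc["p_two_sided"] < 0.1]
        lines.append("## Source-environment shifts vs pre-event (p < 0.1)")
        if len(sigc):
            lines += [
                f"- {r.environment} ({r.period}): {r.direction}, p = {r.p_two_sided:.3f}"
                for r in sigc.itertuples()
            ]
        else:
            lines.append("- none")
        lines.append("")
    if "event_summary" in bundle:
        s = bundle["event_summary"]
        lines += [
            "## Isotopic hydrograph separation",
            f"- pre-event discharge {s['preevent_mean_cms']:.2f} CMS; "
            f"peak {s['peak_cms']:.2f} CMS on {s['peak_date']} "
            f"(+{s['percent_increase']:.0f}%)",
            f"- event-water fraction at peak {s['event_water_fraction_at_peak']:.3f} "
            f"({s['event_water_cms_at_peak']:.2f} CMS of new water)",
            "",
        ]
    return "\n".join(lines)
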