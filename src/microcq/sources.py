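"""Habitat-based source-environment attribution and storm-period contrasts.

Habitat hits per ASV (the tabular output of a habitat-preference lookup such
as ProkAtlas) are collapsed into eight source environments, normalised to a
per-ASV probability profile, and combined with daily abundances into a
community-weighted environment composition per sample day.  Storm periods
(early event, post event) are contrasted against the pre-event baseline with
the Mann-Whitney U test, exact for small tie-free samples.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats

from .io import ENVIRONMENTS

logger = logging.getLogger(__name__)


def aggregate_habitats(hits: pd.DataFrame, mapping: pd.Series) -> pd.DataFrame:
    """Collapse long-format habitat hits into per-ASV environment fractions.

    ``hits`` has columns ``asv_id``, ``habitat``, ``hits``; ``mapping`` maps
    habitat names to one of the eight environments (habitats absent from the
    mapping fall to ``"other"``).  Each ASV's environment totals are
    normalised to sum to 1; ASVs with zero total hits get ``other = 1``.
    """
    if (hits["hits"] < 0).any():
        raise ValueError("negative habitat hit count")
    env = hits["habitat"].map(mapping).fillna("other")
    unknown = ~env.isin(ENVIRONMENTS)
    if unknown.any():
        logger.warning(
            "mapping produced %d hits in unknown environments; reassigned to 'other'",
            int(unknown.sum()),
        )
        env = env.where(~unknown, "other")
    table = (
        hits.assign(environment=env)
        .pivot_table(index="asv_id", columns="environment", values="hits", aggfunc="sum")
        .reindex(columns=list(ENVIRONMENTS))
        .fillna(0.0)
    )
    totals = table.sum(axis=1)
    zero = totals == 0
    with np.errstate(invalid="ignore"):
        profiles = table.div(totals, axis=0)
    profiles.loc[zero] = 0.0
    profiles.loc[zero, "other"] = 1.0
    return profiles


def community_environment_fractions(
    counts: pd.DataFrame, profiles: pd.DataFrame
) -> pd.DataFrame:
    """Abundance-weighted mean source-environment profile per sample day.

    ASVs without a profile are treated as pure ``other``.  Rows (days) sum
    to 1 whenever the day has nonzero total abundance.
    """
    prof = profiles.reindex(index=counts.index, columns=list(ENVIRONMENTS)).fillna(0.0)
    missing = prof.sum(axis=1) == 0
    if missing.any():
        logger.info("%d ASVs without habitat profile assigned to 'other'", int(missing.sum()))
        prof.loc[missing, "other"] = 1.0
    weights = counts.to_numpy(dtype=float)
    totals = weights.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        comp = (prof.to_numpy().T @ weights) / totals
    return pd.DataFrame(
        comp.T, index=pd.DatetimeIndex(counts.columns), columns=list(ENVIRONMENTS)
    )


def mann_whitney_u(x, y) -> tuple[float, float, float]:
    """Mann-Whitney U with exact small-sample p-values.

    Returns ``(U, p_one_sided, p_two_sided)`` where U counts the pairs in
    which an ``x`` value exceeds a ``y`` value (ties count one half).  The
    p-value is exact (full enumeration of rank arrangements) when
    ``len(x) + len(y) <= 12`` and there are no ties, otherwise the normal
    approximation with tie correction is used.  The one-sided p is for the
    smaller tail, i.e. the better-supported direction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) + len(y) <= 12 and not ties) else "asymptotic"
    u, p_greater = scipy.stats.mannwhitneyu(x, y, alternative="greater", method=method)
    _, p_less = scipy.stats.mannwhitneyu(x, y, alternative="less", method=method)
    _, p_two = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(u), float(min(p_greater, p_less)), float(min(p_two, 1.0))


def period_contrast(
    env_fracs: pd.DataFrame, periods: dict[str, list]
) -> pd.DataFrame:
    """Contrast storm-period environment composition against pre-event days.

    ``periods`` maps ``"pre"``, ``"early_event"``, ``"post_event"`` to
    disjoint date lists.  For each environment and each non-pre period:
    the daily differences from the pre-event mean (percentage points) and an
    exact Mann-Whitney U comparing pre-event daily values against the
    period's daily values (one- and two-sided p).  Periods with fewer than
    two days are skipped with a warning.
    """
    if "pre" not in periods or len(periods["pre"]) == 0:
        raise ValueError("periods must include a nonempty 'pre' set")
    names = list(periods)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            overlap = set(pd.DatetimeIndex(periods[a])) & set(pd.DatetimeIndex(periods[b]))
            if overlap:
                raise ValueError(f"periods {a!r} and {b!r} overlap: {sorted(overlap)}")
    pre_dates = pd.DatetimeIndex(periods["pre"])
    pre = env_fracs.loc[pre_dates]
    pre_mean = pre.mean(axis=0)
    rows = []
    for period_name, dates in periods.items():
        if period_name == "pre":
            continue
        dates = pd.DatetimeIndex(dates)
        if len(dates) < 2:
            logger.warning("period %r has <2 days; test skipped", period_name)
            continue
        sub = env_fracs.loc[dates]
        for env in env_fracs.columns:
            diffs = (sub[env] - pre_mean[env]) * 100.0
            u, p1, p2 = mann_whitney_u(pre[env].to_numpy(), sub[env].to_numpy())
            rows.append(
                {
                    "environment": env,
                    "period": period_name,
                    "mean_difference_pct": float(diffs.mean()),
                    "differences_pct": diffs.to_list(),
                    "direction": "increase" if diffs.mean() > 0 else "decrease",
                    "U": u,
                    "p_one_sided": p1,
                    "p_two_sided": p2,
                }
            )
    return pd.DataFrame(rows)
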