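"""Per-taxon abundance-discharge (cQ) classification and its surrogate null.

The classification adapts concentration-discharge analysis from solute
hydrochemistry to amplicon data.  For every ASV detected on at least
``min_detections`` days, its per-day abundance is regressed on daily mean
discharge over the whole study period (zero-count days included once the
detection filter passes).  The taxon is

* ``mobilized``  if the slope is positive and significant (p < alpha),
* ``diluted``    if the slope is negative and significant,
* ``static``     if the slope is not significant at that level, and
* ``uncharacterized`` if detected on too few (< min_detections) days.

Significance is the two-sided t-test on the OLS slope at alpha = 0.1 (a 90%
confidence level).  Degenerate inputs (zero-variance abundance, exactly zero
slope) resolve to static.

Group-level confidence comes from shuffled surrogates: each surrogate first
permutes, independently for every sample day, the assignment of that day's
count values to ASV ids (dissociating counts from identities while
preserving each day's abundance structure exactly), then permutes the
date-to-discharge alignment (destroying the hydrograph pattern).  The
classification and the per-group class fractions are recomputed for every
surrogate; an observed fraction outside the surrogate 5th-95th percentile
band is flagged significant (each tail is a 5% test, so the two-sided rule
has a nominal 10% flag rate under the null).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

LABELS = ("mobilized", "static", "diluted", "uncharacterized")
TESTED_LABELS = ("mobilized", "static", "diluted")


# ---------------------------------------------------------------------------
# vectorised slope / p machinery
# ---------------------------------------------------------------------------

def _slopes_pvalues(y: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS slope and two-sided slope p-value for each row of ``y`` against ``q``.

    Works on 2-D ``y`` (taxa x days) or 3-D ``y`` (surrogates x taxa x days,
    with ``q`` then surrogates x days).  Zero-variance rows return slope 0,
    p 1; exact fits return p 0.
    """
    y = np.asarray(y, dtype=float)
    q = np.asarray(q, dtype=float)
    n = y.shape[-1]
    if n < 3:
        raise ValueError("need at least 3 days for a slope test")
    qc = q - q.mean(axis=-1, keepdims=True)
    sxx = (qc**2).sum(axis=-1)  # scalar or (S,)
    if y.ndim == 2:
        num = y @ qc if qc.ndim == 1 else np.einsum("id,d->i", y, qc)
        slope = num / sxx
        resid = y - y.mean(axis=-1, keepdims=True) - slope[..., None] * qc
    else:
        num = np.einsum("sid,sd->si", y, qc)
        slope = num / sxx[:, None]
        resid = y - y.mean(axis=-1, keepdims=True) - slope[..., None] * qc[:, None, :]
    sse = (resid**2).sum(axis=-1)
    dof = n - 2
    var_y = y.var(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sse / dof / (sxx if y.ndim == 2 else sxx[:, None]))
        t = slope / se
    p = 2.0 * scipy.stats.t.sf(np.abs(t), dof)
    # exact fits: se = 0, nonzero slope -> t = inf -> p = 0 (already handled);
    # zero-variance abundance: slope 0/0 -> force static-compatible values.
    flat = var_y == 0
    slope = np.where(flat, 0.0, slope)
    p = np.where(flat, 1.0, p)
    p = np.where(np.isnan(p), 1.0, p)
    return slope, p


def _labels_from_stats(
    slope: np.ndarray, p: np.ndarray, detected: np.ndarray, alpha: float
) -> np.ndarray:
    """Integer label codes 0=mobilized, 1=static, 2=diluted, 3=uncharacterized."""
    labels = np.ones(slope.shape, dtype=np.int8)  # static by default
    labels[(slope > 0) & (p < alpha)] = 0
    labels[(slope < 0) & (p < alpha)] = 2
    labels[~detected] = 3
    return labels


# ---------------------------------------------------------------------------
# public classification API
# ---------------------------------------------------------------------------

def classify_taxon(
    abundance: pd.Series,
    hydro: pd.DataFrame,
    alpha: float = 0.1,
    min_detections: int = 3,
) -> dict:
    """Classify one taxon's abundance series against daily discharge."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    common = abundance.index.intersection(hydro.index)
    y = abundance.loc[common].to_numpy(dtype=float)
    q = hydro.loc[common, "discharge_cms"].to_numpy(dtype=float)
    n_det = int((y > 0).sum())
    if n_det < min_detections:
        return {
            "label": "uncharacterized",
            "slope": np.nan,
            "p_value": np.nan,
            "n_detections": n_det,
        }
    slope, p = _slopes_pvalues(y[None, :], q)
    label = LABELS[_labels_from_stats(slope, p, np.array([True]), alpha)[0]]
    return {
        "label": label,
        "slope": float(slope[0]),
        "p_value": float(p[0]),
        "n_detections": n_det,
    }


def classify_all(
    counts: pd.DataFrame,
    hydro: pd.DataFrame,
    alpha: float = 0.1,
    min_detections: int = 3,
    use_proportions: bool = False,
) -> pd.DataFrame:
    """Vectorised classification of every ASV in the count matrix.

    ``use_proportions=True`` regresses per-day proportions instead of counts;
    on a rarefied matrix the two are equivalent up to the constant depth.
    """
    if counts.empty:
        return pd.DataFrame(columns=["label", "slope", "p_value", "n_detections"])
    dates = pd.DatetimeIndex(counts.columns)
    common = dates.intersection(hydro.index)
    y = counts[common].to_numpy(dtype=float)
    if use_proportions:
        y = y / y.sum(axis=0, keepdims=True)
    q = hydro.loc[common, "discharge_cms"].to_numpy(dtype=float)
    n_det = (y > 0).sum(axis=1)
    detected = n_det >= min_detections
    slope, p = _slopes_pvalues(y, q)
    codes = _labels_from_stats(slope, p, detected, alpha)
    table = pd.DataFrame(
        {
            "label": pd.Categorical.from_codes(codes, categories=list(LABELS)),
            "slope": np.where(detected, slope, np.nan),
            "p_value": np.where(detected, p, np.nan),
            "n_detections": n_det.astype(int),
        },
        index=counts.index.rename("asv_id"),
    )
    return table


def class_fraction_timeseries(
    counts: pd.DataFrame,
    classification: pd.DataFrame,
    denominator: str = "per_day",
) -> pd.DataFrame:
    """Per-date fraction of retained sequences in each cQ class.

    Uncharacterized taxa are excluded from the denominator (fractions are of
    the abundance identified in at least ``min_detections`` samples).  With
    ``denominator="per_day"`` each day's fractions are of that day's retained
    sequences; ``"whole_study"`` divides by the study-period total instead.
    A day with zero retained sequences is reported as missing.
    """
    if denominator not in ("per_day", "whole_study"):
        raise ValueError("denominator must be 'per_day' or 'whole_study'")
    labels = classification.loc[counts.index, "label"].astype(str)
    retained = labels != "uncharacterized"
    sub = counts.loc[retained]
    lab = labels.loc[retained]
    per_label = sub.groupby(lab.to_numpy()).sum()
    per_label = per_label.reindex(list(TESTED_LABELS)).fillna(0.0)
    if denominator == "per_day":
        denom = sub.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = per_label.div(denom, axis=1)
        frac[per_label.columns[denom == 0]] = np.nan
    else:
        frac = per_label / sub.to_numpy().sum()
    return frac.T  # dates x labels


def group_class_fractions(
    classification: pd.DataFrame, groups: pd.Series, counts: pd.DataFrame
) -> pd.DataFrame:
    """Per-group class fractions, weighted by sequences and by unique taxa.

    For each taxonomy group, the fraction of the group's total study-period
    sequences (and of its unique ASVs) carrying each of the four labels.
    Fractions sum to 1 over labels within a group by either weighting.
    """
    missing = counts.index.difference(groups.index)
    if len(missing):
        raise ValueError(f"ASVs without a group assignment: {list(missing[:5])}")
    totals = counts.sum(axis=1)
    labels = classification.loc[counts.index, "label"].astype(str)
    g = groups.loc[counts.index].astype(str)
    rows = []
    for group_name, idx in totals.groupby(g).groups.items():
        seq_total = totals.loc[idx].sum()
        taxa_total = len(idx)
        for label in LABELS:
            mask = labels.loc[idx] == label
            rows.append(
                {
                    "group": group_name,
                    "label": label,
                    "fraction_sequences": float(totals.loc[idx][mask].sum() / seq_total)
                    if seq_total > 0
                    else np.nan,
                    "fraction_taxa": float(mask.sum() / taxa_total),
                    "n_taxa": int(mask.sum()),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# shuffled surrogates
# ---------------------------------------------------------------------------

def shuffle_day_values(
    y: np.ndarray, rng: np.random.Generator, scope: str = "all"
) -> np.ndarray:
    """One surrogate shuffle of a taxa x days count matrix.

    Permutes each day's (column's) values over the ASV rows, independently
    per day, so every day's multiset of count values is preserved exactly.
    ``scope="all"`` permutes over the full id set; ``"nonzero"`` only among
    that day's detected ASVs (zeros stay in place).
    """
    if scope == "all":
        return rng.permuted(y, axis=0)
    if scope == "nonzero":
        shuffled = y.copy()
        for t in range(y.shape[1]):
            nz = np.flatnonzero(y[:, t] > 0)
            shuffled[nz, t] = y[rng.permutation(nz), t]
        return shuffled
    raise ValueError("scope must be 'all' or 'nonzero'")


def surrogate_null(
    counts: pd.DataFrame,
    hydro: pd.DataFrame,
    groups: pd.Series,
    n_surrogates: int = 1000,
    seed=None,
    alpha: float = 0.1,
    min_detections: int = 3,
    shuffle_scope: str = "all",
) -> pd.DataFrame:
    """Shuffled-surrogate significance test for group-level class fractions.

    Each surrogate permutes every day's count values over the ASV ids
    (``shuffle_scope="all"`` permutes over the full id set;
    ``"nonzero"`` permutes only among that day's detected ASVs) and then
    permutes the day-to-discharge alignment.  Per-day count multisets are
    preserved exactly.  Returns one row per (group, tested label) with the
    observed sequence fraction, the surrogate 5th/95th percentiles (linear
    interpolation between order statistics), and the significance flag.
    """
    if n_surrogates < 100:
        raise ValueError("need at least 100 surrogates for stable percentiles")
    if shuffle_scope not in ("all", "nonzero"):
        raise ValueError("shuffle_scope must be 'all' or 'nonzero'")
    rng = np.random.default_rng(seed)
    dates = pd.DatetimeIndex(counts.columns)
    common = dates.intersection(hydro.index)
    y = counts[common].to_numpy(dtype=float)
    q = hydro.loc[common, "discharge_cms"].to_numpy(dtype=float)
    n_taxa, n_days = y.shape

    group_names = sorted(groups.loc[counts.index].astype(str).unique())
    gcodes = pd.Categorical(groups.loc[counts.index].astype(str), categories=group_names).codes
    indicator = np.zeros((len(group_names), n_taxa))
    indicator[gcodes, np.arange(n_taxa)] = 1.0

    def fractions(mat: np.ndarray, qvec: np.ndarray) -> np.ndarray:
        """(group, tested-label) sequence-fraction matrix for one dataset."""
        n_det = (mat > 0).sum(axis=1)
        detected = n_det >= min_detections
        slope, p = _slopes_pvalues(mat, qvec)
        codes = _labels_from_stats(slope, p, detected, alpha)
        totals = mat.sum(axis=1)
        denom = indicator @ totals
        out = np.empty((len(group_names), len(TESTED_LABELS)))
        for j, _label in enumerate(TESTED_LABELS):
            out[:, j] = indicator @ (totals * (codes == j))
        with np.errstate(invalid="ignore", divide="ignore"):
            out = out / denom[:, None]
        return out

    observed = fractions(y, q)

    surro = np.empty((n_surrogates, len(group_names), len(TESTED_LABELS)))
    for s in range(n_surrogates):
        shuffled = shuffle_day_values(y, rng, shuffle_scope)
        q_perm = rng.permutation(q)
        surro[s] = fractions(shuffled, q_perm)

    p5 = np.nanpercentile(surro, 5, axis=0)
    p95 = np.nanpercentile(surro, 95, axis=0)
    rows = []
    for i, group_name in enumerate(group_names):
        for j, label in enumerate(TESTED_LABELS):
            obs = observed[i, j]
            rows.append(
                {
                    "group": group_name,
                    "label": label,
                    "observed_fraction": float(obs),
                    "surrogate_p5": float(p5[i, j]),
                    "surrogate_p95": float(p95[i, j]),
                    "significant": bool(
                        np.isfinite(obs) and (obs < p5[i, j] or obs > p95[i, j])
                    ),
                }
            )
    return pd.DataFrame(rows)
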