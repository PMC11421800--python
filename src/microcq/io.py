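"""Readers and writers for the tabular inputs and outputs.

All on-disk dialects are defined here once:

* ``counts.tsv`` — ASV rows x ISO-8601 date columns, integer cells.
* ``taxonomy.tsv`` — columns ``asv_id``, ``lineage`` (rank-prefixed,
  semicolon-separated SILVA-style string).
* ``hydro.csv`` — columns ``date``, ``discharge_cms``, ``precip_mm``.
* ``isotopes.csv`` — columns ``date``, ``d2H``, ``d18O`` (permil VSMOW).
* ``habitats.tsv`` — long format ``asv_id``, ``habitat``, ``hits``.
* ``habitat_map.tsv`` — columns ``habitat``, ``environment``.

In memory everything is a pandas object: a count matrix is a DataFrame with
string ASV ids as the index and a ``DatetimeIndex`` of sample dates as
columns; time series are DataFrames indexed by date.  Dates are the join key
everywhere; time-of-day is deliberately not modelled (daily resolution is the
analysis unit).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The eight taxonomic categories used throughout the analysis: five phyla,
#: the two Proteobacteria subgroups, and a catch-all.
TAXONOMY_GROUPS = (
    "Actinobacteriota",
    "Bacteroidota",
    "Cyanobacteria",
    "Planctomycetota",
    "Verrucomicrobiota",
    "Gammaproteobacteria",
    "Alphaproteobacteria",
    "Other",
)

#: The eight source-environment categories habitat hits are collapsed into.
ENVIRONMENTS = (
    "freshwater",
    "sediment",
    "soil",
    "groundwater",
    "biofilm",
    "marine",
    "sewage-wastewater",
    "other",
)


class TableFormatError(ValueError):
    """A tabular input violated its dialect (structure, not cell values)."""


class TableParseError(ValueError):
    """A cell value could not be parsed or failed validation."""


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

def validate_count_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise an ASV x date count matrix.

    Enforces: unique ASV ids, strictly increasing unique dates, nonnegative
    integer cells.  Rows that are all zero are dropped with a warning.
    """
    if counts.index.duplicated().any():
        dupes = counts.index[counts.index.duplicated()].unique().tolist()
        raise TableFormatError(f"duplicate ASV ids: {dupes}")
    dates = pd.DatetimeIndex(counts.columns)
    if dates.duplicated().any():
        raise TableFormatError(
            f"duplicate sample dates: {dates[dates.duplicated()].unique().tolist()}"
        )
    if not dates.is_monotonic_increasing:
        raise TableFormatError("sample dates must be strictly increasing")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise TableParseError("count matrix contains non-numeric cells")
    if np.any(~np.isfinite(values)):
        raise TableParseError("count matrix contains non-finite cells")
    if np.any(values < 0):
        bad = np.argwhere(values < 0)[0]
        raise TableParseError(
            f"negative count at ASV {counts.index[bad[0]]!r}, "
            f"date {counts.columns[bad[1]]}"
        )
    if np.any(values != np.floor(values)):
        bad = np.argwhere(values != np.floor(values))[0]
        raise TableParseError(
            f"non-integer count at ASV {counts.index[bad[0]]!r}, "
            f"date {counts.columns[bad[1]]}"
        )
    out = counts.copy()
    out.columns = dates
    out = out.astype(np.int64)
    empty = out.sum(axis=1) == 0
    if empty.any():
        logger.warning("dropping %d all-zero ASV rows", int(empty.sum()))
        out = out.loc[~empty]
    return out


def read_count_table(path) -> pd.DataFrame:
    """Read a TSV count table (ASV rows, ISO-8601 date columns)."""
    raw = pd.read_csv(path, sep="\t", index_col=0)
    try:
        pd.DatetimeIndex(raw.columns)
    except (ValueError, TypeError) as exc:
        raise TableFormatError(f"count-table header is not ISO dates: {exc}") from exc
    return validate_count_matrix(raw)


def write_count_table(counts: pd.DataFrame, path) -> None:
    out = counts.copy()
    out.columns = [d.date().isoformat() for d in pd.DatetimeIndex(counts.columns)]
    out.index.name = "asv_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

def read_taxonomy_table(path) -> pd.DataFrame:
    tax = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "asv_id" not in tax.columns or "lineage" not in tax.columns:
        raise TableFormatError("taxonomy table needs 'asv_id' and 'lineage' columns")
    if tax["asv_id"].duplicated().any():
        raise TableFormatError("duplicate ASV ids in taxonomy table")
    return tax.set_index("asv_id")


def write_taxonomy_table(taxonomy: pd.DataFrame, path) -> None:
    out = taxonomy.copy()
    out.index.name = "asv_id"
    out.to_csv(path, sep="\t")


def _group_from_lineage(lineage: str) -> str:
    low = lineage.lower()
    # Proteobacteria subgroups take precedence over the phylum name.
    for sub in ("Gammaproteobacteria", "Alphaproteobacteria"):
        if sub.lower() in low:
            return sub
    for phylum in (
        "Actinobacteriota",
        "Bacteroidota",
        "Cyanobacteria",
        "Planctomycetota",
        "Verrucomicrobiota",
    ):
        if phylum.lower() in low:
            return phylum
    return "Other"


def assign_groups(taxonomy: pd.DataFrame, counts: pd.DataFrame) -> pd.Series:
    """Map every ASV in ``counts`` to one of the eight taxonomy groups.

    Lineages are matched case-insensitively on substring per rank, which is
    robust to minor SILVA formatting drift.  ASVs missing from the taxonomy
    table (or with an empty lineage) fall through to ``"Other"`` with a
    warning.
    """
    groups = {}
    missing = []
    for asv in counts.index:
        if asv in taxonomy.index:
            lineage = str(taxonomy.loc[asv, "lineage"])
        else:
            lineage = ""
            missing.append(asv)
        groups[asv] = _group_from_lineage(lineage) if lineage.strip() else "Other"
        if not lineage.strip() and asv not in missing:
            missing.append(asv)
    if missing:
        logger.warning(
            "%d ASVs missing from taxonomy or with empty lineage; assigned 'Other'",
            len(missing),
        )
    return pd.Series(groups, name="group").loc[counts.index]


# ---------------------------------------------------------------------------
# time series
# ---------------------------------------------------------------------------

_TS_COLUMNS = {
    "hydro": ("discharge_cms", "precip_mm"),
    "isotope": ("d2H", "d18O"),
}


def read_timeseries(path, kind: str) -> pd.DataFrame:
    """Read a daily CSV series (``kind`` = ``"hydro"`` or ``"isotope"``)."""
    if kind not in _TS_COLUMNS:
        raise ValueError(f"unknown series kind {kind!r}")
    required = _TS_COLUMNS[kind]
    df = pd.read_csv(path)
    if "date" not in df.columns:
        raise TableFormatError(f"{kind} series missing 'date' column")
    for col in required:
        if col not in df.columns:
            raise TableFormatError(f"{kind} series missing {col!r} column")
    try:
        idx = pd.DatetimeIndex(pd.to_datetime(df["date"], format="ISO8601"))
    except (ValueError, TypeError) as exc:
        raise TableParseError(f"unparseable date in {kind} series: {exc}") from exc
    if idx.duplicated().any():
        raise TableFormatError(f"duplicate dates in {kind} series")
    out = df[list(required)].apply(pd.to_numeric, errors="coerce")
    for col in required:
        if out[col].isna().any() and not df[col].isna().any():
            raise TableParseError(f"non-numeric value in column {col!r}")
        if out[col].isna().any():
            raise TableParseError(f"missing value in column {col!r}")
    out.index = idx
    out = out.sort_index()
    if kind == "hydro" and (out["discharge_cms"] <= 0).any():
        raise TableParseError("discharge must be strictly positive")
    if kind == "isotope" and not np.isfinite(out.to_numpy()).all():
        raise TableParseError("isotope series contains non-finite values")
    return out


def write_timeseries(series: pd.DataFrame, path) -> None:
    out = series.copy()
    out.insert(0, "date", [d.date().isoformat() for d in pd.DatetimeIndex(series.index)])
    out.to_csv(path, index=False)


def align_to_counts(series: pd.DataFrame, counts: pd.DataFrame) -> pd.DataFrame:
    """Inner-join a daily series onto the count-matrix dates.

    Days present in the counts but absent from the series are excluded from
    downstream regressions, with a logged report.
    """
    dates = pd.DatetimeIndex(counts.columns)
    common = dates.intersection(series.index)
    dropped = dates.difference(series.index)
    if len(dropped):
        logger.warning(
            "%d sample dates missing from series and excluded: %s",
            len(dropped),
            [d.date().isoformat() for d in dropped],
        )
    return series.loc[common]


# ---------------------------------------------------------------------------
# habitat hits and mapping
# ---------------------------------------------------------------------------

def read_habitat_hits(path) -> pd.DataFrame:
    """Read a long-format habitat-hit table (asv_id, habitat, hits)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("asv_id", "habitat", "hits"):
        if col not in df.columns:
            raise TableFormatError(f"habitat table missing {col!r} column")
    hits = pd.to_numeric(df["hits"], errors="coerce")
    if hits.isna().any():
        raise TableParseError("non-numeric habitat hit count")
    if (hits < 0).any():
        raise TableParseError("negative habitat hit count")
    df = df.assign(hits=hits)
    return df


def read_habitat_map(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    for col in ("habitat", "environment"):
        if col not in df.columns:
            raise TableFormatError(f"habitat map missing {col!r} column")
    return df.set_index("habitat")["environment"]


def write_long_csv(df: pd.DataFrame, path) -> None:
    """Emit any wide table as tidy long-format CSV for downstream plotting."""
    long = df.reset_index().melt(id_vars=df.index.name or "index")
    long.to_csv(path, index=False)
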