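"""Rarefaction, alpha diversity, Bray-Curtis beta diversity, and PCoA.

Alpha diversity is taxonomic richness (number of unique ASVs) and the
Shannon index in base 2,

    H = -sum_i p_i log2(p_i),

over the proportions p_i of each ASV in a sample.  Beta diversity is the
Bray-Curtis dissimilarity

    BC(u, v) = sum_i |n_iu - n_iv| / sum_i (n_iu + n_iv),

in the standard orientation (0 = identical composition, 1 = disjoint
support).  Ordination is classical scaling (principal coordinates analysis):
Gower-centre -D^2/2, take the symmetric eigendecomposition, and scale
eigenvectors by the square roots of the nonnegative eigenvalues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.spatial.distance as ssd
from skbio import DistanceMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

def rarefy(counts: pd.DataFrame, depth: int, seed=None) -> pd.DataFrame:
    """Subsample every sample (column) to ``depth`` reads without replacement.

    Uses a multivariate hypergeometric draw per column, which is exactly a
    uniform subsample of the column's reads.  ASVs left with zero total are
    dropped.  A column whose total is below ``depth`` raises, naming the
    sample — samples are never silently discarded.
    """
    rng = np.random.default_rng(seed)
    totals = counts.sum(axis=0)
    short = totals[totals < depth]
    if len(short):
        name = short.index[0]
        raise ValueError(
            f"sample {name} has only {int(short.iloc[0])} reads, fewer than depth {depth}"
        )
    out = np.empty(counts.shape, dtype=np.int64)
    values = counts.to_numpy().astype(np.int64)
    for j in range(values.shape[1]):
        out[:, j] = rng.multivariate_hypergeometric(values[:, j], depth)
    rarefied = pd.DataFrame(out, index=counts.index, columns=counts.columns)
    keep = rarefied.sum(axis=1) > 0
    if (~keep).any():
        logger.info("rarefaction dropped %d ASVs with zero remaining reads", int((~keep).sum()))
    return rarefied.loc[keep]


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def shannon(column) -> float:
    """Base-2 Shannon entropy of a count vector (0*log0 treated as 0)."""
    x = np.asarray(column, dtype=float)
    if x.sum() <= 0:
        raise ValueError("Shannon index undefined for an all-zero sample")
    if np.any(x < 0):
        raise ValueError("counts must be nonnegative")
    p = x[x > 0] / x.sum()
    return float(-(p * np.log2(p)).sum())


def richness(column) -> int:
    """Number of ASVs with a nonzero count."""
    return int((np.asarray(column) > 0).sum())


def alpha_diversity(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-date richness and Shannon index."""
    return pd.DataFrame(
        {
            "richness": [richness(counts[c]) for c in counts.columns],
            "shannon": [shannon(counts[c]) for c in counts.columns],
        },
        index=pd.DatetimeIndex(counts.columns),
    )


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(u, v) -> float:
    """Bray-Curtis dissimilarity between two count vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    if np.any(u < 0) or np.any(v < 0):
        raise ValueError("counts must be nonnegative")
    if u.sum() == 0 and v.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(ssd.braycurtis(u, v))


def bray_curtis_matrix(counts: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis over samples, as a labelled distance matrix."""
    data = counts.to_numpy().astype(float).T  # samples x taxa
    condensed = ssd.pdist(data, metric="braycurtis")
    ids = [d.date().isoformat() for d in pd.DatetimeIndex(counts.columns)]
    return DistanceMatrix(ssd.squareform(condensed), ids=ids)


def mean_preevent_distance(
    dist: DistanceMatrix, preevent_ids, include_self: bool = True
) -> pd.DataFrame:
    """Mean (and SD of) distance of every sample from the pre-event samples.

    For each sample l the mean over the s pre-event samples m of D(l, m).
    When l is itself pre-event the self-pair (distance 0) is included by
    default, so pre-event means are small but defined; pass
    ``include_self=False`` to average over the other s-1 pre-event samples.
    """
    pre = list(preevent_ids)
    if not pre:
        raise ValueError("pre-event sample set is empty")
    missing = [p for p in pre if p not in dist.ids]
    if missing:
        raise ValueError(f"pre-event ids not in distance matrix: {missing}")
    rows = []
    for sample in dist.ids:
        vals = np.array([dist[sample, m] for m in pre if include_self or m != sample])
        rows.append((sample, float(vals.mean()), float(vals.std(ddof=0))))
    return pd.DataFrame(rows, columns=["sample", "mean", "sd"]).set_index("sample")


def mean_preevent_euclid(
    series: pd.Series, preevent_dates, include_self: bool = True
) -> pd.DataFrame:
    """Mean absolute difference of a scalar series from its pre-event values.

    The scalar analogue of :func:`mean_preevent_distance`, used for d2H and
    d-excess: the pairwise distance is |x_l - x_m|.
    """
    pre = list(preevent_dates)
    if not pre:
        raise ValueError("pre-event sample set is empty")
    rows = []
    for d, x in series.items():
        vals = np.array(
            [abs(x - series[m]) for m in pre if include_self or m != d]
        )
        rows.append((d, float(vals.mean()), float(vals.std(ddof=0))))
    return pd.DataFrame(rows, columns=["sample", "mean", "sd"]).set_index("sample")


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass
class PcoaResult:
    """Classical-scaling embedding of a distance matrix.

    ``coordinates`` is samples x axes with axes ordered by decreasing
    eigenvalue; ``proportion_explained`` is relative to the sum of the
    positive eigenvalues.  Negative eigenvalues (possible for
    non-Euclidean dissimilarities such as Bray-Curtis) are dropped, with
    their magnitudes retained in ``negative_eigenvalues``.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def pcoa(dist: DistanceMatrix, n_axes: int | None = None) -> PcoaResult:
    """Principal coordinates analysis by classical (Torgerson-Gower) scaling."""
    d = np.asarray(dist.data, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    if n_axes is not None and n_axes > n - 1:
        raise ValueError("n_axes must be at most n_samples - 1")
    a = -0.5 * d**2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = centering @ a @ centering
    eigvals, eigvecs = scipy.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    tol = max(abs(eigvals).max(), 1.0) * 1e-12
    positive = eigvals > tol
    negative = eigvals < -tol
    if negative.any():
        logger.info(
            "dropping %d negative PCoA eigenvalues (largest magnitude %.3g)",
            int(negative.sum()),
            float(-eigvals[negative].min()),
        )
    pos_vals = eigvals[positive]
    coords = eigvecs[:, positive] * np.sqrt(pos_vals)[None, :]
    if n_axes is not None:
        coords = coords[:, :n_axes]
        retained = pos_vals[:n_axes]
    else:
        retained = pos_vals
    prop = retained / pos_vals.sum() if pos_vals.sum() > 0 else np.zeros_like(retained)
    coord_df = pd.DataFrame(
        coords[:, : len(retained)],
        index=list(dist.ids),
        columns=[f"PC{i + 1}" for i in range(len(retained))],
    )
    return PcoaResult(
        coordinates=coord_df,
        eigenvalues=retained,
        proportion_explained=prop,
        negative_eigenvalues=-eigvals[negative],
    )
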