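"""Least-squares regressions of stream discharge on community summaries.

These are the descriptive fits that link the ordination and the diversity
series back to the hydrograph: discharge regressed on the first p principal
coordinates, and on richness, Shannon index, or the isotope pair.  All fits
are ordinary least squares with an intercept, two-sided t-test p-values with
n - p - 1 degrees of freedom, and

    r2_adj = 1 - (1 - r2) (n - 1) / (n - p - 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .diversity import PcoaResult


@dataclass
class RegressionFit:
    coefficients: pd.Series  # includes "intercept"
    p_values: pd.Series
    r2: float
    r2_adjusted: float
    fitted: pd.Series
    n: int
    p: int

    def to_dict(self) -> dict:
        return {
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "p_values": {k: float(v) for k, v in self.p_values.items()},
            "r2": float(self.r2),
            "r2_adjusted": float(self.r2_adjusted),
            "n": int(self.n),
            "p": int(self.p),
        }


def ols_fit(X: pd.DataFrame, y: pd.Series) -> RegressionFit:
    """OLS of ``y`` on the columns of ``X`` with an intercept.

    Raises on rank-deficient design, naming the collinear columns.
    """
    if isinstance(X, pd.Series):
        X = X.to_frame()
    X = X.astype(float)
    y = y.astype(float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (got n={n}, p={p})")
    design = sm.add_constant(X.to_numpy(), has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        collinear = _collinear_columns(X)
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    model = sm.OLS(y.to_numpy(), design).fit()
    names = ["intercept"] + list(X.columns)
    coef = pd.Series(model.params, index=names)
    pvals = pd.Series(model.pvalues, index=names)
    fitted = pd.Series(model.fittedvalues, index=y.index)
    return RegressionFit(
        coefficients=coef,
        p_values=pvals,
        r2=float(model.rsquared),
        r2_adjusted=float(model.rsquared_adj),
        fitted=fitted,
        n=n,
        p=p,
    )


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    """Columns whose removal restores full rank (greedy diagnosis)."""
    bad = []
    cols = list(X.columns)
    arr = sm.add_constant(X.to_numpy(), has_constant="add")
    for j, name in enumerate(cols):
        reduced = np.delete(arr, j + 1, axis=1)
        if np.linalg.matrix_rank(reduced) == np.linalg.matrix_rank(arr):
            bad.append(name)
    return bad or cols


def discharge_from_coordinates(
    pcoa_result: PcoaResult, hydro: pd.DataFrame, p: int
) -> tuple[RegressionFit, pd.DataFrame]:
    """Discharge regressed on the first ``p`` principal coordinates.

    Also returns the r2-vs-p profile for every usable p (the profile is
    non-decreasing in p because the models are nested).
    """
    coords = pcoa_result.coordinates
    if p > coords.shape[1]:
        raise ValueError(f"requested p={p} but only {coords.shape[1]} axes available")
    ids = [d.date().isoformat() for d in pd.DatetimeIndex(hydro.index)]
    y = pd.Series(hydro["discharge_cms"].to_numpy(), index=ids).loc[coords.index]
    fit = ols_fit(coords.iloc[:, :p], y)
    n = len(y)
    max_p = min(coords.shape[1], n - 2)
    profile = []
    for k in range(1, max_p + 1):
        f = ols_fit(coords.iloc[:, :k], y)
        profile.append((k, f.r2, f.r2_adjusted))
    profile_df = pd.DataFrame(profile, columns=["p", "r2", "r2_adjusted"]).set_index("p")
    return fit, profile_df


def diversity_discharge_fit(
    predictors: pd.DataFrame, hydro: pd.DataFrame
) -> dict[str, RegressionFit]:
    """Discharge regressed on community/tracer summaries.

    For an alpha-diversity table (columns ``richness``, ``shannon``) each
    metric gets its own simple linear fit; for an isotope table (columns
    ``d2H``, ``d18O``) the two tracers enter one joint fit, mirroring how the
    isotopic signature is two-dimensional.
    """
    common = predictors.index.intersection(hydro.index)
    X = predictors.loc[common]
    y = hydro.loc[common, "discharge_cms"]
    fits: dict[str, RegressionFit] = {}
    if {"d2H", "d18O"} <= set(X.columns):
        fits["isotopes"] = ols_fit(X[["d2H", "d18O"]], y)
    for col in X.columns:
        if col in ("d2H", "d18O"):
            continue
        fits[col] = ols_fit(X[[col]], y)
    return fits
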