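"""Stable-isotope tracer computations.

Two quantities: deuterium excess, d = d2H - 8 * d18O (the Dansgaard
definition; sensitive to vapour source and evaporation), and two-component
isotopic hydrograph separation.  Separation solves the tracer mass balance

    c_stream = f_new * c_new + (1 - f_new) * c_old
    =>  f_new = (c_stream - c_old) / (c_new - c_old),

where the old-water endmember is by default the pre-event stream mean and
the new-water endmember is the event precipitation signature.  Fractions
outside [0, 1] — common with noisy endmembers — are reported raw and
clipped with a warning rather than raised.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def d_excess(d2h, d18o):
    """Deuterium excess, d2H - 8 * d18O [permil]."""
    return np.asarray(d2h, dtype=float) - 8.0 * np.asarray(d18o, dtype=float)


def two_component_fraction(
    c_stream, c_old: float, c_new: float, min_separation: float = 1.0
):
    """New-water (event) fraction from a two-endmember tracer mass balance.

    ``c_stream`` may be a scalar or an array.  Raises when the endmembers
    are closer than ``min_separation`` (the mixing model is unidentifiable).
    The returned value is raw (not clipped); see
    :func:`hydrograph_separation` for the clipped per-day series.
    """
    if abs(c_new - c_old) < min_separation:
        raise ValueError(
            f"endmember separation |{c_new} - {c_old}| below {min_separation}; "
            "mixing model unidentifiable"
        )
    c = np.asarray(c_stream, dtype=float)
    f = (c - c_old) / (c_new - c_old)
    return float(f) if np.isscalar(c_stream) else f


def hydrograph_separation(
    isotopes: pd.DataFrame,
    hydro: pd.DataFrame,
    c_new: float,
    preevent_dates=None,
    c_old: float | None = None,
    tracer: str = "d2H",
    min_separation: float = 1.0,
) -> pd.DataFrame:
    """Per-day two-component separation of the stream into old and new water.

    The old-water endmember is ``c_old`` if given, else the mean stream
    tracer value over ``preevent_dates``.  Returns per-day raw and clipped
    new-water fractions, the old-water fraction, and the new-water discharge
    (fraction times daily discharge).
    """
    if c_old is None:
        if preevent_dates is None or len(list(preevent_dates)) == 0:
            raise ValueError("need either c_old or a nonempty pre-event date set")
        c_old = float(isotopes.loc[pd.DatetimeIndex(preevent_dates), tracer].mean())
    common = isotopes.index.intersection(hydro.index)
    raw = two_component_fraction(
        isotopes.loc[common, tracer].to_numpy(), c_old, c_new, min_separation
    )
    clipped = np.clip(raw, 0.0, 1.0)
    n_out = int((raw != clipped).sum())
    if n_out:
        logger.warning("%d mixing fractions outside [0, 1] were clipped", n_out)
    q = hydro.loc[common, "discharge_cms"].to_numpy()
    return pd.DataFrame(
        {
            "f_new_raw": raw,
            "f_new": clipped,
            "f_old": 1.0 - clipped,
            "event_water_cms": clipped * q,
        },
        index=common,
    )


def event_response_summary(
    hydro: pd.DataFrame, mixing: pd.DataFrame, preevent_dates
) -> dict:
    """Headline numbers of the storm response.

    Pre-event mean discharge, the peak discharge and its date, the percent
    increase 100 * (Q_peak - Q_pre) / Q_pre, and the estimated event-water
    discharge at the peak (new-water fraction times peak discharge).
    """
    pre = pd.DatetimeIndex(preevent_dates)
    if len(pre) == 0:
        raise ValueError("pre-event date set is empty")
    q = hydro["discharge_cms"]
    q_pre = float(q.loc[pre].mean())
    peak_date = q.idxmax()
    q_peak = float(q.max())
    f_peak = float(mixing.loc[peak_date, "f_new"]) if peak_date in mixing.index else np.nan
    return {
        "preevent_mean_cms": q_pre,
        "peak_cms": q_peak,
        "peak_date": peak_date.date().isoformat(),
        "percent_increase": 100.0 * (q_peak - q_pre) / q_pre,
        "event_water_fraction_at_peak": f_peak,
        "event_water_cms_at_peak": f_peak * q_peak,
    }
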