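"""Bioclimatic niche positions and latitudinal relative range positions.

A species' bioclimatic niche axis is its occupied climatic range rescaled
to [-1, 1]: the coldest/wettest occupied value (leading margin) maps to -1,
the hottest/driest (trailing margin) to +1.  Precipitation is inverted
before rescaling so the axis orientation matches temperature and aridity.
The latitudinal relative range position (RRP) rescales each occupied site's
latitude to [0, 1] over the species' occupied extent, 0 at the southern
(trailing) edge; a per-species Pearson correlation between the two axes
checks their alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class DegenerateNicheError(ValueError):
    pass


def rescale_to_niche(values, vmin: float | None = None, vmax: float | None = None):
    """Min-max rescale climatic values to the [-1, 1] niche axis."""
    v = np.asarray(values, dtype=float)
    lo = float(np.min(v)) if vmin is None else float(vmin)
    hi = float(np.max(v)) if vmax is None else float(vmax)
    if hi <= lo:
        raise DegenerateNicheError("degenerate niche: max equals min climatic value")
    return 2.0 * (v - lo) / (hi - lo) - 1.0


def niche_positions(
    window_values: pd.DataFrame,
    variable: str = "temperature",
    extent: str = "site_year",
) -> pd.DataFrame:
    """Per-site niche positions from occupied window climate summaries.

    Parameters
    ----------
    window_values
        Occupied site-year summaries for the species' selected variable and
        window: columns ``site_id, year, value`` (a single value per site is
        also accepted).
    variable
        Name of the climatic variable; precipitation is inverted so that the
        wettest occupied value maps to the leading margin (-1).
    extent
        ``site_year``: min/max taken over all occupied site-year values
        (interior sites need not attain +-1);
        ``site_mean``: min/max over site long-run means (endpoints attained).

    Returns columns ``site_id, mean_value, niche_position``.
    """
    df = window_values.copy()
    df["v"] = df["value"].astype(float)
    if variable == "precipitation":
        df["v"] *= -1.0
    site_means = df.groupby("site_id")["v"].mean()
    if extent == "site_year":
        lo, hi = float(df["v"].min()), float(df["v"].max())
    elif extent == "site_mean":
        lo, hi = float(site_means.min()), float(site_means.max())
    else:
        raise ValueError(f"unknown extent {extent!r}")
    pos = rescale_to_niche(site_means.to_numpy(), lo, hi)
    return pd.DataFrame(
        {
            "site_id": site_means.index,
            "mean_value": site_means.to_numpy() * (-1.0 if variable == "precipitation" else 1.0),
            "niche_position": pos,
        }
    ).reset_index(drop=True)


def relative_range_position(latitudes: pd.Series | pd.DataFrame) -> pd.DataFrame:
    """Latitudinal relative range position per occupied site.

    ``latitudes`` maps site_id -> latitude (Series) or is a DataFrame with
    ``site_id, latitude``.  Returns ``site_id, latitude, rrp`` with rrp = 0
    at the lowest-latitude (trailing) site and 1 at the highest (leading).
    """
    if isinstance(latitudes, pd.DataFrame):
        lat = latitudes.set_index("site_id")["latitude"]
    else:
        lat = latitudes
    lo, hi = float(lat.min()), float(lat.max())
    if hi <= lo:
        raise DegenerateNicheError("species occupies a single latitude")
    rrp = (lat - lo) / (hi - lo)
    return pd.DataFrame(
        {"site_id": lat.index, "latitude": lat.to_numpy(), "rrp": rrp.to_numpy()}
    ).reset_index(drop=True)


def abundance_weighted_centroid(latitudes, weights) -> float:
    """Abundance-weighted mean latitude of a species (range-centroid
    diagnostic)."""
    lat = np.asarray(latitudes, dtype=float)
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("non-positive total weight")
    return float(np.sum(lat * w) / np.sum(w))


@dataclass
class NicheRangeAlignment:
    r: float
    n: int
    valid: bool
    reason: str = ""


def niche_range_correlation(
    positions: pd.DataFrame, range_positions: pd.DataFrame
) -> NicheRangeAlignment:
    """Pearson alignment between the niche axis and the latitudinal axis.

    RRP is re-oriented as 1 - 2*RRP (so trailing margin -> +1, like the niche
    axis); a positive r therefore means the two axes agree.
    """
    merged = positions.merge(range_positions, on="site_id", how="inner")
    n = len(merged)
    if n < 3:
        return NicheRangeAlignment(np.nan, n, False, "fewer than 3 paired sites")
    r, _ = stats.pearsonr(merged["niche_position"], 1.0 - 2.0 * merged["rrp"])
    return NicheRangeAlignment(float(r), n, True)
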