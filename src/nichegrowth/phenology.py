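"""Flight curves, annual abundance indices, growth rates and data filters.

Weekly transect counts are smoothed into an annual flight curve per species
and zone (a Poisson spline regression over week number, pooled across the
zone's sites), which provides

* percentile-based phenological windows (flight period = weeks between the
  10th and 90th percentile of the curve),
* imputation of missing survey weeks when deriving the annual abundance
  index N_jit (observed weeks are summed as-is; missing weeks contribute
  their curve-expected share, scaled from the observed weeks).

Downstream filters mirror the monitoring-scheme protocol: indices with more
than 50% of season weeks missing are excluded, and only site x species
series contributing at least ten interannual growth observations within the
study window are retained.  Growth is r = log(N_t / N_{t-1}), defined only
when both consecutive indices are positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate import (
    WindowDefinition,
    flight_window,
    overwinter_window,
    post_flight_window,
    pre_flight_window,
)
from .simulate import N_WEEKS, WEEK1_DOY


class PhenologySignalError(ValueError):
    """Raised when a count pool carries no usable phenology signal."""


@dataclass
class FlightCurve:
    """Normalized weekly flight-activity proportions for one species/zone/year."""

    species_id: str
    zone: str
    year: int | None
    props: np.ndarray              # length N_WEEKS, >= 0, sums to 1

    def __post_init__(self):
        self.props = np.asarray(self.props, dtype=float)
        total = self.props.sum()
        if not np.isfinite(total) or total <= 0:
            raise PhenologySignalError("flight curve has no mass")
        self.props = self.props / total

    def percentile_week(self, q: float) -> int:
        """Smallest week whose cumulative proportion reaches q."""
        cum = np.cumsum(self.props)
        return int(np.searchsorted(cum, q - 1e-12) + 1)

    @property
    def p10_week(self) -> int:
        return self.percentile_week(0.10)

    @property
    def p90_week(self) -> int:
        return self.percentile_week(0.90)


def week_start_doy(week: int) -> int:
    return WEEK1_DOY + 7 * (week - 1)


def fit_flight_curve(
    counts: pd.DataFrame,
    species_id: str,
    zone: str | None = None,
    year: int | None = None,
    site_zone: pd.Series | None = None,
    spline_df: int = 6,
    min_weeks: int = 5,
) -> FlightCurve:
    """Fit a normalized flight curve from pooled weekly counts.

    Pools the counts of one species over the sites of a zone (all sites if
    ``zone`` is None) for one year (all years if None), fits a Poisson
    spline regression of count on week, and normalizes the fitted weekly
    values to sum 1.  Degenerate fits fall back to the empirical normalized
    mean weekly profile.
    """
    pool = counts[counts["species_id"] == species_id]
    if year is not None:
        pool = pool[pool["year"] == year]
    if zone is not None:
        if site_zone is None:
            raise ValueError("zone pooling requires a site_id -> zone mapping")
        pool = pool[pool["site_id"].map(site_zone) == zone]
    pool = pool.dropna(subset=["count"])
    weeks_with_data = pool["week"].nunique()
    if weeks_with_data < min_weeks:
        raise PhenologySignalError(
            f"{species_id}: only {weeks_with_data} non-missing weeks (< {min_weeks})"
        )
    if not (pool["count"] > 0).any():
        raise PhenologySignalError(f"{species_id}: no phenology signal (all counts zero)")

    props = _spline_profile(pool, spline_df)
    if props is None:
        props = _empirical_profile(pool)
    return FlightCurve(species_id, zone or "all", year, props)


def _spline_profile(pool: pd.DataFrame, spline_df: int) -> np.ndarray | None:
    import statsmodels.api as sm
    from statsmodels.gam.api import BSplines, GLMGam

    try:
        x = pool[["week"]].to_numpy(dtype=float)
        y = pool["count"].to_numpy(dtype=float)
        # spline support must cover the full season for prediction
        anchored_x = np.vstack([x, [[1.0]], [[float(N_WEEKS)]]])
        bs = BSplines(anchored_x, df=[spline_df], degree=[3], include_intercept=True)
        mat = bs.transform(x)
        model = sm.GLM(y, mat, family=sm.families.Poisson())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=100)
        grid = bs.transform(np.arange(1.0, N_WEEKS + 1)[:, None])
        mu = res.predict(grid)
        if not np.all(np.isfinite(mu)) or mu.sum() <= 0:
            return None
        return mu
    except Exception:
        return None


def _empirical_profile(pool: pd.DataFrame) -> np.ndarray:
    prof = pool.groupby("week")["count"].mean()
    props = np.zeros(N_WEEKS)
    props[prof.index.astype(int) - 1] = prof.to_numpy()
    return props


def define_windows(curve: FlightCurve) -> list[WindowDefinition]:
    """Phenological windows anchored on the flight-curve percentiles.

    Flight = [start of p10 week, end of p90 week); pre-flight = February 1 to
    the flight start; post-flight = flight end to end of October, year t-1
    only; overwinter fixed November (t-1) to January (t).
    """
    p10 = curve.p10_week
    p90 = curve.p90_week
    start = week_start_doy(p10)
    end = week_start_doy(p90) + 7
    return [
        overwinter_window(0),
        pre_flight_window(start, 0),
        flight_window(start, end, 0),
        post_flight_window(end),
    ]


@dataclass
class AnnualIndex:
    species_id: str
    site_id: str
    year: int
    index: float
    n_weeks_observed: int
    n_weeks_expected: int
    excluded: bool
    reason: str = ""


def impute_and_index(
    counts: pd.DataFrame,
    curve: FlightCurve,
    species_id: str,
    site_id: str,
    year: int,
    max_missing: float = 0.5,
    n_weeks_expected: int = N_WEEKS,
) -> AnnualIndex:
    """Annual abundance index with curve-based imputation of missing weeks.

    Observed weeks contribute their counts directly; missing weeks contribute
    the flight-curve expectation scaled by the abundance multiplier estimated
    from the observed weeks.  On complete data the index is exactly the
    weekly sum.  Indices with more than ``max_missing`` of the season's weeks
    missing are flagged excluded.
    """
    sub = counts[
        (counts["species_id"] == species_id)
        & (counts["site_id"] == site_id)
        & (counts["year"] == year)
    ]
    observed = sub.dropna(subset=["count"])
    obs_weeks = set(observed["week"].astype(int))
    n_obs = len(obs_weeks)
    missing_frac = 1.0 - n_obs / n_weeks_expected
    if n_obs == 0:
        return AnnualIndex(
            species_id, site_id, year, np.nan, 0, n_weeks_expected, True, "no observed weeks"
        )
    obs_sum = float(observed["count"].sum())
    props = curve.props
    p_obs = sum(props[w - 1] for w in obs_weeks if 1 <= w <= N_WEEKS)
    p_missing = 1.0 - p_obs
    multiplier = obs_sum / p_obs if p_obs > 0 else 0.0
    index = obs_sum + multiplier * p_missing
    excluded = missing_frac > max_missing
    return AnnualIndex(
        species_id, site_id, year, float(index), n_obs, n_weeks_expected,
        excluded, "missing weeks > 50%" if excluded else "",
    )


def index_table(
    counts: pd.DataFrame,
    site_zone: pd.Series | None = None,
    pool_years: bool = True,
    max_missing: float = 0.5,
) -> pd.DataFrame:
    """Annual abundance indices for every species x site x year in ``counts``.

    Flight curves are fitted per species x zone (pooled over years when
    ``pool_years``, else per year); species/zone/year pools without a usable
    phenology signal yield excluded indices.
    """
    rows = []
    zones = counts["site_id"].map(site_zone) if site_zone is not None else pd.Series(
        "all", index=counts.index
    )
    counts = counts.assign(_zone=zones.to_numpy())
    for (sp, zone), sub in counts.groupby(["species_id", "_zone"]):
        curves: dict[int | None, FlightCurve] = {}
        for (site, year), cell in sub.groupby(["site_id", "year"]):
            key = None if pool_years else int(year)
            if key not in curves:
                try:
                    curves[key] = fit_flight_curve(
                        sub, sp,
                        zone=None,
                        year=key,
                    )
                except PhenologySignalError:
                    curves[key] = None
            curve = curves[key]
            if curve is None:
                rows.append(
                    AnnualIndex(sp, site, int(year), np.nan, 0, N_WEEKS, True, "no phenology signal")
                )
                continue
            rows.append(
                impute_and_index(cell, curve, sp, site, int(year), max_missing=max_missing)
            )
    return pd.DataFrame([vars(r) for r in rows])


def filter_series(
    indices: pd.DataFrame,
    min_growth_obs: int = 10,
    years: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Retain site x species series with at least ``min_growth_obs``
    interannual growth observations inside the study window; drop excluded
    indices.  Idempotent."""
    df = indices.copy()
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    df = df.dropna(subset=["index"])
    if years is not None:
        df = df[(df["year"] >= years[0]) & (df["year"] <= years[1])]
    keep = []
    for key, sub in df.groupby(["species_id", "site_id"]):
        sub = sub.sort_values("year")
        yrs = sub["year"].to_numpy()
        pos = sub["index"].to_numpy() > 0
        n_growth = int(
            np.sum((np.diff(yrs) == 1) & pos[:-1] & pos[1:])
        )
        if n_growth >= min_growth_obs:
            keep.append(sub)
    if not keep:
        return df.iloc[0:0]
    return pd.concat(keep, ignore_index=True)


def growth_rates(indices: pd.DataFrame) -> pd.DataFrame:
    """Interannual growth observations r = log(N_t / N_{t-1}).

    Defined only for consecutive-year pairs with both indices positive;
    pairs touching a zero index are dropped.  Returns
    ``species_id, site_id, year, r, log_n_lag``.
    """
    rows = []
    for (sp, site), sub in indices.groupby(["species_id", "site_id"]):
        sub = sub.sort_values("year")
        yrs = sub["year"].to_numpy()
        n = sub["index"].to_numpy(dtype=float)
        for k in range(1, len(sub)):
            if yrs[k] - yrs[k - 1] == 1 and n[k] > 0 and n[k - 1] > 0:
                rows.append(
                    (sp, site, int(yrs[k]), float(np.log(n[k] / n[k - 1])), float(np.log(n[k - 1])))
                )
    return pd.DataFrame(rows, columns=["species_id", "site_id", "year", "r", "log_n_lag"])
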