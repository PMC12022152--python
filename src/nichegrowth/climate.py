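"""Phenological climate windows, the standardized aridity index and site anomalies.

Daily site climate (mean temperature, total precipitation) is summarised into
species-specific temporal windows anchored on the flight period: pre-flight,
flight, post-flight and overwintering, each referable to the focal year ``t``
or the previous year ``t-1``.  Window summaries feed three derived products:

* the standardized aridity index (SAI), a per-site composite of temperature
  and (inverted) precipitation z-scores -- positive in hot-dry years;
* raw climatic anomalies, the deviation of a year's window summary from the
  site's long-run mean for the same window;
* standardized anomalies, z-scored separately per climatic variable with
  precipitation sign-inverted so that "higher = hotter and/or drier" holds
  for every variable.

Conventions: temperature summaries are means of daily means (deg C);
precipitation summaries are totals (mm); day-of-year windows are half-open
``[start, end)``; the overwinter window spans November--December of year
``t-1`` plus January of year ``t`` and is assigned to the later year; all
standard deviations use the sample (n-1) convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

VARIABLES = ("temperature", "precipitation", "aridity")
WINDOW_KINDS = ("overwinter", "pre_flight", "flight", "post_flight")

#: day-of-year anchors (non-leap calendar)
FEB1 = 32
MAR1 = 60
NOV1 = 305
DEC31_END = 366  # exclusive


class ClimateCoverageError(KeyError):
    """Raised when a window's dates are absent from a daily climate series."""


@dataclass(frozen=True)
class WindowDefinition:
    """A temporal window over which daily climate is summarised.

    Parameters
    ----------
    kind
        One of ``overwinter``, ``pre_flight``, ``flight``, ``post_flight``.
    year_offset
        0 for year ``t``, 1 for year ``t-1`` (delayed response).
    segments
        Tuples ``(year_delta, start_doy, end_doy)`` with half-open day-of-year
        bounds, relative to the label year before ``year_offset`` is applied.
        The overwinter window has two segments because it straddles the
        calendar year boundary.
    """

    kind: str
    year_offset: int
    segments: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        if self.kind not in WINDOW_KINDS:
            raise ValueError(f"unknown window kind {self.kind!r}")
        if self.year_offset not in (0, 1):
            raise ValueError("year_offset must be 0 (year t) or 1 (year t-1)")
        if self.kind == "post_flight" and self.year_offset != 1:
            # adults are dead by the post-flight period of year t, so it can
            # only act with a one-year delay
            raise ValueError("post_flight window is only defined for year t-1")
        for _, s, e in self.segments:
            if not (1 <= s < e <= DEC31_END):
                raise ValueError(f"invalid segment bounds ({s}, {e})")

    @property
    def n_days(self) -> int:
        return sum(e - s for _, s, e in self.segments)

    @property
    def label(self) -> str:
        return f"{self.kind}@{'t-1' if self.year_offset else 't'}"


def flight_window(p10_doy: int, p90_end_doy: int, year_offset: int = 0) -> WindowDefinition:
    """Flight period: 10th to 90th percentile of the flight curve."""
    return WindowDefinition("flight", year_offset, ((0, p10_doy, p90_end_doy),))


def pre_flight_window(p10_doy: int, year_offset: int = 0) -> WindowDefinition:
    """Pre-flight period: February 1 to the flight 10th percentile."""
    return WindowDefinition("pre_flight", year_offset, ((0, FEB1, p10_doy),))


def post_flight_window(p90_end_doy: int) -> WindowDefinition:
    """Post-flight period of year t-1: flight 90th percentile to end of October."""
    return WindowDefinition("post_flight", 1, ((0, p90_end_doy, NOV1),))


def overwinter_window(year_offset: int = 0) -> WindowDefinition:
    """Overwintering period, fixed November (t-1) through January (t)."""
    return WindowDefinition(
        "overwinter", year_offset, ((-1, NOV1, DEC31_END), (0, 1, FEB1))
    )


def candidate_windows(p10_doy: int, p90_end_doy: int) -> list[WindowDefinition]:
    """The default candidate set: every phenological window crossed with year
    t / t-1, except post-flight which exists only at t-1 (7 windows)."""
    return [
        overwinter_window(0),
        overwinter_window(1),
        pre_flight_window(p10_doy, 0),
        pre_flight_window(p10_doy, 1),
        flight_window(p10_doy, p90_end_doy, 0),
        flight_window(p10_doy, p90_end_doy, 1),
        post_flight_window(p90_end_doy),
    ]


def _prepare_climate(climate: pd.DataFrame) -> pd.DataFrame:
    """Add year and a 365-day day-of-year (Feb 29 dropped, later leap days
    shifted back) so window bounds mean the same calendar dates every year."""
    out = climate.copy()
    if not np.issubdtype(out["date"].dtype, np.datetime64):
        out["date"] = pd.to_datetime(out["date"])
    out = out[~((out["date"].dt.month == 2) & (out["date"].dt.day == 29))].copy()
    out["year"] = out["date"].dt.year
    doy = out["date"].dt.dayofyear
    leap = out["date"].dt.is_leap_year
    out["doy"] = np.where(leap & (doy > 59), doy - 1, doy)
    return out


def window_values(
    climate: pd.DataFrame,
    windows: list[WindowDefinition],
    variables: tuple[str, ...] = VARIABLES,
    min_coverage: float = 0.95,
    sai_form: str = "difference",
) -> pd.DataFrame:
    """Summarise daily climate into per site x year x window x variable values.

    Parameters
    ----------
    climate
        Daily table with columns ``site_id, date, tmean_c, prec_mm``.
    windows
        Window definitions to evaluate.
    variables
        Subset of ``temperature``, ``precipitation``, ``aridity``.
    min_coverage
        Minimum fraction of window days that must be present for a
        site x year summary to be retained (boundary years are dropped).
    sai_form
        Passed to :func:`sai_from_z` for the aridity variable.

    Returns
    -------
    DataFrame with columns
    ``site_id, year, variable, window_kind, year_offset, value``.
    """
    unknown = set(variables) - set(VARIABLES)
    if unknown:
        raise ValueError(f"unknown variables {sorted(unknown)}")
    clim = _prepare_climate(climate)
    frames = []
    for w in windows:
        parts = []
        for d, s, e in w.segments:
            sub = clim[(clim["doy"] >= s) & (clim["doy"] < e)].copy()
            sub["label_year"] = sub["year"] - d + w.year_offset
            parts.append(sub)
        pooled = pd.concat(parts, ignore_index=True)
        g = pooled.groupby(["site_id", "label_year"]).agg(
            tmean=("tmean_c", "mean"), ptot=("prec_mm", "sum"), n=("doy", "size")
        )
        g = g[g["n"] >= min_coverage * w.n_days].reset_index()
        g = g.rename(columns={"label_year": "year"})

        if "aridity" in variables:
            g["aridity"] = _sai_by_site(g, sai_form)
        long_vars = [v for v in variables]
        colmap = {"temperature": "tmean", "precipitation": "ptot", "aridity": "aridity"}
        melted = g.melt(
            id_vars=["site_id", "year"],
            value_vars=[colmap[v] for v in long_vars],
            var_name="variable",
            value_name="value",
        )
        inv = {v: k for k, v in colmap.items()}
        melted["variable"] = melted["variable"].map(inv)
        melted["window_kind"] = w.kind
        melted["year_offset"] = w.year_offset
        frames.append(melted)
    out = pd.concat(frames, ignore_index=True)
    out = out.dropna(subset=["value"]).reset_index(drop=True)
    return out[["site_id", "year", "variable", "window_kind", "year_offset", "value"]]


def _sai_by_site(g: pd.DataFrame, form: str) -> pd.Series:
    """SAI per row of a site x year window table with tmean/ptot columns."""
    out = pd.Series(np.nan, index=g.index)
    for _, idx in g.groupby("site_id").groups.items():
        t = g.loc[idx, "tmean"]
        p = g.loc[idx, "ptot"]
        if len(idx) < 2:
            continue
        sd_t, sd_p = t.std(ddof=1), p.std(ddof=1)
        if sd_t == 0 or sd_p == 0:
            raise ValueError(
                "degenerate climate: zero interannual s.d. prevents the "
                "standardized aridity index"
            )
        out.loc[idx] = sai_from_z((t - t.mean()) / sd_t, (p - p.mean()) / sd_p, form)
    return out


def sai_from_z(z_t, z_p, form: str = "difference"):
    """Standardized aridity index from temperature/precipitation z-scores.

    ``difference`` (default): SAI = 0.5 * (z_T - z_P), positive in hot-dry
    years.  ``literal``: the product reading -z_P * 0.5 * z_T, kept for
    comparison.
    """
    if form == "difference":
        return 0.5 * (np.asarray(z_t) - np.asarray(z_p))
    if form == "literal":
        return -np.asarray(z_p) * 0.5 * np.asarray(z_t)
    raise ValueError(f"unknown SAI form {form!r}")


def window_mean(
    climate: pd.DataFrame,
    window: WindowDefinition,
    site_id,
    year: int,
    variable: str = "temperature",
) -> float:
    """A single site x year window summary (mean temperature, total
    precipitation, or SAI), raising :class:`ClimateCoverageError` when the
    window's dates are absent from the series."""
    sub = climate[climate["site_id"] == site_id]
    if sub.empty:
        raise ClimateCoverageError(f"no climate for site {site_id!r}")
    vals = window_values(sub, [window], variables=(variable,), min_coverage=1.0)
    row = vals[vals["year"] == year]
    if row.empty:
        raise ClimateCoverageError(
            f"climate for site {site_id!r}, year {year}, window {window.label} "
            "is incomplete or absent"
        )
    return float(row["value"].iloc[0])


def site_climatology(values: pd.DataFrame) -> pd.DataFrame:
    """Long-run mean and s.d. (over years) of window values, per
    site x variable x window."""
    g = (
        values.groupby(["site_id", "variable", "window_kind", "year_offset"])["value"]
        .agg(site_mean="mean", site_sd=lambda s: s.std(ddof=1), n_years="size")
        .reset_index()
    )
    return g


def compute_anomalies(values: pd.DataFrame, climatology: pd.DataFrame | None = None) -> pd.DataFrame:
    """Raw site climatic anomalies: window value minus the site long-run mean
    for the same window/variable."""
    if climatology is None:
        climatology = site_climatology(values)
    keys = ["site_id", "variable", "window_kind", "year_offset"]
    merged = values.merge(climatology[keys + ["site_mean"]], on=keys, how="left", validate="m:1")
    if merged["site_mean"].isna().any():
        missing = merged[merged["site_mean"].isna()].iloc[0]
        raise KeyError(
            f"no climatology for site {missing['site_id']!r}, "
            f"variable {missing['variable']}, window {missing['window_kind']}"
        )
    merged["anomaly"] = merged["value"] - merged["site_mean"]
    return merged.drop(columns=["site_mean"])


def standardize_anomalies(
    anomalies: pd.DataFrame,
    invert_precipitation: bool = True,
    column: str = "anomaly",
) -> pd.DataFrame:
    """Z-score anomalies separately per climatic variable.

    Precipitation is sign-inverted before standardization so that higher
    standardized values always mean hotter and/or drier conditions.
    """
    out = anomalies.copy()
    raw = out[column].astype(float).copy()
    if invert_precipitation:
        raw[out["variable"] == "precipitation"] *= -1.0
    std = pd.Series(np.nan, index=out.index)
    for var, idx in out.groupby("variable").groups.items():
        x = raw.loc[idx]
        sd = x.std(ddof=1)
        if len(idx) < 2 or sd == 0 or not np.isfinite(sd):
            raise ValueError(f"cannot standardize constant anomaly column for {var!r}")
        std.loc[idx] = (x - x.mean()) / sd
    out["standardized"] = std
    return out
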