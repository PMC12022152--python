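"""Degree of local adaptation: candidate anomaly models, AIC selection, dla.

For each species, annual log population growth is regressed on lagged log
abundance (Gompertz density dependence) and on a standardized climatic
anomaly plus its square, for every candidate combination of

* climatic variable: temperature, precipitation, aridity;
* phenological window: overwinter, pre-flight, flight (years t and t-1)
  and post-flight (year t-1 only);
* anomaly scale: local (deviation from the site's own long-run mean) or
  global (deviation from the species-wide mean over all occupied sites
  and years).

The best candidate per scale is chosen by AIC; the degree of local
adaptation (dla) is the difference in variance explained,
``dla = R2_local - R2_global`` (marginal R-squared by default), positive
for locally adapted species.  Site enters as a random intercept except for
species occupying fewer than 10 sites, for which the model reduces to
ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._lmm import FitConvergenceError, LinearMixedFit, fit_linear_model

VARIABLE_ORDER = ("temperature", "precipitation", "aridity")
WINDOW_ORDER = (
    ("overwinter", 0),
    ("overwinter", 1),
    ("pre_flight", 0),
    ("pre_flight", 1),
    ("flight", 0),
    ("flight", 1),
    ("post_flight", 1),
)

MIN_SITES_FOR_RANDOM_INTERCEPT = 10
MIN_GROWTH_OBSERVATIONS = 20


@dataclass
class CandidateModel:
    """One fitted anomaly-growth candidate (one variable x window x scale)."""

    species_id: str
    scale: str
    variable: str
    window_kind: str
    year_offset: int
    fit: LinearMixedFit | None
    converged: bool
    n_obs: int
    n_sites: int
    message: str = ""

    @property
    def aic(self) -> float:
        return self.fit.aic if self.fit is not None else np.inf

    @property
    def r2_marginal(self) -> float:
        return self.fit.r2_marginal if self.fit is not None else np.nan

    @property
    def r2_conditional(self) -> float:
        return self.fit.r2_conditional if self.fit is not None else np.nan

    def canonical_rank(self) -> tuple[int, int]:
        return (
            VARIABLE_ORDER.index(self.variable),
            WINDOW_ORDER.index((self.window_kind, self.year_offset)),
        )


@dataclass
class AdaptationResult:
    """Per-species outcome of the candidate scan."""

    species_id: str
    dla: float
    classification: str            # "local" | "global" | "ambiguous"
    best_scale: str                # scale with the lower AIC among the two bests
    r2_local: float
    r2_global: float
    best_local: CandidateModel
    best_global: CandidateModel
    n_obs: int
    n_sites: int


def global_anomalies(values: pd.DataFrame, occupied_sites) -> pd.DataFrame:
    """Anomalies from the species-wide mean over all occupied sites and years.

    ``values`` holds window summaries (site_id, year, variable, window_kind,
    year_offset, value); the species-wide mean is the flat average over all
    occupied site-year rows, per variable x window.
    """
    occ = values[values["site_id"].isin(list(occupied_sites))].copy()
    if occ.empty:
        raise ValueError("species occupies no site present in the climate table")
    keys = ["variable", "window_kind", "year_offset"]
    means = occ.groupby(keys)["value"].mean().rename("species_mean").reset_index()
    merged = occ.merge(means, on=keys, validate="m:1")
    merged["anomaly"] = merged["value"] - merged["species_mean"]
    return merged.drop(columns=["species_mean"])


def local_anomalies(values: pd.DataFrame, occupied_sites) -> pd.DataFrame:
    """Anomalies from each site's own long-run window mean."""
    occ = values[values["site_id"].isin(list(occupied_sites))].copy()
    if occ.empty:
        raise ValueError("species occupies no site present in the climate table")
    keys = ["site_id", "variable", "window_kind", "year_offset"]
    means = occ.groupby(keys)["value"].mean().rename("site_mean").reset_index()
    merged = occ.merge(means, on=keys, validate="m:1")
    merged["anomaly"] = merged["value"] - merged["site_mean"]
    return merged.drop(columns=["site_mean"])


def _standardize(anoms: pd.DataFrame) -> pd.DataFrame:
    """Z-score anomalies per variable over the species table, inverting
    precipitation so higher always means hotter/drier."""
    out = anoms.copy()
    a = out["anomaly"].astype(float).copy()
    a[out["variable"] == "precipitation"] *= -1.0
    z = pd.Series(np.nan, index=out.index)
    for _, idx in out.groupby(["variable", "window_kind", "year_offset"]).groups.items():
        x = a.loc[idx]
        sd = x.std(ddof=1)
        z.loc[idx] = (x - x.mean()) / sd if sd > 0 else 0.0
    out["w"] = z
    return out


def fit_growth_model(
    growth: pd.DataFrame,
    anomalies: pd.DataFrame,
    species_id: str = "",
    scale: str = "local",
    variable: str = "temperature",
    window_kind: str = "flight",
    year_offset: int = 0,
    min_sites_for_re: int = MIN_SITES_FOR_RANDOM_INTERCEPT,
    reml: bool = False,
) -> CandidateModel:
    """Fit one candidate: r ~ log N_{t-1} + W + W^2 (+ site random intercept).

    ``growth`` needs columns ``site_id, year, r, log_n_lag``; ``anomalies``
    needs ``site_id, year, w`` (standardized anomaly) already restricted to
    one variable x window.
    """
    merged = growth.merge(anomalies[["site_id", "year", "w"]], on=["site_id", "year"], how="inner")
    merged = merged.dropna(subset=["r", "log_n_lag", "w"])
    n_sites = merged["site_id"].nunique()
    X = pd.DataFrame(
        {
            "const": 1.0,
            "log_n_lag": merged["log_n_lag"].to_numpy(),
            "w": merged["w"].to_numpy(),
            "w2": merged["w"].to_numpy() ** 2,
        }
    )
    groups = merged["site_id"] if n_sites >= min_sites_for_re else None
    try:
        fit = fit_linear_model(merged["r"].to_numpy(), X, groups=groups, reml=reml)
        return CandidateModel(
            species_id, scale, variable, window_kind, year_offset,
            fit=fit, converged=fit.converged, n_obs=fit.n_obs, n_sites=n_sites,
        )
    except (FitConvergenceError, ValueError) as err:
        return CandidateModel(
            species_id, scale, variable, window_kind, year_offset,
            fit=None, converged=False, n_obs=len(merged), n_sites=n_sites,
            message=str(err),
        )


def select_best_candidate(candidates: list[CandidateModel]) -> CandidateModel:
    """Minimum-AIC candidate among converged fits; exact ties broken by the
    canonical variable-then-window order."""
    ok = [c for c in candidates if c.converged]
    if not ok:
        raise FitConvergenceError("no converged candidate model")
    return min(ok, key=lambda c: (c.aic, c.canonical_rank()))


def compute_dla(
    best_local: CandidateModel,
    best_global: CandidateModel,
    r2_kind: str = "marginal",
) -> AdaptationResult:
    """Degree of local adaptation from the two scale-specific best fits."""
    if best_local.n_obs != best_global.n_obs:
        raise ValueError(
            "local and global fits cover different observations "
            f"({best_local.n_obs} vs {best_global.n_obs})"
        )
    r2l = best_local.r2_marginal if r2_kind == "marginal" else best_local.r2_conditional
    r2g = best_global.r2_marginal if r2_kind == "marginal" else best_global.r2_conditional
    dla = float(r2l - r2g)
    if dla > 0:
        cls = "local"
    elif dla < 0:
        cls = "global"
    else:
        cls = "ambiguous"
    best_scale = "local" if best_local.aic <= best_global.aic else "global"
    return AdaptationResult(
        species_id=best_local.species_id,
        dla=dla,
        classification=cls,
        best_scale=best_scale,
        r2_local=float(r2l),
        r2_global=float(r2g),
        best_local=best_local,
        best_global=best_global,
        n_obs=best_local.n_obs,
        n_sites=best_local.n_sites,
    )


class DegreeOfAdaptationModel:
    """Candidate scan for one or more species.

    Parameters
    ----------
    growth
        Growth observations: ``species_id, site_id, year, r, log_n_lag``.
    window_values
        Window climate summaries for every candidate variable x window:
        ``site_id, year, variable, window_kind, year_offset, value``.
    occupancy
        Optional ``{species_id: iterable of site_ids}``; defaults to the
        sites present in ``growth`` for each species.
    min_obs
        Species with fewer growth observations are skipped with a warning
        entry rather than fitted.
    """

    def __init__(
        self,
        growth: pd.DataFrame,
        window_values: pd.DataFrame,
        occupancy: dict | None = None,
        min_obs: int = MIN_GROWTH_OBSERVATIONS,
        r2_kind: str = "marginal",
        min_sites_for_re: int = MIN_SITES_FOR_RANDOM_INTERCEPT,
    ) -> None:
        self.growth = growth
        self.window_values = window_values
        self.occupancy = occupancy
        self.min_obs = min_obs
        self.r2_kind = r2_kind
        self.min_sites_for_re = min_sites_for_re

    def _species_candidates(self, sp: str) -> tuple[list[CandidateModel], list[CandidateModel]]:
        g = self.growth[self.growth["species_id"] == sp]
        occupied = (
            list(self.occupancy[sp]) if self.occupancy is not None else sorted(g["site_id"].unique())
        )
        occupied = [s if not hasattr(s, "site_id") else s.site_id for s in occupied]
        loc = _standardize(local_anomalies(self.window_values, occupied))
        glo = _standardize(global_anomalies(self.window_values, occupied))
        out: dict[str, list[CandidateModel]] = {"local": [], "global": []}
        for scale, table in (("local", loc), ("global", glo)):
            for variable in VARIABLE_ORDER:
                for kind, offset in WINDOW_ORDER:
                    sub = table[
                        (table["variable"] == variable)
                        & (table["window_kind"] == kind)
                        & (table["year_offset"] == offset)
                    ]
                    if sub.empty:
                        continue
                    out[scale].append(
                        fit_growth_model(
                            g, sub, species_id=sp, scale=scale, variable=variable,
                            window_kind=kind, year_offset=offset,
                            min_sites_for_re=self.min_sites_for_re,
                        )
                    )
        return out["local"], out["global"]

    def fit(self) -> "DegreeOfAdaptationResults":
        results, skipped = [], []
        for sp in sorted(self.growth["species_id"].unique()):
            n = len(self.growth[self.growth["species_id"] == sp].dropna(subset=["r"]))
            if n < self.min_obs:
                skipped.append((sp, f"only {n} growth observations (< {self.min_obs})"))
                continue
            local_c, global_c = self._species_candidates(sp)
            try:
                best_l = select_best_candidate(local_c)
                best_g = select_best_candidate(global_c)
            except FitConvergenceError as err:
                skipped.append((sp, str(err)))
                continue
            results.append(compute_dla(best_l, best_g, r2_kind=self.r2_kind))
        return DegreeOfAdaptationResults(results, skipped)


@dataclass
class DegreeOfAdaptationResults:
    """Collection of per-species adaptation results."""

    results: list[AdaptationResult]
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "species_id": r.species_id,
                    "best_scale": r.best_scale,
                    "best_variable": r.best_local.variable
                    if r.best_scale == "local"
                    else r.best_global.variable,
                    "window_kind": r.best_local.window_kind
                    if r.best_scale == "local"
                    else r.best_global.window_kind,
                    "year_offset": r.best_local.year_offset
                    if r.best_scale == "local"
                    else r.best_global.year_offset,
                    "r2_local": r.r2_local,
                    "r2_global": r.r2_global,
                    "dla": r.dla,
                    "classification": r.classification,
                    "n_obs": r.n_obs,
                    "n_sites": r.n_sites,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "species_id", "best_scale", "best_variable", "window_kind",
                "year_offset", "r2_local", "r2_global", "dla", "classification",
                "n_obs", "n_sites",
            ],
        )

    def summary(self) -> str:
        df = self.to_frame()
        lines = ["Degree of local adaptation", "=" * 60]
        if not df.empty:
            lines.append(df.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
        for sp, why in self.skipped:
            lines.append(f"skipped {sp}: {why}")
        return "\n".join(lines)
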